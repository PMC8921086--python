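"""Model inputs for the pancreatic-cancer M-staging cost-effectiveness model.

All quantities live in a single :class:`ModelParams` record: diagnostic test
performance of contrast-enhanced CT, one-time procedure costs, long-term
annual therapy costs, health-state utilities, and annual transition
probabilities, together with the decision framing (willingness-to-pay,
discount rate, horizon).  Structural modelling conventions that the input
evidence does not pin down — reward accrual timing, which published
post-surgery utility pair is active, how the R1/local-recurrence split is
applied, which states also pay the post-surgery follow-up schedule — are
collected in :class:`StructureFlags` so they can be enumerated explicitly
(see :func:`pancea.sensitivity.structure_search`).

Currency values are unit-less USD of the source cost year; no inflation
adjustment is applied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "StructureFlags",
    "ParameterError",
    "default_params",
    "load_params",
    "save_params",
    "perturb_params",
    "with_structure",
    "M0_UTILITY_SETS",
    "REFERENCE_BASE_CASE",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


#: The two published utility pairs for resected, metastasis-free patients
#: (first year after surgery, following years).  Both circulate in the
#: source literature; the active pair is chosen by
#: ``StructureFlags.utility_set``.
M0_UTILITY_SETS = {
    "table1": (0.79, 0.87),
    "text": (0.726, 0.797),
}

#: Published base-case outputs used as calibration targets by the structure
#: search: discounted totals per patient over the 5-year horizon.
REFERENCE_BASE_CASE = {
    "cost_ce_ct": 187_601.0,
    "qaly_ce_ct": 2.337,
    "cost_ce_mr_ct": 185_597.0,
    "qaly_ce_mr_ct": 2.347,
}

_ENUM_FLAGS = {
    "accrual": ("begin", "end"),
    "utility_set": ("table1", "text"),
    "r1_split_timing": ("at_entry", "annual"),
    "r1_cost_schedule": ("flat", "first_year_replaced", "plus_followup"),
    "met_cost_schedule": ("flat", "plus_followup"),
    "surgery_cost_scope": ("operated", "staged_resectable"),
    "first_year_reference": ("global", "state_entry"),
}


@dataclass(frozen=True)
class StructureFlags:
    """Structural conventions left open by the published model description.

    Defaults are the combination selected by the structure search against
    the published base-case totals (``REFERENCE_BASE_CASE``); every flag is
    re-enumerated by :func:`pancea.sensitivity.structure_search`.

    Attributes
    ----------
    half_cycle_correction:
        Average state membership between cycle start and end when accruing
        rewards.  Overrides ``accrual`` when on.
    accrual:
        ``"begin"`` — cycle-k rewards use the state distribution at the
        start of the cycle; ``"end"`` — at the end.
    terminal_stage:
        With ``accrual="begin"``, add one further accrual for the state
        distribution reached at the horizon (stage counting inclusive of
        both the entry and the terminal stage, as cohort software commonly
        does).  A 5-year horizon then carries 6 reward points.
    utility_set:
        Which published M0 post-surgery utility pair is active (see
        ``M0_UTILITY_SETS``).
    r1_split_timing:
        ``"at_entry"`` — the R1 proportion splits resected survivors at
        model entry; ``"annual"`` — it acts as a yearly hazard of moving
        from the disease-free to the local-recurrence state.
    r1_mortality:
        Annual death probability of the R1/local-recurrence state:
        ``"m0"`` reuses the metastasis-free mortality, or a float override.
    r1_cost_schedule:
        Annual cost of the R1/local state: ``"flat"`` — local-recurrence
        therapy every year; ``"first_year_replaced"`` — the first-year
        post-surgery therapy cost in year one, local-recurrence therapy
        thereafter; ``"plus_followup"`` — local-recurrence therapy plus the
        post-surgery follow-up schedule.
    met_cost_schedule:
        Whether resected patients with metastases pay the post-surgery
        follow-up schedule on top of metastatic therapy.
    surgery_cost_scope:
        ``"operated"`` — only operated patients incur the surgery cost;
        ``"staged_resectable"`` — the whole CT-resectable cohort incurs it
        (the resection pathway is costed at the decision node, before MRI
        reclassification).
    first_year_reference:
        Whether "first year" rewards key on global cycle 1 or on time since
        entering the state.
    """

    half_cycle_correction: bool = False
    accrual: str = "begin"
    terminal_stage: bool = True
    utility_set: str = "text"
    r1_split_timing: str = "at_entry"
    r1_mortality: str | float = "m0"
    r1_cost_schedule: str = "first_year_replaced"
    met_cost_schedule: str = "plus_followup"
    surgery_cost_scope: str = "staged_resectable"
    first_year_reference: str = "global"

    def validate(self) -> None:
        for name, allowed in _ENUM_FLAGS.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ParameterError(
                    f"structure.{name}: {value!r} not one of {allowed}"
                )
        r1m = self.r1_mortality
        if r1m != "m0":
            if not isinstance(r1m, (int, float)) or not 0.0 <= float(r1m) <= 1.0:
                raise ParameterError(
                    "structure.r1_mortality: must be 'm0' or a probability in [0, 1]"
                )
        if self.terminal_stage and (self.accrual != "begin" or self.half_cycle_correction):
            raise ParameterError(
                "structure.terminal_stage: only defined for accrual='begin' "
                "without half-cycle correction"
            )


# field groups used by validation, perturbation and the PSA
PROBABILITY_FIELDS = (
    "p_ct_tp",
    "p_ct_fp",
    "p_mri_detect",
    "p_r1",
    "p_met_after_resection",
    "p_surgery_death",
    "p_death_m1",
    "p_death_m0",
)
UTILITY_FIELDS = (
    "u_m1_post_surgery",
    "u_m1_no_surgery",
    "u_m0_post_surgery_y1",
    "u_m0_post_surgery_later",
    "u_dead",
)
COST_FIELDS = (
    "cost_ct",
    "cost_mri",
    "cost_surgery",
    "cost_m1_therapy",
    "cost_post_surgery_y1",
    "cost_post_surgery_later",
    "cost_m1_after_surgery",
    "cost_local_recurrence",
)


@dataclass(frozen=True)
class ModelParams:
    """Complete input set for one model run.

    Defaults are the published base-case estimates: a 70-year-old cohort
    staged for pancreatic cancer, annual cycles over a 5-year horizon, 3%
    discounting and a willingness-to-pay of $100,000/QALY.  Note that the
    M0 post-surgery utilities default to the pair selected by
    ``structure.utility_set`` (use :func:`default_params`).
    """

    # decision framing
    start_age: int = 70
    horizon: int = 5
    discount_rate: float = 0.03
    wtp: float = 100_000.0

    # diagnostic test performance (CE-CT resectability classification)
    p_ct_tp: float = 0.9225
    p_ct_fp: float = 0.0775
    p_mri_detect: float = 1.0

    # one-time costs
    cost_ct: float = 692.0
    cost_mri: float = 615.0
    cost_surgery: float = 42_869.0

    # annual costs
    cost_m1_therapy: float = 60_000.0
    cost_post_surgery_y1: float = 36_126.0
    cost_post_surgery_later: float = 1_126.0
    cost_m1_after_surgery: float = 60_000.0
    cost_local_recurrence: float = 30_000.0

    # utilities
    u_m1_post_surgery: float = 0.6
    u_m1_no_surgery: float = 0.65
    u_m0_post_surgery_y1: float = 0.726
    u_m0_post_surgery_later: float = 0.797
    u_dead: float = 0.0

    # transition probabilities (annual unless noted)
    p_r1: float = 0.8
    p_met_after_resection: float = 0.38
    p_surgery_death: float = 0.037  # applied once, at resection
    p_death_m1: float = 0.5074
    p_death_m0: float = 0.029

    structure: StructureFlags = field(default_factory=StructureFlags)

    def validate(self) -> "ModelParams":
        """Check every invariant; raise :class:`ParameterError` naming the field."""
        for name in PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}: probability {v} outside [0, 1]")
        for name in UTILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}: utility {v} outside [0, 1]")
        for name in COST_FIELDS:
            v = getattr(self, name)
            if v < 0.0:
                raise ParameterError(f"{name}: cost {v} is negative")
        if self.u_dead != 0.0:
            raise ParameterError(f"u_dead: must be 0, got {self.u_dead}")
        if self.horizon < 1:
            raise ParameterError(f"horizon: must be >= 1, got {self.horizon}")
        if self.wtp < 0.0:
            raise ParameterError(f"wtp: must be >= 0, got {self.wtp}")
        if self.discount_rate < 0.0:
            raise ParameterError(
                f"discount_rate: must be >= 0, got {self.discount_rate}"
            )
        if abs(self.p_ct_tp + self.p_ct_fp - 1.0) > 1e-12:
            raise ParameterError(
                f"p_ct_tp + p_ct_fp = {self.p_ct_tp + self.p_ct_fp!r}, expected 1"
            )
        self.structure.validate()
        return self

    @property
    def r1_death_probability(self) -> float:
        """Annual death probability of the R1/local-recurrence state."""
        r1m = self.structure.r1_mortality
        return self.p_death_m0 if r1m == "m0" else float(r1m)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def with_structure(params: ModelParams, structure: StructureFlags) -> ModelParams:
    """Return ``params`` under a different structural configuration.

    If the active utility set changes, the M0 post-surgery utility pair is
    swapped to the published values of the new set — but only when the
    current pair still equals the published values of the old set (a
    user-perturbed pair is preserved).
    """
    updates: dict = {"structure": structure}
    old_set = params.structure.utility_set
    new_set = structure.utility_set
    if new_set != old_set:
        current = (params.u_m0_post_surgery_y1, params.u_m0_post_surgery_later)
        if current == M0_UTILITY_SETS[old_set]:
            y1, later = M0_UTILITY_SETS[new_set]
            updates["u_m0_post_surgery_y1"] = y1
            updates["u_m0_post_surgery_later"] = later
    return replace(params, **updates)


def default_params(structure: StructureFlags | None = None, **overrides) -> ModelParams:
    """Published base-case parameter set.

    Parameters
    ----------
    structure:
        Structural flags; defaults to the structure-search-selected
        configuration.  The M0 post-surgery utility pair follows the
        ``utility_set`` flag.
    overrides:
        Field overrides applied after utility-set resolution.
    """
    structure = structure or StructureFlags()
    y1, later = M0_UTILITY_SETS[structure.utility_set]
    params = ModelParams(
        structure=structure,
        u_m0_post_surgery_y1=y1,
        u_m0_post_surgery_later=later,
    )
    if overrides:
        params = replace(params, **overrides)
    return params.validate()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _params_to_plain(params: ModelParams) -> dict:
    d = {}
    for f in fields(ModelParams):
        if f.name == "structure":
            continue
        d[f.name] = getattr(params, f.name)
    d["structure"] = dataclasses.asdict(params.structure)
    return d


def _plain_to_params(data: dict, source: str = "<dict>") -> ModelParams:
    if not isinstance(data, dict):
        raise ParameterError(f"{source}: expected a mapping at top level")
    data = dict(data)
    structure_data = data.pop("structure", None) or {}
    known = {f.name for f in fields(ModelParams)} - {"structure"}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(f"{source}: unknown field(s) {sorted(unknown)}")
    missing = known - set(data)
    if missing:
        raise ParameterError(f"{source}: missing required field(s) {sorted(missing)}")
    flag_names = {f.name for f in fields(StructureFlags)}
    unknown_flags = set(structure_data) - flag_names
    if unknown_flags:
        raise ParameterError(
            f"{source}: unknown structure flag(s) {sorted(unknown_flags)}"
        )
    structure = StructureFlags(**structure_data)  # missing flags take defaults
    return ModelParams(structure=structure, **data).validate()


def load_params(path: str | Path) -> ModelParams:
    """Load and validate a parameter file (YAML or JSON, by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    elif path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        raise ParameterError(
            f"{path}: unsupported extension {path.suffix!r} (use .yaml/.yml/.json)"
        )
    return _plain_to_params(data, source=str(path))


def save_params(params: ModelParams, path: str | Path) -> None:
    """Serialize a parameter set to YAML or JSON (stable key order)."""
    path = Path(path)
    plain = _params_to_plain(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(plain, indent=2) + "\n")
    elif path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(plain, sort_keys=False))
    else:
        raise ParameterError(
            f"{path}: unsupported extension {path.suffix!r} (use .yaml/.yml/.json)"
        )


def bundled_defaults_path() -> Path:
    """Path of the bundled base-case parameter file."""
    return Path(resources.files("pancea").joinpath("data/base_case.yaml"))


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def perturb_params(
    base: ModelParams, relative_width: float, seed: int
) -> ModelParams:
    """Randomly perturb every probability, utility and cost of ``base``.

    Each value is multiplied by an independent uniform factor in
    ``[1 - relative_width, 1 + relative_width]`` and clipped back to its
    valid support.  The CT accuracy pair is perturbed through the
    false-positive rate so that TP + FP = 1 is preserved, and ``u_dead``
    stays 0.  Reproducible for a fixed seed.
    """
    if not 0.0 <= relative_width < 1.0:
        raise ParameterError(
            f"relative_width: must be in [0, 1), got {relative_width}"
        )
    rng = np.random.default_rng(seed)
    updates: dict = {}

    def factor() -> float:
        return float(rng.uniform(1.0 - relative_width, 1.0 + relative_width))

    for name in PROBABILITY_FIELDS:
        if name == "p_ct_tp":
            continue  # derived from p_ct_fp
        v = float(np.clip(getattr(base, name) * factor(), 0.0, 1.0))
        updates[name] = v
    updates["p_ct_tp"] = 1.0 - updates["p_ct_fp"]
    for name in UTILITY_FIELDS:
        if name == "u_dead":
            continue
        updates[name] = float(np.clip(getattr(base, name) * factor(), 0.0, 1.0))
    for name in COST_FIELDS:
        updates[name] = max(0.0, getattr(base, name) * factor())
    return replace(base, **updates).validate()
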