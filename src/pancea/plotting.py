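"""Publication-style figures for the staging cost-effectiveness analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_tornado",
    "plot_ceac",
    "plot_psa_scatter",
    "plot_nmb_vs_resectability",
]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_tornado(frame: pd.DataFrame, path: str | Path, top: int = 15) -> Path:
    """Horizontal-bar tornado of incremental NMB (CE-MR/CT vs CE-CT)."""
    frame = frame.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(frame) + 1.5))
    base = frame["inmb_base"].iloc[0]
    lo = np.minimum(frame["inmb_low"], frame["inmb_high"])
    hi = np.maximum(frame["inmb_low"], frame["inmb_high"])
    ax.barh(frame["parameter"], hi - lo, left=lo, color="#4878b0")
    ax.axvline(base, color="k", lw=1, ls="--", label="base case")
    ax.axvline(0, color="r", lw=1, label="indifference")
    ax.set_xlabel("incremental NMB of CE-MR/CT vs CE-CT ($)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    return _save(fig, path)


def plot_ceac(ceac: pd.DataFrame, path: str | Path) -> Path:
    """Cost-effectiveness acceptability curve of CE-MR/CT."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["acceptability_ce_mr_ct"], marker="o", ms=3)
    ax.axhline(0.5, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("willingness-to-pay ($/QALY)")
    ax.set_ylabel("P(CE-MR/CT cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    return _save(fig, path)


def plot_psa_scatter(
    iterations: pd.DataFrame, path: str | Path, sample: int = 2_000
) -> Path:
    """Cost vs effectiveness scatter of Monte Carlo iterations."""
    it = iterations.head(sample)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(it["qaly_ce_ct"], it["cost_ce_ct"], s=4, alpha=0.4,
               label="CE-CT", color="#c44e52")
    ax.scatter(it["qaly_ce_mr_ct"], it["cost_ce_mr_ct"], s=4, alpha=0.4,
               label="CE-MR/CT", color="#4878b0")
    ax.set_xlabel("effectiveness (QALYs)")
    ax.set_ylabel("cost ($)")
    ax.legend()
    fig.tight_layout()
    return _save(fig, path)


def plot_nmb_vs_resectability(
    curve: pd.DataFrame, path: str | Path, crossover: float | None = None
) -> Path:
    """NMB of both strategies against the resectability classification rate."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["p_ct_tp"], curve["nmb_ce_ct"], label="CE-CT", color="#c44e52")
    ax.plot(curve["p_ct_tp"], curve["nmb_ce_mr_ct"], label="CE-MR/CT",
            color="#4878b0")
    if crossover is not None:
        ax.axvline(crossover, color="grey", ls="--", lw=1,
                   label=f"crossover {100 * crossover:.2f}%")
    ax.set_xlabel("probability of correct resectability classification")
    ax.set_ylabel("net monetary benefit ($)")
    ax.legend()
    fig.tight_layout()
    return _save(fig, path)
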