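# Methods

## Cohort and decision tree

The modelled cohort is the population of pancreatic-cancer patients whom
contrast-enhanced CT classifies as resectable at initial staging. Patients
CT classifies as non-resectable are managed identically under both
strategies and cannot generate an incremental difference, so they are
excluded; this keeps the comparison focused on the harm the added MRI can
avert — resection of patients with occult metastases.

With probability `p_ct_tp = 0.9225` the classification is correct; the
complementary `p_ct_fp = 0.0775` of the cohort carries occult metastases.
Under CE-CT alone everyone is operated. Under CE-MR/CT the added liver
MRI detects the occult metastases of a false positive with probability
`p_mri_detect` (default 1.0 — no MRI error rate is published for this
setting, so perfect detection is the base assumption and the parameter is
exposed for sensitivity work; reported MRI sensitivity for liver
metastases is 90–97%). Detected patients move to palliative management
without surgery; MRI false negatives among truly resectable patients are
assumed absent.

Perioperative mortality (`p_surgery_death = 0.037`) applies once, at
cycle 0, to operated patients, who accrue the one-time costs but no
utility. Resected survivors without metastases split at entry into the
disease-free and the R1/local-recurrence states in proportion
`p_r1 = 0.8` (the alternative reading — an annual disease-free → local
hazard — is the structural flag `r1_split_timing="annual"`).

## Markov engine

Five states: alive non-resectable (`NONRES`), alive resected no
metastasis/recurrence (`RES_NED`), alive resected with R1/local
recurrence (`RES_LOC`), alive resected with metastases (`RES_MET`), dead
(`DEAD`, absorbing). Annual cycles, horizon 5 years, discount rate
3%/year applied as `1/(1+r)^k`.

Competing risks are composed **death-first**: the annual death
probability is applied and every non-death transition acts on survivors
(e.g. `RES_NED → RES_MET` is `(1 − 0.029) × 0.38`). This keeps every row
of the transition matrix stochastic for *any* valid parameter set, which
matters when the sensitivity analyses push probabilities toward their
bounds; no ad-hoc capping is ever needed.

Annual inputs: metastasis after resection 38%/yr; mortality 50.74%/yr
with metastatic disease (used by `NONRES` and `RES_MET`), 2.9%/yr without
(used by `RES_NED`, and by `RES_LOC` unless the `r1_mortality` flag
overrides it). The constant 2.9%/yr stands in for an age-specific life
table; `build_transition_matrix` accepts an optional `m0_hazard(age)`
callable for age-dependent mortality, defaulting to off.

No published utility or mortality exists for the R1/local-recurrence
state; it uses the active M0 post-surgery utility pair (its occupants are
metastasis-free) and M0 mortality by default.

## Reward timing and the structure search

The published model was built in commercial decision-tree software and
its description leaves several conventions open. Each is an explicit
`StructureFlags` field, and `structure_search()` runs the base case under
all 192 combinations, ranking them by maximum relative error against the
four published base-case totals (costs $187,601 / $185,597 and
effectiveness 2.337 / 2.347 QALYs). The package defaults are the selected
configuration:

* **Accrual timing**: cycle-k rewards use the state distribution at the
  *start* of the cycle, discounted by `1/(1.03)^k`, and stage counting is
  inclusive of the terminal stage, so the 5-year horizon carries six
  reward points (`accrual="begin"`, `terminal_stage=True`). This is the
  only timing convention that reproduces the published CE-CT
  effectiveness essentially exactly (2.33718 computed vs 2.33718 implied
  by the published cost/NMB pair); end-of-cycle accrual and half-cycle
  correction miss it by 0.2–0.3 QALY.
* **Utility set**: the published description carries two M0 post-surgery
  utility pairs, 0.79/0.87 (tabulated) and 0.726/0.797 (text). The search
  selects the text pair (`utility_set="text"`); both ship and neither is
  silently preferred elsewhere.
* **Cost schedules**: the R1/local state pays the first-year post-surgery
  therapy cost ($36,126) in year one and local-recurrence therapy
  ($30,000/yr) thereafter (`r1_cost_schedule="first_year_replaced"`);
  resected patients with metastases pay metastatic therapy ($60,000/yr)
  plus the post-surgery follow-up schedule
  (`met_cost_schedule="plus_followup"`).
* **Surgery cost scope**: the resection-pathway cost is attached at the
  decision node, i.e. charged to the whole CT-resectable cohort in both
  arms (`surgery_cost_scope="staged_resectable"`). The alternative —
  charging only operated patients — fits the published CE-MR/CT cost
  visibly worse (−1.9% vs −0.1%); under the selected scope the CE-MR/CT
  saving comes from the averted downstream metastatic-therapy costs of
  futile resections rather than the operation itself.
* **First-year reference**: "first year" rewards key on global cycle 1
  (`first_year_reference="global"`). The alternative, time-since-state-
  entry, is implemented through internal one-cycle tunnel expansions of
  `RES_LOC` and `RES_MET` and re-enumerated by the search.

The selected configuration reproduces the published totals with a maximum
relative error of 0.23% and both net monetary benefits within 1%. One-time
costs enter undiscounted at cycle 0.

## Cost-effectiveness metrics

`NMB = WTP × QALY − cost` with WTP $100,000/QALY by default. Decisions
(dominance verdicts, acceptability curves, thresholds) are made on NMB;
the ICER `Δcost/ΔQALY` is reported but is sign-ambiguous when one
strategy dominates, and is left undefined (None) at zero QALY difference.

## Sensitivity analyses

**Tornado (one-way)**: each input varied ±25% of its base value, clipped
to its valid support, others fixed; the outcome is the incremental NMB of
CE-MR/CT (ICERs at the endpoints are recorded alongside). The CT accuracy
pair has one degree of freedom (TP + FP = 1) and a ±25% swing of the
92.25% true-positive rate would exceed 1, so the pair is varied through
the false-positive rate. Parameters with identical effects on both arms
(e.g. the CT cost itself) correctly produce zero-width bars.

**Threshold analysis**: plain bisection on `p_ct_tp` (FP rate set to the
complement) for the root of `NMB(CE-MR/CT) − NMB(CE-CT)`, default bracket
[0.80, 1.0], tolerance 1e-6; a bracket without a sign change raises an
explicit no-crossover error carrying both endpoint values. The base-case
crossover is 98.60%.

**Probabilistic sensitivity analysis**: the published description states
the iteration count (30,000) but not the distributions, so conventional
families are used — probabilities and utilities ~ Beta with mean equal to
the base value and standard error 10% of the mean (capped at half the
maximal Beta SD so the distribution stays proper; degenerate means stay
fixed), costs ~ Gamma with mean equal to the base value and SE 20% of the
mean — all independent, the accuracy pair drawn through the FP rate. All
hyperparameters are overridable per parameter in `PSASpec`. Acceptability
is the fraction of iterations in which CE-MR/CT has the strictly higher
NMB, evaluated on a $0–$200,000 grid in $5,000 steps (covering both
published operating points, $0 and $100,000). Because the distributions
are a reconstruction, the probabilistic results are checked as ordering
claims (acceptability > 0.5), not as figures to digit precision. At
30,000 iterations the binomial 95% half-width near p = 0.5 is below
0.006, so majority assertions are robust to Monte Carlo noise.

## Microsimulation oracle

`simulate_patients` walks individual patients through the *same* decision
tree, transition matrices, reward schedules, accrual timing and
discounting as the cohort engine (single source of transition truth), so
cohort-vs-microsimulation disagreement isolates accumulation or
discounting bugs. Agreement is asserted at n = 200,000 within 3 standard
errors for the base case and across 20 generated stress scenarios
(n = 50,000, 4 SE) that pin edge regions — zero false positives, certain
metastatic mortality, zero discounting — and rotate through the
alternative structural conventions. Convergence is additionally
spot-checked via the 1/√n scaling of the standard error.

## Synthetic inputs and what the tests show

No external data exist: every input is a published point estimate. The
fixture generators (`perturb_params`, `generate_test_scenarios`) create
valid random parameter sets around those estimates (±30–40% uniform
perturbations plus pinned corners), which is what the invariant and
oracle properties are exercised on. Passing tests therefore demonstrate
internal correctness of the model mechanics and faithful reproduction of
the published base case — not that the published point estimates
themselves are right, nor how the conclusion would fare under parameter
correlations, tumor-stage stratification, or horizons beyond 5 years,
none of which the model represents.

## Numerical choices and limitations

* Row sums and occupancy conservation are enforced to 1e-12 / 1e-9.
* Bisection tolerance 1e-6 on the probability scale; ties at an exact
  root return immediately.
* Degenerate inputs are handled structurally: zero QALY difference yields
  an undefined ICER, `relative_width = 0` perturbation is the identity,
  zero-variance PSA reproduces the base case bit-for-bit.
* The model has no tunnel states beyond the single first-year reward
  distinction, no stage (T/N) stratification, no correlated PSA draws,
  no EVPI, and a constant (non-age-specific) background mortality by
  default; currency is not inflation-adjusted.
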