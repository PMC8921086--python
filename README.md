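# pancea

Decision-analytic cost-effectiveness model for the initial **M-staging of
pancreatic cancer**: contrast-enhanced CT alone (**CE-CT**, the standard of
care) versus CT plus an additional contrast-enhanced liver MRI
(**CE-MR/CT**).

Pancreatic cancer is frequently metastatic at diagnosis, and unrecognized
liver metastases lead to futile resections — major surgery with
perioperative mortality and no survival benefit. An added liver MRI can
reclassify such false-positive "resectable" patients before the operation.
`pancea` asks whether that extra scan is worth paying for, from a US
healthcare perspective, and is aimed at health-economics and
medical-imaging researchers who want a transparent, scriptable
re-implementation of this model rather than proprietary decision-tree
software.

## Model

A diagnostic decision tree feeds a five-state Markov cohort model with
annual cycles over a 5-year horizon:

* states: alive non-resectable; alive resected without metastasis or
  recurrence; alive resected with R1/local recurrence; alive resected with
  metastases; dead (absorbing);
* the cohort is the set of patients CE-CT classifies as resectable
  (correctly with probability 92.25%); in the CE-MR/CT arm the MRI
  reclassifies occult-metastatic false positives to palliative management;
* perioperative mortality (3.7%) applies once at resection; annual
  transition probabilities, costs and utilities are the published
  base-case estimates bundled in `src/pancea/data/base_case.yaml`;
* costs and QALYs are discounted at 3%/year and combined through the net
  monetary benefit at willingness-to-pay λ:

  NMB = λ·E − C,  ICER = ΔC/ΔE,

  with strategy choice made on NMB (the ICER is sign-ambiguous in the
  dominant quadrant).

Structural conventions the published description leaves open (reward
accrual timing, which published utility pair applies, the R1 cost
schedule, where the surgery cost is attached in the tree) are explicit
`StructureFlags`; `pancea.structure_search()` enumerates all 192
combinations against the published base-case totals and the package
defaults are the selected configuration. See `docs/methods.md`.

## Worked example

```python
import pancea

params = pancea.default_params()
results, comparison = pancea.run_base_case(params)
for name, res in results.items():
    print(f"{name:9s} cost ${res.total_cost:,.0f}  "
          f"QALY {res.total_qaly:.3f}  NMB ${res.nmb(params.wtp):,.0f}")
print(comparison.dominance, f"ICER {comparison.icer:,.0f}")
print(f"crossover {100 * pancea.threshold_resectability(params):.2f}%")
```

prints

```
CE-CT     cost $187,164  QALY 2.337  NMB $46,554
CE-MR/CT  cost $185,405  QALY 2.347  NMB $49,342
dominant ICER -171,006
crossover 98.60%
```

CE-MR/CT is *dominant*: it saves money (the averted futile resections and
their downstream metastatic therapy outweigh the MRI cost) while adding
QALYs, so the ICER is negative. The threshold analysis shows CE-MR/CT
keeps the higher net monetary benefit until CT's correct-classification
probability exceeds ≈98.6%, far above reported CT accuracy.

The same analyses are available from the command line:

```sh
pancea --out run basecase
pancea --out run --seed 1 psa --iterations 30000
pancea --out run tornado
pancea --out run threshold
pancea --out run structure-search
```

Each subcommand writes JSON/CSV artifacts (and figures) stamped with the
seed and a hash of the resolved parameter set.

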