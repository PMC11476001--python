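# vascband

Quantification of the macro-vasculature surrounding a pulmonary nodule, and
logistic malignancy modelling on top of it.

Screen-detected indeterminate pulmonary nodules are hard to classify from
nodule appearance alone. The vessels *around* a nodule are a candidate
biomarker: tumour angiogenesis recruits arteries in the peri-nodular
region. `vascband` implements the full analysis for that idea:

- **Band features.** Given 3-D NIfTI masks for the nodule, the artery tree,
  and the vein tree, the package computes — per compartment c ∈ {artery,
  vein} and cumulative band d ∈ {5, 10, 15} mm from the nodule surface —
  the branch count, vessel volume (cm³), and mean branch tortuosity
  (curved/chord length of the skeleton branches), always excluding
  vasculature inside the nodule. Features are named `artery5_count`,
  `vein10_volume`, etc.
- **Nodule characteristics.** Volume, mean density, mean/max diameter,
  surface area, irregularity (surface area / volume), HU composition ratios
  (cavity, ground-glass, fat, solid, calcified), and an Agatston-style
  calcification score.
- **Models.** Univariate logistic screens on raw units; then, per model
  family, z-scoring → LASSO (CV-tuned penalty) → VIF filter (threshold 5.0)
  → one-in-ten forward stepwise → logistic fit, evaluated by stratified
  k-fold CV with pooled out-of-fold AUC (DeLong 95% CI) and accuracy at the
  0.5 threshold (Wilson CI). Families cover the Artery/Vein/Vessel × band
  grid and the integrative demographics/nodule/composite sets, on the full
  cohort (10-fold) and the 8–20 mm subset (5-fold); AUCs are compared with
  the DeLong test.
- **Importance.** Permutation importance and exact Shapley values (closed
  form for linear models, full 2^p enumeration otherwise) across logistic
  regression, linear SVM, and an MLP; the six score columns are min-max
  normalized and averaged into one ranking.
- **Synthetic ground truth.** Nodule/vessel phantoms with analytically known
  band metrics and a cohort simulator matching published group moments make
  every stage testable without any data download.

See `docs/methods.md` for the model details and every numerical choice.

## Worked example

```python
import numpy as np
from vascband import (
    make_nodule_phantom, grow_vessel_tree, rasterize_tubes, extract_features,
    simulate_logit_cohort, run_model_families, odds_change_percent,
)

# a 10 mm nodule with 3 arteries near the surface and veins appearing
# at controlled band distances (1 within 5 mm, 2 within 10, 4 within 15)
nodule = make_nodule_phantom(10.0, spacing=(0.5, 0.5, 0.5), margin_mm=21.0)
arteries, truth = grow_vessel_tree(nodule, "artery", n_branches=3,
                                   tortuosity_amp=0.5, seed=7)
veins, _ = grow_vessel_tree(nodule, "vein", band_targets={5: 1, 10: 2, 15: 4},
                            seed=8, avoid=arteries)
features = extract_features(nodule, rasterize_tubes(arteries, nodule),
                            rasterize_tubes(veins, nodule))
print(features[["artery5_count", "artery5_volume", "artery5_tortuosity",
                "vein15_count"]].round(4).to_string())
```

```
artery5_count         3.0000
artery5_volume        0.0322
artery5_tortuosity    1.0099
vein15_count          4.0000
```

All three arteries intersect the 5 mm band (the generated truth says 3
branches, 0.0335 cm³, mean tortuosity 1.0086 — the extraction recovers the
count exactly, the volume within 4%, and the tortuosity within 0.002), and
the vein counts follow the requested band targets.

```python
# a simulated cohort in which only artery5_count carries signal
cohort = simulate_logit_cohort(2000, {"artery5_count": 1.0}, seed=1)
reports, delong = run_model_families(cohort, "all", seed=1,
                                     families=["Artery5", "Vein5", "Vessel5"])
for name, r in reports.items():
    print(f"{name}: selected={r.selected} AUC={r.auc:.3f} "
          f"(95% CI {r.auc_ci[0]:.3f}-{r.auc_ci[1]:.3f})")
print("age -0.12/yr -> odds decrease:", round(odds_change_percent(-0.12), 1), "%")
```

```
Artery5: selected=['artery5_count', 'artery5_tortuosity'] AUC=0.706 (95% CI 0.684-0.729)
Vein5: selected=['vein5_count', 'vein5_volume', 'vein5_tortuosity'] AUC=0.564 (95% CI 0.538-0.589)
Vessel5: selected=['artery5_count', 'artery5_tortuosity'] AUC=0.706 (95% CI 0.684-0.729)
age -0.12/yr -> odds decrease: 11.3 %
```

The artery models pick up the planted `artery5_count` effect and clearly
beat the vein model (DeLong p < 10⁻⁴ on this cohort); the Vessel5 model,
which may choose from both compartments, converges on the artery features.
The last line is the analytic odds-change reading of a univariate logistic
slope: a coefficient of −0.12 per year of age is a 1 − e^(−0.12) = 11.3%
decrease in the odds of malignancy per additional year.

## Command line

```sh
vascband phantom --diameter 12 --branches 6 --seed 7 --out phantom_dir/
vascband extract --nodule n.nii.gz --artery a.nii.gz --vein v.nii.gz --out features.csv
vascband simulate-cohort --n-malignant 69 --n-benign 79 --seed 1 --out cohort.csv
vascband fit --cohort-csv cohort.csv --cohort all --seed 1 --out models.csv
vascband importance --cohort-csv cohort.csv --model macrovasc --out importance.csv
vascband run-all --seed 1 --out bundle/
```

`run-all` produces the complete seeded bundle: the simulated cohort, the
univariate table, model reports and DeLong matrices for both cohorts, the
pooled out-of-fold predictions (ROC data), and both importance tables.
Identical config + seed reproduces every file byte for byte.

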