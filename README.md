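# bruiseage

Forensic age assessment of human-inflicted bruises in slaughter pigs, and the
statistical question that comes with it: when a pig carries multiple bruises
inflicted at (nearly) the same moment, do two sampled lesions actually tell
the same histological story?

Veterinary pathologists grade inflammatory-cell infiltration on
semi-quantitative scales — neutrophils and macrophages 0–3 in the densest
40× field, muscle-fiber necrosis 0–3 by area — and convert two of those
grades to a calibrated age interval in hours: neutrophils in the subcutis
(score 1 → 1–3 h, 2 → 1–8 h, 3 → 4–10 h) and macrophages in the muscle
(1 → 2–9 h, 2 → 2–10 h, 3 → 4–10 h). Overlapping intervals are intersected
to the narrowest interval consistent with both; disjoint intervals defer to
the higher score; two zero scores are inconclusive. The combined interval is
binned into four categories: inconclusive, <4 h, >4 h, or overlapping 4 h.

Agreement between two bruises *a* and *b* on the same pig is summarized by
unweighted Cohen's kappa on the paired calls,

    κ = (p_o − p_e) / (1 − p_e),      p_e = Σ_i r_i c_i / n²,

with the large-sample standard error
`se = sqrt(p_o (1 − p_o) / (n (1 − p_e)²))` for the 95 % CI, a one-sided
test of κ = 0 against the null-variance standard error, and Landis–Koch
verbal bands (slight / fair / moderate / substantial / almost perfect) gated
on significance.

The package provides:

- `bruiseage.datamodel` — validated per-bruise score records with a fixed
  CSV schema (booleans as `present`/`absent`, ordinal scores 0–3).
- `bruiseage.age_estimation` — interval mapping, combination rules, and the
  exhaustive 16-row score-pair table.
- `bruiseage.agreement` — `PairwiseAgreement` model / `AgreementResults`
  (statsmodels-style `fit()` + `summary()`), kappa implemented from the
  formulas above for all 14 histological variables and the age category.
- `bruiseage.synthetic_data` — seeded cohort generator (shared latent
  infliction time per pig, noisy ordinal score emission), consensus-probability
  Monte Carlo, and noise-to-kappa calibration.
- `bruiseage.cli` — `bruiseage simulate | estimate | agree | report`.

## Worked example

```python
from bruiseage.datasets import load_age_crosstab
from bruiseage.agreement import cohen_kappa, percent_agreement

tab = load_age_crosstab()        # 81 pigs, rows = bruise b, cols = bruise a
res = cohen_kappa(tab)
print(f"kappa = {res.kappa:.2f}, 95% CI [{res.ci_lower:.2f}, {res.ci_upper:.2f}], "
      f"label = {res.label.value}")
print(f"same category in {100 * percent_agreement(tab):.0f} % of pigs")
```

prints

```
kappa = 0.24, 95% CI [0.08, 0.40], label = fair
same category in 48 % of pigs
```

i.e. only a *fair*, though significant, agreement: in about half of the pigs
the two bruises land in different age categories even though they were
inflicted near-simultaneously — two lesions are a thin basis for a common
age call. The simulator quantifies the design consequence:

```python
from bruiseage import SimulationConfig, calibrate_noise_to_kappa, consensus_probability

cfg = SimulationConfig(n_pigs=81, seed=1)
noise = calibrate_noise_to_kappa(cfg, target_kappa=0.24, reps=20)
for k in (2, 4):
    p, se = consensus_probability(SimulationConfig(emission_noise=noise, seed=1), k=k, reps=10_000)
    print(f"P(all {k} bruises agree) = {p:.2f} ± {se:.3f}")
```

```
P(all 2 bruises agree) = 0.53 ± 0.005
P(all 4 bruises agree) = 0.27 ± 0.004
```

From the shell, the same pipeline:

```
bruiseage simulate --n-pigs 81 --noise 0.34 --seed 1 --out cohort.csv
bruiseage report --input cohort.csv --out-prefix run
```

writes per-bruise ages (`run_ages.csv`), the per-variable kappa table
(`run_kappa.csv`), the 4×4 age cross-tabulation and its marginal counts with
percentages, plus a `run.manifest.txt` echoing the configuration.

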