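# Methods

## Age estimation as interval algebra

Each bruise carries two calibrated ordinal scores: neutrophil infiltration
in the subcutis and macrophage infiltration in the muscle, each 0–3 by cell
count in the densest 40× field. A nonzero score maps to a closed integer
interval of hours post-infliction (neutrophils: 1 → [1, 3], 2 → [1, 8],
3 → [4, 10]; macrophages: 1 → [2, 9], 2 → [2, 10], 3 → [4, 10]); a zero
score carries no age information. Combination rules, applied in order:

1. both scores zero → inconclusive, no interval;
2. one score zero → the other cell type's interval stands alone;
3. overlapping intervals → their set intersection. "Narrowest interval
   consistent with both pieces of evidence" is exactly the intersection of
   the two closed intervals, which is why we implement it that way rather
   than, say, the interval between midpoints;
4. disjoint intervals → the interval of the strictly higher score.

With this calibration the only disjoint pair is neutrophil 1 ([1, 3]) vs
macrophage 3 ([4, 10]); a score *tie* with disjoint intervals is therefore
unreachable, and since no defensible rule exists for it, `combine_intervals`
raises a `ValueError` rather than guessing. Intervals stay integer-hour
exactly as calibrated; no continuous-time interpolation is attempted.

Categorization: upper bound < 4 → `<4 h`; lower bound ≥ 4 → `>4 h`;
otherwise `overlapping 4 h`; no interval → inconclusive. An interval with
upper bound exactly 4 never arises from the calibrated table, so the
boundary convention (lower bound 4 counts as `>4 h`) only has to be
consistent, not empirically adjudicated; we document it rather than claim it
is the only possible reading.

All 16 score pairs are enumerated by `full_combination_table()`, which the
tests treat as the oracle surface: narrowing, containment, the uniqueness of
the inconclusive row and of the dominant-score pair are asserted by
enumeration, and the whole table is checked against an independent
brute-force computation that enumerates consistent integer hours.

## Cohen's kappa with asymptotic inference

For a square r×r table of paired calls (rows: bruise b; columns: bruise a),
with cell counts `x_ij`, marginal counts `r_i`, `c_j` and total `n`:

- observed agreement `p_o = Σ_i x_ii / n`; chance agreement
  `p_e = Σ_i r_i c_i / n²`; `κ = (p_o − p_e) / (1 − p_e)`;
- CI standard error `se = sqrt(p_o (1 − p_o) / (n (1 − p_e)²))`, normal
  quantile at the requested confidence (default 95 %);
- null standard error
  `se₀ = sqrt(p_e + p_e² − Σ_i r_i c_i (r_i + c_i) / n³) / ((1 − p_e) √n)`,
  `z = κ / se₀`, one-sided upper-tail p-value.

Kappa is unweighted even for the ordinal scores: each variable is compared
as nominal categories, which is the convention of the standard
epidemiological implementations of this test and keeps one statistic per
variable. Weighted and multi-rater variants are out of scope.

Degenerate inputs are flagged, not raised, because real cohorts contain
constant variables: if all mass sits in one row-and-column pair (`p_e = 1`)
the result carries κ = 0, NaN inference fields and the label `degenerate`;
if exactly one rater is constant, `p_e < 1` but the null variance is
identically zero and κ is identically 0, so the z and p fields are NaN and
the label again `degenerate`. Interpretation labels otherwise follow
Landis–Koch bands of the point estimate — (0, 0.2] slight, (0.2, 0.4] fair,
(0.4, 0.6] moderate, (0.6, 0.8] substantial, (0.8, 1] almost perfect — but
only when the one-sided p is below alpha (default 0.05) and the CI excludes
zero; otherwise `not significant`. One-sided p-values can differ by a
factor of two from two-sided conventions in other software; labels and CIs
are unaffected.

Per-variable n is computed from the pigs actually contributing both named
bruises; pigs missing either label are listed in `exclusions`, never
silently dropped.

## The synthetic cohort generator

The generator encodes the sampling design it is meant to probe, not the
biology of inflammation. Its assumptions:

- **One latent time per pig.** All bruises on a pig share a single
  infliction-to-slaughter time `t`, reflecting the premise that multiple
  uniform bruises are inflicted within minutes of each other.
- **Timing.** `t` is the sum of a transport and a lairage component, each a
  normal truncated at zero, with defaults (2.13 h mean, 3.33 h SD) and
  (3.03 h mean, 3.44 h SD) — the only quantitative timing information
  available for this population. Both are overridable via `TimeModel`.
- **Score emission.** The noiseless score at time `t` is the lowest
  calibrated score whose interval contains `t`; before the earliest interval
  opens the score is 0, after 10 h it is 3. Ties at interval boundaries
  break toward the lower score — a deterministic, testable convention chosen
  because nothing in the calibration dictates one. (For macrophages no
  calibrated interval covers 1 ≤ t < 2 h; the latent score there is 0, the
  pre-infiltration reading.) Noise spreads emission geometrically:
  `P(s|t) ∝ noise^|s − s*(t)|` over s ∈ {0..3}, `noise ∈ [0, 1)`. This
  kernel is a stand-in: no distributional information about same-age
  score variability exists beyond "substantial", so the single dispersion
  parameter is the honest minimum. Default noise 0.3 gives moderate
  inter-bruise variability; `calibrate_noise_to_kappa` exists precisely so
  demonstrations can match an observed agreement level instead of trusting
  the default.
- **Ancillary variables** (hemorrhage, hyper-leukocytosis, dermal
  leukocytes, necrosis grade, leukocyte localization) follow simple
  threshold rules in `t` — hemorrhage immediate, hyper-leukocytosis in the
  1–8 h window, necrosis stepping up at 1/4/8 h, localization interstitial
  until 8 h then intramuscular — with a flip probability of
  `0.25 × noise` per boolean. They exist so the full per-variable agreement
  report has data in every row; they never feed the age call, and no claim
  is made that their kinetics are realistic.

Consequences used by the tests: at noise 0 the channel is deterministic, so
every bruise on a pig gets the same category, percent agreement is 1 and
every kappa is either exactly 1 or degenerate; kappa decreases as noise
grows; and the marginal category distribution converges to the analytic
marginal obtained by numerically integrating the emission model over the
time density (computed by grid convolution of the two truncated normals).

What passing these tests does **not** show about real data: real bruises
need not share one exact time, real score variability is not a symmetric
geometric kernel, ancillary variables have richer kinetics, and the
calibrated score→interval table itself is taken as given, not re-derived.

## Numerical and design choices

- `calibrate_noise_to_kappa` bisects the empirical noise→kappa curve on
  [0, 0.95], averaging 20 simulated cohorts per evaluation, after verifying
  the curve actually decreases over the bracket; unreachable targets raise
  with the achievable range. Tolerance 0.01 on the mean kappa; the MC spread
  of kappa at n = 81 (SD ≈ 0.08) dominates any bisection tolerance.
- Monte-Carlo estimates (`consensus_probability`) carry binomial standard
  errors; simulation sizes in the tests (500-pig cohorts for the noise
  grid, 10 000 reps for consensus, 10 000 pigs for marginal recovery) were
  chosen so 3-SE bands are decisive for the properties asserted.
- Display rounding: kappa and CI bounds to 2 decimals, p to 4, marginal
  percentages half-up to integers. Internal values are never rounded.
- Determinism: every stochastic entry point takes a seed
  (`SimulationConfig.seed`, CLI `--seed`); identical config yields
  byte-identical CSV output.

## Limitations

- The score→interval calibration covers 1–10 h only; bruises older than
  10 h saturate at score 3 and are indistinguishable beyond `>4 h`.
- The agreement analysis is strictly pairwise (two named bruises); k-bruise
  consensus is addressed by simulation, not by a multi-rater statistic.
- p-values use the asymptotic normal null; at n = 81 with sparse categories
  the CI (which drives the labels) is the more trustworthy quantity.
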