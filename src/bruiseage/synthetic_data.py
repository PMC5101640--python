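"""Synthetic cohorts of pigs with near-simultaneous bruises.

The generator encodes the study design it emulates: every bruise on a pig is
inflicted at one shared latent time ``t`` hours before slaughter (bruises on
a pig are assumed near-simultaneous), ``t`` being the sum of a transport and
a lairage component, each a normal truncated at zero (defaults: transport
2.13 h mean, 3.33 h SD; lairage 3.03 h mean, 3.44 h SD).

Scores are emitted per bruise from a noisy ordinal channel around the
noiseless score implied by the calibrated score->interval table: the latent
score at time ``t`` is the lowest score whose calibrated interval contains
``t`` (score 0 before the earliest interval opens, score 3 after the last
one closes), and emission spreads geometrically to neighbouring scores,

    P(s | t) ∝ noise**|s - s*(t)|,   s in {0, 1, 2, 3},  noise in [0, 1),

so ``noise = 0`` is a deterministic channel and larger noise means more
inter-bruise variability at fixed age.  Ancillary variables (hemorrhage,
hyper-leukocytosis, necrosis, leukocyte localization) follow simple
documented threshold rules in ``t`` with a noise-proportional flip
probability; they feed only the agreement report, never the age call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .age_estimation import (
    CATEGORY_ORDER,
    AgeCategory,
    CellType,
    combine_intervals,
    score_to_interval,
)
from .agreement import ContingencyTable, cohen_kappa
from .datamodel import BruiseHistology, LeukocyteLocalization, PigRecord

__all__ = [
    "TimeModel",
    "AncillaryModel",
    "SimulationConfig",
    "GroundTruth",
    "default_emission",
    "latent_score",
    "generate_cohort",
    "consensus_probability",
    "calibrate_noise_to_kappa",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """The target agreement level is outside the reachable range."""


@dataclass(frozen=True)
class TimeModel:
    """Infliction-to-slaughter time: transport + lairage, each a normal
    truncated at 0 (hours)."""

    transport_mean_h: float = 2.13
    transport_sd_h: float = 3.33
    lairage_mean_h: float = 3.03
    lairage_sd_h: float = 3.44

    def _component(self, mean: float, sd: float):
        a = (0.0 - mean) / sd
        return stats.truncnorm(a, np.inf, loc=mean, scale=sd)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        transport = self._component(self.transport_mean_h, self.transport_sd_h)
        lairage = self._component(self.lairage_mean_h, self.lairage_sd_h)
        return transport.rvs(size=size, random_state=rng) + lairage.rvs(
            size=size, random_state=rng
        )


@dataclass(frozen=True)
class AncillaryModel:
    """Threshold rules in t for the descriptive variables, with a flip
    probability of ``flip_scale * emission_noise`` per boolean.

    Hemorrhage is present from the moment of infliction; hyper-leukocytosis
    (capillary pavement) is an early sign, present in the 1-8 h window;
    dermal leukocyte infiltration appears from 1 h; necrosis grade steps up
    at 1, 4 and 8 h; muscle leukocytes sit interstitially up to 8 h and move
    into necrotic fibers later.
    """

    flip_scale: float = 0.25
    hyperleukocytosis_window_h: tuple[float, float] = (1.0, 8.0)
    dermis_leukocytes_onset_h: float = 1.0
    necrosis_steps_h: tuple[float, float, float] = (1.0, 4.0, 8.0)
    intramuscular_onset_h: float = 8.0

    def necrosis_grade(self, t: float) -> int:
        return int(np.searchsorted(np.asarray(self.necrosis_steps_h), t, side="right"))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort design: sizes, timing, emission noise, ancillary rules, seed."""

    n_pigs: int = 81
    bruises_per_pig: int = 2
    time_model: TimeModel = field(default_factory=TimeModel)
    emission_noise: float = 0.3
    ancillary_model: AncillaryModel = field(default_factory=AncillaryModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pigs < 1:
            raise ValueError("n_pigs must be >= 1")
        if self.bruises_per_pig < 1:
            raise ValueError("bruises_per_pig must be >= 1")
        if not 0.0 <= self.emission_noise < 1.0:
            raise ValueError(f"emission_noise must be in [0, 1), got {self.emission_noise}")


@dataclass
class GroundTruth:
    """Latent state of a simulated cohort, kept beside (never inside) the
    exported histology CSV."""

    true_time_h: dict[str, float]
    latent_category: dict[str, AgeCategory]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pig_id": list(self.true_time_h),
                "true_time_h": list(self.true_time_h.values()),
                "true_category": [self.latent_category[p].value for p in self.true_time_h],
            }
        )


def latent_score(cell_type: CellType, t: float) -> int:
    """Noiseless score at time t: the lowest score whose calibrated interval
    contains t; 0 before the earliest interval opens, 3 after 10 h."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    intervals = {s: score_to_interval(cell_type, s) for s in (1, 2, 3)}
    containing = [s for s, iv in intervals.items() if iv.lower_h <= t <= iv.upper_h]
    if containing:
        return min(containing)
    if t < min(iv.lower_h for iv in intervals.values()):
        return 0
    return 3


def default_emission(t: float, noise: float = 0.0) -> dict[CellType, np.ndarray]:
    """Score-probability vectors over {0..3} for both cell types at time t."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if not 0.0 <= noise < 1.0:
        raise ValueError(f"noise must be in [0, 1), got {noise}")
    out = {}
    for ct in CellType:
        star = latent_score(ct, t)
        weights = np.array([noise ** abs(s - star) for s in range(4)], dtype=float)
        out[ct] = weights / weights.sum()
    return out


# --- fast vectorized internals (no record objects) -------------------------

def _latent_scores_vec(cell_type: CellType, t: np.ndarray) -> np.ndarray:
    # thresholds derived once from the calibrated table
    edges = _latent_edges(cell_type)
    scores = np.zeros(t.shape, dtype=np.int64)
    for score, (lo, hi) in edges.items():
        scores[(t >= lo) & (t <= hi)] = score
    scores[t > max(hi for _, hi in edges.values())] = 3
    return scores


def _latent_edges(cell_type: CellType) -> dict[int, tuple[float, float]]:
    """Per-score time bands implied by lowest-containing-interval semantics."""
    intervals = {s: score_to_interval(cell_type, s) for s in (1, 2, 3)}
    edges: dict[int, tuple[float, float]] = {}
    prev_hi = -np.inf
    for s in (1, 2, 3):
        iv = intervals[s]
        lo = max(iv.lower_h, np.nextafter(prev_hi, np.inf)) if prev_hi >= iv.lower_h else iv.lower_h
        if lo <= iv.upper_h:
            edges[s] = (lo, iv.upper_h)
            prev_hi = iv.upper_h
    return edges


def _emit_scores(rng: np.random.Generator, star: np.ndarray, noise: float) -> np.ndarray:
    """Sample scores around latent scores with the geometric leak kernel."""
    if noise == 0.0:
        return star.copy()
    kernel = noise ** np.abs(np.arange(4)[None, :] - np.arange(4)[:, None])  # (star, s)
    probs = kernel / kernel.sum(axis=1, keepdims=True)
    u = rng.random(star.shape)
    cum = np.cumsum(probs[star], axis=-1)
    return (u[..., None] > cum).sum(axis=-1)


_CATEGORY_CODE = np.empty((4, 4), dtype=np.int64)
for _n in range(4):
    for _m in range(4):
        _CATEGORY_CODE[_n, _m] = CATEGORY_ORDER.index(combine_intervals(_n, _m).category)


def _category_codes(n_scores: np.ndarray, m_scores: np.ndarray) -> np.ndarray:
    """Age-category index (into CATEGORY_ORDER) for arrays of score pairs."""
    return _CATEGORY_CODE[n_scores, m_scores]


def _flip(rng: np.random.Generator, base: np.ndarray, p_flip: float) -> np.ndarray:
    if p_flip <= 0.0:
        return base.copy()
    return base ^ (rng.random(base.shape) < p_flip)


def generate_cohort(config: SimulationConfig) -> tuple[list[PigRecord], GroundTruth]:
    """Simulate a full cohort; output always passes datamodel validation.

    All bruises on a pig share one drawn time; scores and ancillary
    variables are drawn independently per bruise.  Identical config (seed
    included) yields a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    k = config.bruises_per_pig
    noise = config.emission_noise
    anc = config.ancillary_model
    p_flip = anc.flip_scale * noise

    times = config.time_model.sample(rng, config.n_pigs)
    star_n = _latent_scores_vec(CellType.NEUTROPHIL_SUBCUTIS, times)
    star_m = _latent_scores_vec(CellType.MACROPHAGE_MUSCLE, times)

    width = len(str(config.n_pigs))
    labels = [chr(ord("a") + i) if k <= 26 else f"b{i+1}" for i in range(k)]

    records: list[PigRecord] = []
    true_time: dict[str, float] = {}
    latent_cat: dict[str, AgeCategory] = {}
    lo_w, hi_w = anc.hyperleukocytosis_window_h

    for i in range(config.n_pigs):
        pig_id = f"P{i+1:0{width}d}"
        t = float(times[i])
        true_time[pig_id] = t
        latent_cat[pig_id] = CATEGORY_ORDER[int(_CATEGORY_CODE[star_n[i], star_m[i]])]

        # per-bruise draws, shapes (k,)
        sn = _emit_scores(rng, np.full(k, star_n[i]), noise)
        sm = _emit_scores(rng, np.full(k, star_m[i]), noise)
        mn = _emit_scores(rng, np.full(k, star_n[i]), noise)  # muscle neutrophils
        sub_m = _emit_scores(rng, np.full(k, star_m[i]), noise)  # subcutis macrophages
        necro = _emit_scores(rng, np.full(k, anc.necrosis_grade(t)), noise)

        hem = _flip(rng, np.ones(k, dtype=bool), p_flip)
        hem_s = _flip(rng, np.ones(k, dtype=bool), p_flip)
        hem_m = _flip(rng, np.ones(k, dtype=bool), p_flip)
        hl_base = np.full(k, lo_w <= t <= hi_w)
        hl_d = _flip(rng, hl_base, p_flip)
        hl_s = _flip(rng, hl_base, p_flip)
        hl_m = _flip(rng, hl_base, p_flip)
        leuk_d = _flip(rng, np.full(k, t >= anc.dermis_leukocytes_onset_h), p_flip)
        inter_base = np.full(k, t <= anc.intramuscular_onset_h)
        inter = _flip(rng, inter_base, p_flip)

        bruises = []
        for j in range(k):
            if mn[j] == 0 and sm[j] == 0:
                loc = LeukocyteLocalization.NOT_APPLICABLE
            elif inter[j]:
                loc = LeukocyteLocalization.INTERSTITIAL
            else:
                loc = LeukocyteLocalization.INTRAMUSCULAR
            bruises.append(
                BruiseHistology(
                    pig_id=pig_id,
                    bruise_label=labels[j],
                    dermis_hemorrhage=bool(hem[j]),
                    dermis_hyperleukocytosis=bool(hl_d[j]),
                    dermis_leukocytes=bool(leuk_d[j]),
                    subcutis_hemorrhage=bool(hem_s[j]),
                    subcutis_hyperleukocytosis=bool(hl_s[j]),
                    subcutis_neutrophils=int(sn[j]),
                    subcutis_macrophages=int(sub_m[j]),
                    muscle_hemorrhage=bool(hem_m[j]),
                    muscle_hyperleukocytosis=bool(hl_m[j]),
                    muscle_necrosis=int(necro[j]),
                    muscle_neutrophils=int(mn[j]),
                    muscle_macrophages=int(sm[j]),
                    muscle_leukocyte_localization=loc,
                )
            )
        records.append(PigRecord(pig_id=pig_id, bruises=bruises))
    return records, GroundTruth(true_time_h=true_time, latent_category=latent_cat)


def _simulate_category_pairs(
    rng: np.random.Generator, config: SimulationConfig, k: int
) -> np.ndarray:
    """Fast path: (n_pigs, k) array of age-category codes, no record objects."""
    times = config.time_model.sample(rng, config.n_pigs)
    star_n = np.repeat(
        _latent_scores_vec(CellType.NEUTROPHIL_SUBCUTIS, times)[:, None], k, axis=1
    )
    star_m = np.repeat(
        _latent_scores_vec(CellType.MACROPHAGE_MUSCLE, times)[:, None], k, axis=1
    )
    sn = _emit_scores(rng, star_n, config.emission_noise)
    sm = _emit_scores(rng, star_m, config.emission_noise)
    return _category_codes(sn, sm)


def consensus_probability(
    config: SimulationConfig, k: int, reps: int
) -> tuple[float, float]:
    """Monte-Carlo probability that all k bruises on a pig get the same age
    category, with its standard error.

    One rep is one pig: a shared time, k independent score emissions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if reps < 100:
        raise ValueError("reps must be >= 100 for a usable standard error")
    rng = np.random.default_rng(config.seed)
    cfg = replace(config, n_pigs=reps)
    codes = _simulate_category_pairs(rng, cfg, k)
    same = (codes == codes[:, [0]]).all(axis=1)
    p = float(same.mean())
    se = math.sqrt(p * (1.0 - p) / reps)
    return p, se


def _mean_kappa(
    rng: np.random.Generator, config: SimulationConfig, noise: float, reps: int
) -> float:
    """Mean age-category kappa over simulated 2-bruise cohorts; degenerate
    replicates (single occupied category) count as kappa 1 at noise 0 and
    are skipped otherwise."""
    cfg = replace(config, emission_noise=noise, bruises_per_pig=2)
    values = []
    for _ in range(reps):
        codes = _simulate_category_pairs(rng, cfg, 2)
        counts = np.zeros((4, 4), dtype=np.int64)
        np.add.at(counts, (codes[:, 1], codes[:, 0]), 1)
        res = cohen_kappa(ContingencyTable(categories=CATEGORY_ORDER, counts=counts))
        if res.degenerate:
            if noise == 0.0:
                values.append(1.0)
        else:
            values.append(res.kappa)
    if not values:
        raise CalibrationError(f"all {reps} replicates degenerate at noise {noise}")
    return float(np.mean(values))


def calibrate_noise_to_kappa(
    config: SimulationConfig,
    target_kappa: float,
    reps: int = 20,
    bracket: tuple[float, float] = (0.0, 0.95),
    tol: float = 0.01,
    max_iter: int = 20,
) -> float:
    """Find the emission noise whose simulated mean kappa matches a target.

    Bisection on the empirically decreasing noise -> kappa curve; the
    decrease over the bracket is verified before searching, and an
    unreachable target raises :class:`CalibrationError` reporting the
    achievable range.
    """
    if not 0.0 < target_kappa < 1.0:
        raise ValueError(f"target_kappa must be in (0, 1), got {target_kappa}")
    rng = np.random.default_rng(config.seed)
    lo, hi = bracket
    k_lo = _mean_kappa(rng, config, lo, reps)
    k_hi = _mean_kappa(rng, config, hi, reps)
    if k_lo <= k_hi:
        raise CalibrationError(
            f"kappa is not decreasing over the bracket: kappa({lo})={k_lo:.3f}, "
            f"kappa({hi})={k_hi:.3f}"
        )
    if not (k_hi <= target_kappa <= k_lo):
        raise CalibrationError(
            f"target kappa {target_kappa} outside the achievable range "
            f"[{k_hi:.3f}, {k_lo:.3f}] for noise in [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        k_mid = _mean_kappa(rng, config, mid, reps)
        if abs(k_mid - target_kappa) < tol:
            return mid
        if k_mid > target_kappa:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
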