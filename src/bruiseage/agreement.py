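"""Inter-lesion agreement: Cohen's kappa with asymptotic inference.

Paired categorical calls (bruise *a* vs bruise *b* on the same pig) are
cross-tabulated into a square contingency table and summarized by unweighted
Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

where ``p_o`` is the observed proportion of agreement (trace / n) and ``p_e``
the chance agreement implied by the marginals, ``p_e = sum_i r_i c_i / n^2``.
The 95 % confidence interval uses the large-sample standard error

    se = sqrt( p_o (1 - p_o) / ( n (1 - p_e)^2 ) ),

and the one-sided test of kappa = 0 uses the null-hypothesis standard error

    se_0 = sqrt( p_e + p_e^2 - sum_i r_i c_i (r_i + c_i) / n^3 )
           / ( (1 - p_e) sqrt(n) ),

with z = kappa / se_0 and an upper-tail normal p-value.  Point estimates are
labelled on the Landis-Koch scale (slight / fair / moderate / substantial /
almost perfect) only when significant; tables whose marginals concentrate all
mass in a single category (p_e = 1) are flagged degenerate rather than
raising, since real cohorts produce constant variables.

:class:`PairwiseAgreement` is the model object: build it from
:class:`~bruiseage.datamodel.PigRecord` collections, a DataFrame or a CSV,
call :meth:`~PairwiseAgreement.fit`, and read the per-variable kappa table,
the age-category cross-tabulation and marginals off the returned
:class:`AgreementResults`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import datamodel
from .age_estimation import CATEGORY_DISPLAY, CATEGORY_ORDER, estimate_age
from .datamodel import LeukocyteLocalization, PigRecord

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "AgreementLabel",
    "crosstab",
    "percent_agreement",
    "cohen_kappa",
    "interpret",
    "agreement_report",
    "PairwiseAgreement",
    "AgreementResults",
    "VARIABLES",
]


class AgreementLabel(enum.Enum):
    NOT_SIGNIFICANT = "not_significant"
    SLIGHT = "slight"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    ALMOST_PERFECT = "almost_perfect"
    DEGENERATE = "degenerate"


_LABEL_DISPLAY = {
    AgreementLabel.NOT_SIGNIFICANT: "Not significant",
    AgreementLabel.SLIGHT: "Slight",
    AgreementLabel.FAIR: "Fair",
    AgreementLabel.MODERATE: "Moderate",
    AgreementLabel.SUBSTANTIAL: "Substantial",
    AgreementLabel.ALMOST_PERFECT: "Almost perfect",
    AgreementLabel.DEGENERATE: "Degenerate",
}


@dataclass(frozen=True)
class ContingencyTable:
    """Square r x r cross-tabulation of paired calls.

    Rows index bruise *b*'s call, columns bruise *a*'s call, both over the
    same ordered category list.
    """

    categories: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "categories", tuple(self.categories))
        r = len(self.categories)
        if counts.shape != (r, r):
            raise ValueError(f"counts must be {r}x{r}, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        """Marginal counts of bruise b's calls."""
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        """Marginal counts of bruise a's calls."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        labels = [str(c) for c in self.categories]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa point estimate with asymptotic inference."""

    kappa: float
    p_observed: float
    p_expected: float
    se_estimate: float
    se_null: float
    ci_lower: float
    ci_upper: float
    z: float
    p_value: float
    label: AgreementLabel
    n: int
    confidence: float = 0.95

    @property
    def degenerate(self) -> bool:
        return self.label is AgreementLabel.DEGENERATE


def crosstab(pairs: Iterable[tuple], categories: Sequence) -> ContingencyTable:
    """Cross-tabulate (call_a, call_b) pairs over a fixed category list.

    ``counts[i, j]`` counts pigs with call_b = categories[i] and
    call_a = categories[j].
    """
    categories = tuple(categories)
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    n = 0
    for call_a, call_b in pairs:
        if call_a not in index:
            raise ValueError(f"unknown category label for bruise a: {call_a!r}")
        if call_b not in index:
            raise ValueError(f"unknown category label for bruise b: {call_b!r}")
        counts[index[call_b], index[call_a]] += 1
        n += 1
    if n == 0:
        raise ValueError("empty input: at least one pair is required")
    return ContingencyTable(categories=categories, counts=counts)


def percent_agreement(table: ContingencyTable) -> float:
    """Observed proportion of agreement: trace / n."""
    if table.n == 0:
        raise ValueError("empty table: n must be positive")
    return float(np.trace(table.counts)) / table.n


def cohen_kappa(table: ContingencyTable, confidence: float = 0.95) -> KappaResult:
    """Unweighted Cohen's kappa with asymptotic CI and one-sided test.

    A degenerate table (all mass in one marginal category on both axes,
    ``p_e = 1``) yields kappa 0 with label ``degenerate`` and NaN inference
    fields instead of raising.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table: n must be positive")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    counts = table.counts.astype(float)
    p_o = float(np.trace(counts)) / n
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    p_e = float((rows * cols).sum()) / n**2

    if p_e >= 1.0 - 1e-12:
        return KappaResult(
            kappa=0.0, p_observed=p_o, p_expected=p_e,
            se_estimate=float("nan"), se_null=float("nan"),
            ci_lower=float("nan"), ci_upper=float("nan"),
            z=float("nan"), p_value=float("nan"),
            label=AgreementLabel.DEGENERATE, n=n, confidence=confidence,
        )

    kappa = (p_o - p_e) / (1.0 - p_e)
    se_estimate = float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    null_var = max(p_e + p_e**2 - float((rows * cols * (rows + cols)).sum()) / n**3, 0.0)
    se_null = float(np.sqrt(null_var) / ((1.0 - p_e) * np.sqrt(n)))
    zq = stats.norm.ppf(0.5 + confidence / 2.0)
    ci_lower = kappa - zq * se_estimate
    ci_upper = kappa + zq * se_estimate
    if se_null == 0.0:
        # one rating constant: kappa is identically 0 and the null is untestable
        z, p_value = float("nan"), float("nan")
    else:
        z = kappa / se_null
        p_value = float(stats.norm.sf(z))

    result = KappaResult(
        kappa=float(kappa), p_observed=p_o, p_expected=p_e,
        se_estimate=se_estimate, se_null=se_null,
        ci_lower=float(ci_lower), ci_upper=float(ci_upper),
        z=float(z), p_value=p_value,
        label=AgreementLabel.NOT_SIGNIFICANT, n=n, confidence=confidence,
    )
    return KappaResult(**{**result.__dict__, "label": interpret(result)})


def interpret(result: KappaResult, alpha: float = 0.05) -> AgreementLabel:
    """Landis-Koch verbal band of a kappa estimate, gated on significance.

    Degenerate tables stay degenerate; a non-significant test (one-sided
    p >= alpha, or a CI containing 0) is labelled ``not_significant``
    regardless of the point estimate.
    """
    if result.label is AgreementLabel.DEGENERATE or np.isnan(result.p_value):
        return AgreementLabel.DEGENERATE
    if result.p_value >= alpha or (result.ci_lower <= 0.0 <= result.ci_upper):
        return AgreementLabel.NOT_SIGNIFICANT
    k = result.kappa
    if k <= 0.20:
        return AgreementLabel.SLIGHT
    if k <= 0.40:
        return AgreementLabel.FAIR
    if k <= 0.60:
        return AgreementLabel.MODERATE
    if k <= 0.80:
        return AgreementLabel.SUBSTANTIAL
    return AgreementLabel.ALMOST_PERFECT


# (display name, tissue layer, extractor) in the report's fixed order
def _loc_is(which: LeukocyteLocalization):
    def extract(b) -> str:
        return "yes" if b.muscle_leukocyte_localization is which else "no"
    return extract


def _bool(name: str):
    def extract(b) -> str:
        return "present" if getattr(b, name) else "absent"
    return extract


def _score(name: str):
    def extract(b) -> str:
        return str(int(getattr(b, name)))
    return extract


VARIABLES: tuple[tuple[str, str, object], ...] = (
    ("Hyper-leukocytosis", "Dermis", _bool("dermis_hyperleukocytosis")),
    ("Leukocytes", "Dermis", _bool("dermis_leukocytes")),
    ("Hemorrhage", "Dermis", _bool("dermis_hemorrhage")),
    ("Neutrophils", "Subcutis", _score("subcutis_neutrophils")),
    ("Hyper-leukocytosis", "Subcutis", _bool("subcutis_hyperleukocytosis")),
    ("Macrophages", "Subcutis", _score("subcutis_macrophages")),
    ("Hemorrhage", "Subcutis", _bool("subcutis_hemorrhage")),
    ("Necrosis", "Muscle", _score("muscle_necrosis")),
    ("Neutrophils", "Muscle", _score("muscle_neutrophils")),
    ("Macrophages", "Muscle", _score("muscle_macrophages")),
    ("Leukocytes in the interstitial space", "Muscle", _loc_is(LeukocyteLocalization.INTERSTITIAL)),
    ("Leukocytes present intramuscularly", "Muscle", _loc_is(LeukocyteLocalization.INTRAMUSCULAR)),
    ("Hyper-leukocytosis", "Muscle", _bool("muscle_hyperleukocytosis")),
    ("Hemorrhage", "Muscle", _bool("muscle_hemorrhage")),
)

_VARIABLE_CATEGORIES: dict[str, tuple] = {
    "present/absent": ("absent", "present"),
    "score": ("0", "1", "2", "3"),
    "yes/no": ("no", "yes"),
}


def _categories_for(name: str) -> tuple:
    if name in ("Neutrophils", "Macrophages", "Necrosis"):
        return _VARIABLE_CATEGORIES["score"]
    if name.startswith("Leukocytes in") or name.startswith("Leukocytes present"):
        return _VARIABLE_CATEGORIES["yes/no"]
    return _VARIABLE_CATEGORIES["present/absent"]


class PairwiseAgreement:
    """Agreement model for two named bruises per pig.

    Parameters
    ----------
    records : iterable of PigRecord
        The cohort.  Pigs missing either label are excluded from every
        cross-tabulation and listed in ``exclusions``.
    pair_labels : (str, str)
        Bruise labels to compare; default ``("a", "b")``.
    """

    def __init__(self, records: Iterable[PigRecord], pair_labels: tuple[str, str] = ("a", "b")):
        self.records = list(records)
        self.pair_labels = tuple(pair_labels)
        if len(self.pair_labels) != 2:
            raise ValueError("pair_labels must name exactly two bruises")
        la, lb = self.pair_labels
        self.exclusions = [r.pig_id for r in self.records
                           if not (r.has_label(la) and r.has_label(lb))]
        self._paired = [r for r in self.records if r.pig_id not in set(self.exclusions)]

    @classmethod
    def from_csv(cls, source: IO[str], pair_labels: tuple[str, str] = ("a", "b")) -> "PairwiseAgreement":
        return cls(datamodel.read_bruise_table(source), pair_labels=pair_labels)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, pair_labels: tuple[str, str] = ("a", "b")) -> "PairwiseAgreement":
        import io

        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        return cls.from_csv(buf, pair_labels=pair_labels)

    @property
    def nobs(self) -> int:
        """Number of pigs contributing a complete pair."""
        return len(self._paired)

    def _pairs(self, extract) -> list[tuple[str, str]]:
        la, lb = self.pair_labels
        return [(extract(r.bruise(la)), extract(r.bruise(lb))) for r in self._paired]

    def age_crosstab(self) -> ContingencyTable:
        """4x4 cross-tabulation of the two bruises' age categories."""
        pairs = self._pairs(lambda b: estimate_age(b).category)
        return crosstab(pairs, CATEGORY_ORDER)

    def fit(self, confidence: float = 0.95, alpha: float = 0.05) -> "AgreementResults":
        """Compute kappa for every histological variable and the age category."""
        if not self._paired:
            raise ValueError("no pig carries both bruises "
                             f"{self.pair_labels[0]!r} and {self.pair_labels[1]!r}")
        rows: list[tuple[str, str, KappaResult]] = []
        for name, layer, extract in VARIABLES:
            table = crosstab(self._pairs(extract), _categories_for(name))
            rows.append((name, layer, cohen_kappa(table, confidence=confidence)))
        age_table = self.age_crosstab()
        age_kappa = cohen_kappa(age_table, confidence=confidence)
        return AgreementResults(
            model=self,
            variable_results=rows,
            age_table=age_table,
            age_kappa=age_kappa,
            confidence=confidence,
            alpha=alpha,
        )


@dataclass
class AgreementResults:
    """Fitted agreement results: per-variable kappas plus the age analysis."""

    model: PairwiseAgreement
    variable_results: list[tuple[str, str, KappaResult]]
    age_table: ContingencyTable
    age_kappa: KappaResult
    confidence: float
    alpha: float
    _frame: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def exclusions(self) -> list[str]:
        return self.model.exclusions

    def kappa_frame(self) -> pd.DataFrame:
        """Per-variable kappa table (display rounding: kappa/CI to 2 dp,
        p to 4 dp), with the 4-way age category as the last row."""
        rows = []
        for name, layer, res in self.variable_results + [
            ("Age category", "Combined", self.age_kappa)
        ]:
            rows.append({
                "tissue_layer": layer,
                "variable": name,
                "n": res.n,
                "kappa": round(res.kappa, 2),
                "ci_lower": round(res.ci_lower, 2) if np.isfinite(res.ci_lower) else np.nan,
                "ci_upper": round(res.ci_upper, 2) if np.isfinite(res.ci_upper) else np.nan,
                "label": _LABEL_DISPLAY[res.label],
                "p_value": round(res.p_value, 4) if np.isfinite(res.p_value) else np.nan,
            })
        return pd.DataFrame(rows)

    def age_marginals(self) -> pd.DataFrame:
        """Counts and half-up-rounded integer percentages of the four age
        categories for each bruise (the row/column sums of the cross-tab)."""
        from .reporting import round_half_up

        tab = self.age_table
        n = tab.n
        rows = []
        for i, cat in enumerate(tab.categories):
            ca = int(tab.col_totals()[i])
            cb = int(tab.row_totals()[i])
            rows.append({
                "age_category": CATEGORY_DISPLAY[cat],
                "bruise_a_count": ca,
                "bruise_a_percent": round_half_up(100.0 * ca / n),
                "bruise_b_count": cb,
                "bruise_b_percent": round_half_up(100.0 * cb / n),
            })
        return pd.DataFrame(rows)

    def age_crosstab_frame(self) -> pd.DataFrame:
        labels = [CATEGORY_DISPLAY[c] for c in self.age_table.categories]
        return pd.DataFrame(self.age_table.counts, index=labels, columns=labels)

    def percent_agreement(self) -> float:
        return percent_agreement(self.age_table)

    def summary(self) -> str:
        """Plain-text summary in the style of a statsmodels results table."""
        lines = []
        lines.append("Pairwise bruise agreement (Cohen's kappa)")
        lines.append("=" * 78)
        lines.append(f"Pigs with both bruises {self.model.pair_labels}: {self.nobs}"
                     f"    excluded: {len(self.exclusions)}")
        lines.append(f"Confidence level: {self.confidence:.0%}    alpha: {self.alpha}")
        lines.append("-" * 78)
        frame = self.kappa_frame()
        lines.append(frame.to_string(index=False))
        lines.append("-" * 78)
        pct = 100.0 * self.percent_agreement()
        lines.append(f"Same age category for both bruises: {pct:.0f} % of pigs")
        lines.append("")
        lines.append("Age-category cross-tabulation (rows: bruise b, columns: bruise a)")
        lines.append(self.age_crosstab_frame().to_string())
        return "\n".join(lines)


def agreement_report(records: Iterable[PigRecord],
                     pair_labels: tuple[str, str] = ("a", "b"),
                     confidence: float = 0.95,
                     alpha: float = 0.05) -> AgreementResults:
    """Convenience wrapper: build :class:`PairwiseAgreement` and fit it."""
    return PairwiseAgreement(records, pair_labels=pair_labels).fit(
        confidence=confidence, alpha=alpha)
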