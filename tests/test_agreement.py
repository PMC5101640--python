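"""Cohen's kappa: cross-tabulation, formulas, inference and labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bruiseage.agreement import (
    AgreementLabel,
    ContingencyTable,
    KappaResult,
    PairwiseAgreement,
    agreement_report,
    cohen_kappa,
    crosstab,
    interpret,
    percent_agreement,
)
from bruiseage.datamodel import PigRecord
from .conftest import make_bruise


def brute_force_kappa(counts):
    """Defining-sums kappa, written loop-wise and independently of the
    formula implementation: expand the table to pairs and count."""
    r = len(counts)
    pairs = []
    for i in range(r):
        for j in range(r):
            pairs.extend([(j, i)] * int(counts[i][j]))  # (call_a, call_b)
    n = len(pairs)
    p_o = sum(1 for a, b in pairs if a == b) / n
    p_e = 0.0
    for c in range(r):
        pa = sum(1 for a, _ in pairs if a == c) / n
        pb = sum(1 for _, b in pairs if b == c) / n
        p_e += pa * pb
    return (p_o - p_e) / (1 - p_e)


def table(counts, categories=None):
    counts = np.asarray(counts)
    cats = categories or tuple(f"c{i}" for i in range(counts.shape[0]))
    return ContingencyTable(categories=cats, counts=counts)


def test_crosstab_counts_and_marginals():
    pairs = [("x", "x"), ("x", "y"), ("y", "y"), ("y", "y"), ("x", "x")]
    tab = crosstab(pairs, ["x", "y"])
    assert tab.n == 5
    # rows: call_b, columns: call_a
    assert tab.counts.tolist() == [[2, 0], [1, 2]]
    assert tab.col_totals().tolist() == [3, 2]
    assert tab.row_totals().tolist() == [2, 3]
    with pytest.raises(ValueError, match="unknown category"):
        crosstab([("z", "x")], ["x", "y"])
    with pytest.raises(ValueError, match="empty"):
        crosstab([], ["x", "y"])


def test_percent_agreement_extremes():
    assert percent_agreement(table([[3, 0], [0, 7]])) == 1.0
    assert percent_agreement(table([[0, 4], [6, 0]])) == 0.0


def test_kappa_hand_computed_two_by_two():
    """[[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4."""
    res = cohen_kappa(table([[20, 5], [10, 15]]))
    assert res.p_observed == pytest.approx(0.7)
    assert res.p_expected == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.4)
    assert res.ci_lower <= res.kappa <= res.ci_upper


def test_kappa_is_one_iff_diagonal():
    res = cohen_kappa(table([[10, 0], [0, 5]]))
    assert res.kappa == pytest.approx(1.0)
    res = cohen_kappa(table([[10, 1], [0, 5]]))
    assert res.kappa < 1.0


def test_kappa_zero_when_observed_equals_chance():
    # independent margins: counts proportional to outer product
    res = cohen_kappa(table([[9, 21], [21, 49]]))
    assert res.kappa == pytest.approx(0.0)
    assert res.label in (AgreementLabel.NOT_SIGNIFICANT, AgreementLabel.DEGENERATE)


def test_degenerate_single_category_table():
    res = cohen_kappa(table([[50, 0], [0, 0]]))
    assert res.degenerate
    assert res.kappa == 0.0
    assert np.isnan(res.p_value)


def test_one_constant_rater_has_untestable_null():
    # every call_a is category 0: p_e < 1 but the null variance vanishes
    res = cohen_kappa(table([[30, 0], [20, 0]]))
    assert res.kappa == pytest.approx(0.0)
    assert np.isnan(res.p_value)
    assert res.label is AgreementLabel.DEGENERATE


def test_kappa_invariant_under_simultaneous_label_permutation():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 20, size=(4, 4))
    base = cohen_kappa(table(counts)).kappa
    for _ in range(5):
        perm = rng.permutation(4)
        permuted = counts[np.ix_(perm, perm)]
        assert cohen_kappa(table(permuted)).kappa == pytest.approx(base, abs=1e-12)


def test_ci_width_shrinks_with_n():
    counts = np.array([[20, 5], [10, 15]])
    widths = []
    for mult in (1, 4, 16):
        res = cohen_kappa(table(counts * mult))
        widths.append(res.ci_upper - res.ci_lower)
    assert widths[0] > widths[1] > widths[2]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(2, 5), st.integers(0, 2**31 - 1))
def test_formula_matches_brute_force_on_random_tables(r, seed):
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(rng.integers(r * r, 200), np.ones(r * r) / (r * r)).reshape(r, r)
    res = cohen_kappa(table(counts))
    if not res.degenerate and res.p_expected < 1 - 1e-9:
        assert res.kappa == pytest.approx(brute_force_kappa(counts), abs=1e-12)


def test_point_estimate_agrees_with_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(11)
    a = rng.integers(0, 4, 150)
    b = (a + (rng.random(150) < 0.4) * rng.integers(0, 4, 150)) % 4
    tab = crosstab(list(zip(a.tolist(), b.tolist())), [0, 1, 2, 3])
    assert cohen_kappa(tab).kappa == pytest.approx(
        cohen_kappa_score(a, b), abs=1e-12)


def fake_result(kappa, ci_lower, ci_upper, p_value):
    return KappaResult(
        kappa=kappa, p_observed=0.5, p_expected=0.3,
        se_estimate=0.1, se_null=0.1, ci_lower=ci_lower, ci_upper=ci_upper,
        z=kappa / 0.1, p_value=p_value, label=AgreementLabel.NOT_SIGNIFICANT, n=81,
    )


@pytest.mark.parametrize("kappa, lo, hi, p, expected", [
    (0.15, 0.05, 0.25, 0.01, AgreementLabel.SLIGHT),
    (0.24, 0.08, 0.40, 0.0004, AgreementLabel.FAIR),
    (0.52, 0.23, 0.80, 0.0034, AgreementLabel.MODERATE),
    (0.70, 0.50, 0.90, 0.001, AgreementLabel.SUBSTANTIAL),
    (0.90, 0.80, 1.00, 0.0001, AgreementLabel.ALMOST_PERFECT),
    (0.29, -0.18, 0.76, 0.1508, AgreementLabel.NOT_SIGNIFICANT),  # CI spans 0
    (0.40, 0.10, 0.70, 0.20, AgreementLabel.NOT_SIGNIFICANT),     # p too large
])
def test_interpret_bands_and_significance_gate(kappa, lo, hi, p, expected):
    assert interpret(fake_result(kappa, lo, hi, p)) is expected


def _pig(pid, score_a, score_b):
    return PigRecord(pid, [
        make_bruise(pid, "a", subcutis_neutrophils=score_a),
        make_bruise(pid, "b", subcutis_neutrophils=score_b),
    ])


def test_identical_bruises_give_kappa_one_or_degenerate():
    records = [_pig(f"P{i}", i % 4, i % 4) for i in range(20)]
    results = agreement_report(records)
    for _, _, res in results.variable_results:
        assert res.degenerate or res.kappa == pytest.approx(1.0)
    assert results.age_kappa.kappa == pytest.approx(1.0)
    assert results.percent_agreement() == 1.0


def test_independent_calls_give_kappa_near_zero():
    rng = np.random.default_rng(42)
    records = [_pig(f"P{i}", int(rng.integers(0, 4)), int(rng.integers(0, 4)))
               for i in range(600)]
    results = agreement_report(records)
    row = [r for name, _, r in results.variable_results if name == "Neutrophils"][0]
    # large-n kappa for independent draws; tolerance ~3 SEs of kappa at n=600
    assert abs(row.kappa) < 0.1


def test_pigs_missing_a_label_are_excluded_and_listed():
    records = [_pig("P1", 1, 1), PigRecord("P2", [make_bruise("P2", "a")])]
    model = PairwiseAgreement(records)
    assert model.exclusions == ["P2"]
    assert model.nobs == 1


def test_summary_renders(two_bruise_pig):
    results = agreement_report([two_bruise_pig, _pig("P9", 1, 2)])
    text = results.summary()
    assert "Cohen's kappa" in text
    assert "Age category" in text
    assert "bruise b" in text
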