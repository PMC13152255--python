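"""Agreement categories, rate summaries and the Bhapkar test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sgecurate import (
    ValidationError,
    agreement_category,
    bhapkar_test,
    crosstab,
    rate_summary,
)
from sgecurate.concordance import AGREEMENT_CATEGORIES


@pytest.mark.parametrize(
    "clinical, call, expected",
    [
        ("LBV", "pathogenic", "major_error"),
        ("BV", "pathogenic", "major_error"),
        ("PV", "benign", "major_error"),
        ("LPV", "benign", "major_error"),
        ("PV", "uncertain", "minor_error"),
        ("LBV", "uncertain", "minor_error"),
        ("VUS", "pathogenic", "minor_error"),
        ("VUS", "benign", "minor_error"),
        ("VUS", "uncertain", "concordant"),
        ("PV", "pathogenic", "concordant"),
        ("BV", "benign", "concordant"),
        # IARC classes collapse to the same three-way scheme
        (5, "pathogenic", "concordant"),
        (4, "benign", "major_error"),
        (3, "uncertain", "concordant"),
        (2, "pathogenic", "major_error"),
        (1, "uncertain", "minor_error"),
    ],
)
def test_agreement_category_definitions(clinical, call, expected):
    assert agreement_category(clinical, call) == expected


def test_agreement_category_rejects_unknown_inputs():
    with pytest.raises(ValidationError):
        agreement_category("LP", "benign")
    with pytest.raises(ValidationError):
        agreement_category("PV", "maybe")


def test_rate_summary_rounding_and_counts():
    cats = ["major_error"] * 2 + ["minor_error"] * 6 + ["concordant"] * 5
    summary = rate_summary(cats)
    assert summary.n == 13
    assert summary.as_tuple() == (15.4, 46.2, 38.5)
    assert rate_summary(["concordant"] * 7).as_tuple() == (0.0, 0.0, 100.0)
    with pytest.raises(ValidationError):
        rate_summary([])


def test_crosstab_marginals():
    pairs = [
        ("concordant", "major_error"),
        ("minor_error", "concordant"),
        ("concordant", "minor_error"),
        ("major_error", "concordant"),
        ("concordant", "major_error"),
    ]
    table = crosstab(pairs)
    assert table.to_numpy().sum() == 5
    assert list(table.sum(axis=1)) == [1, 1, 3]  # dataset-1 marginals
    assert list(table.sum(axis=0)) == [2, 1, 2]  # dataset-2 marginals
    assert crosstab([]).to_numpy().sum() == 0
    diagonal = crosstab([("major_error", "major_error"), ("concordant", "concordant")])
    assert np.trace(diagonal.to_numpy()) == 2


def test_bhapkar_symmetric_table_is_null():
    table = np.array([[5, 2, 3], [2, 7, 1], [3, 1, 4]])
    res = bhapkar_test(table)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 2


def test_bhapkar_invariant_under_joint_permutation():
    rng = np.random.default_rng(5)
    table = rng.integers(0, 20, (3, 3))
    base = bhapkar_test(table)
    for perm in ([1, 2, 0], [2, 0, 1], [2, 1, 0]):
        permuted = table[np.ix_(perm, perm)]
        res = bhapkar_test(permuted)
        assert res.statistic == pytest.approx(base.statistic, rel=1e-9)


def test_bhapkar_p_decreases_when_asymmetry_replicated():
    table = np.array([[4, 6, 1], [2, 5, 3], [2, 1, 6]])
    p_values = [bhapkar_test(table * m).p_value for m in (1, 2, 4)]
    assert p_values[0] > p_values[1] > p_values[2]


def test_bhapkar_statistic_zero_iff_marginals_match():
    homogeneous = np.array([[1, 2], [2, 3]])
    assert bhapkar_test(homogeneous).statistic == pytest.approx(0.0, abs=1e-12)
    asymmetric = np.array([[1, 5], [2, 3]])
    assert bhapkar_test(asymmetric).statistic > 0


def test_bhapkar_k2_closed_form():
    """k=2 reduces to (n12-n21)^2 / (n12+n21 - (n12-n21)^2/n)."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        table = rng.integers(0, 30, (2, 2)).astype(float)
        n12, n21 = table[0, 1], table[1, 0]
        n = table.sum()
        if n == 0 or n12 + n21 == 0:
            continue
        denom = n12 + n21 - (n12 - n21) ** 2 / n
        res = bhapkar_test(table)
        if denom <= 0:
            assert res.p_value == pytest.approx(0.0, abs=1e-12)
        else:
            assert res.statistic == pytest.approx((n12 - n21) ** 2 / denom, rel=1e-9)
            assert res.df == 1


def test_bhapkar_degenerate_conventions():
    # d = 0 and V = 0: homogeneity holds trivially
    res = bhapkar_test(np.array([[7, 0], [0, 3]]))
    assert (res.statistic, res.p_value) == (0.0, 1.0)
    # V = 0 with d != 0: complete asymmetry
    res = bhapkar_test(np.array([[0, 5], [0, 0]]))
    assert res.p_value == pytest.approx(0.0)
    with pytest.raises(ValidationError):
        bhapkar_test(np.zeros((2, 2)))
    with pytest.raises(ValidationError):
        bhapkar_test(np.ones((2, 3)))


def test_bhapkar_matches_statsmodels():
    """Independent cross-check against statsmodels' implementation."""
    sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
    rng = np.random.default_rng(3)
    for _ in range(20):
        table = rng.integers(1, 25, (3, 3))
        ours = bhapkar_test(table)
        theirs = sm_ct.SquareTable(table).homogeneity(method="bhapkar")
        assert ours.statistic == pytest.approx(float(theirs.statistic), rel=1e-8)
        assert ours.p_value == pytest.approx(float(theirs.pvalue), rel=1e-6, abs=1e-12)
        assert ours.df == int(theirs.df)
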