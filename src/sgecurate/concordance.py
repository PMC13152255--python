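"""Agreement of functional calls with clinical classifications.

Each SGE dataset's binary functional call is scored against a clinical
classification (five-tier ACMG/AMP label or IARC class) collapsed to a
three-way scheme — pathogenic-side (PV/LPV, IARC 4-5), uncertain (VUS,
IARC 3), benign-side (LBV/BV, IARC 1-2):

* **major error** — a pathogenic call for a benign-side classification or
  a benign call for a pathogenic-side classification;
* **minor error** — an uncertain call for a definitive classification, or
  a definitive call for an uncertain classification;
* **concordant** — everything else.

Rates are reported as percentages to one decimal.  To compare the two
datasets, the per-variant agreement categories are cross-tabulated and
tested for marginal homogeneity with the Bhapkar chi-square test — the
k-category generalization of McNemar's test for paired data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "AGREEMENT_CATEGORIES",
    "clinical_side",
    "agreement_category",
    "AgreementRecord",
    "RateSummary",
    "rate_summary",
    "crosstab",
    "BhapkarResult",
    "bhapkar_test",
]

#: Ordered agreement categories used throughout.
AGREEMENT_CATEGORIES = ("major_error", "minor_error", "concordant")

_ACMG_SIDE = {"PV": "pathogenic", "LPV": "pathogenic", "VUS": "uncertain", "LBV": "benign", "BV": "benign"}
_IARC_SIDE = {5: "pathogenic", 4: "pathogenic", 3: "uncertain", 2: "benign", 1: "benign"}


def clinical_side(clinical: Union[str, int]) -> str:
    """Collapse a clinical classification to pathogenic/uncertain/benign.

    Accepts a five-tier label (``"PV"`` ... ``"BV"``), an IARC class
    (1-5), or one of the three side names directly.
    """
    if isinstance(clinical, str):
        token = clinical.strip()
        if token.upper() in _ACMG_SIDE:
            return _ACMG_SIDE[token.upper()]
        if token.lower() in ("pathogenic", "uncertain", "benign"):
            return token.lower()
        try:
            clinical = int(token)
        except ValueError:
            raise ValidationError(f"unknown clinical classification: {clinical!r}") from None
    try:
        return _IARC_SIDE[int(clinical)]
    except (KeyError, TypeError):
        raise ValidationError(f"unknown clinical classification: {clinical!r}") from None


def agreement_category(clinical: Union[str, int], call: str) -> str:
    """Score one functional call against one clinical classification."""
    side = clinical_side(clinical)
    if call not in ("pathogenic", "benign", "uncertain"):
        raise ValidationError(f"unknown functional call: {call!r}")
    if side == "uncertain":
        return "concordant" if call == "uncertain" else "minor_error"
    if call == "uncertain":
        return "minor_error"
    return "concordant" if call == side else "major_error"


@dataclass(frozen=True)
class AgreementRecord:
    """Per-variant agreement category of one dataset's call."""

    variant_id: str
    dataset: str  # "HAP1" or "mES"
    category: str


def _round1(x: float) -> float:
    # round half away from zero at one decimal (inputs are >= 0 here)
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class RateSummary:
    """Major/minor/concordance percentages over *n* variants."""

    n: int
    major_pct: float
    minor_pct: float
    concordant_pct: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.major_pct, self.minor_pct, self.concordant_pct)


def rate_summary(categories: Iterable[Union[str, AgreementRecord]]) -> RateSummary:
    """Summarize agreement categories as one-decimal percentages."""
    labels = [c.category if isinstance(c, AgreementRecord) else c for c in categories]
    if not labels:
        raise ValidationError("rate_summary requires at least one record")
    for lab in labels:
        if lab not in AGREEMENT_CATEGORIES:
            raise ValidationError(f"unknown agreement category: {lab!r}")
    n = len(labels)
    counts = {cat: labels.count(cat) for cat in AGREEMENT_CATEGORIES}
    return RateSummary(
        n=n,
        major_pct=_round1(100.0 * counts["major_error"] / n),
        minor_pct=_round1(100.0 * counts["minor_error"] / n),
        concordant_pct=_round1(100.0 * counts["concordant"] / n),
    )


def crosstab(
    pairs: Sequence[tuple[str, str]],
    categories: Sequence[str] = AGREEMENT_CATEGORIES,
) -> pd.DataFrame:
    """k x k paired contingency table (rows: dataset 1, columns: dataset 2)."""
    table = pd.DataFrame(0, index=list(categories), columns=list(categories), dtype=int)
    for a, b in pairs:
        if a not in categories or b not in categories:
            raise ValidationError(f"pair ({a!r}, {b!r}) outside category set {tuple(categories)}")
        table.loc[a, b] += 1
    return table


@dataclass(frozen=True)
class BhapkarResult:
    statistic: float
    df: int
    p_value: float
    pair_table: pd.DataFrame


def bhapkar_test(pair_table: Union[pd.DataFrame, np.ndarray]) -> BhapkarResult:
    """Bhapkar chi-square test of marginal homogeneity on a k x k table.

    With cell proportions ``p_ij = n_ij / n`` and marginal differences
    ``d_i = p_i. - p_.i`` (i = 1..k-1), the statistic is
    ``n * d' V^{-1} d`` where ``v_ii = p_i. + p_.i - 2 p_ii - d_i^2`` and
    ``v_ij = -(p_ij + p_ji) - d_i d_j``.  It is referred to a chi-square
    with k-1 degrees of freedom; when V is singular (small tables with
    empty categories) a Moore-Penrose generalized inverse is used and the
    degrees of freedom drop to rank(V).  A fully degenerate table (d = 0,
    V = 0) returns statistic 0 with p-value 1 by convention.
    """
    if isinstance(pair_table, pd.DataFrame):
        frame = pair_table
        counts = pair_table.to_numpy(dtype=float)
    else:
        counts = np.asarray(pair_table, dtype=float)
        frame = pd.DataFrame(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValidationError(f"pair table must be square, got shape {counts.shape}")
    k = counts.shape[0]
    if k < 2:
        raise ValidationError("pair table needs at least two categories")
    if np.any(counts < 0):
        raise ValidationError("pair table counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValidationError("pair table must contain at least one observation")

    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    d = (row - col)[: k - 1]
    V = np.empty((k - 1, k - 1))
    for i in range(k - 1):
        for j in range(k - 1):
            if i == j:
                V[i, i] = row[i] + col[i] - 2.0 * p[i, i] - d[i] ** 2
            else:
                V[i, j] = -(p[i, j] + p[j, i]) - d[i] * d[j]

    if np.allclose(d, 0.0) and np.allclose(V, 0.0):
        return BhapkarResult(statistic=0.0, df=k - 1, p_value=1.0, pair_table=frame)

    rank = int(np.linalg.matrix_rank(V))
    if rank == 0:
        # V vanishes while the marginals differ: complete asymmetry
        return BhapkarResult(statistic=float("inf"), df=k - 1, p_value=0.0, pair_table=frame)
    if rank == k - 1:
        statistic = float(n * d @ np.linalg.solve(V, d))
        df = k - 1
    else:
        statistic = float(n * d @ np.linalg.pinv(V) @ d)
        df = max(rank, 1)
    statistic = max(statistic, 0.0)
    p_value = float(stats.chi2.sf(statistic, df))
    return BhapkarResult(statistic=statistic, df=df, p_value=p_value, pair_table=frame)
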