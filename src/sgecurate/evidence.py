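"""ACMG/AMP evidence codes and the point-based five-tier classifier.

Evidence for or against pathogenicity is expressed as standardized tokens
(``PVS1``, ``PM2``, ``BP4`` ...) whose strength may be modified with a
suffix: ``_P`` supporting, ``_M`` moderate, ``_S`` strong, ``_VS`` very
strong (so ``PM2_P`` is the PM2 criterion applied at supporting strength).
Each applied code converts to a signed integer number of points —
supporting/moderate/strong/very-strong evidence is worth 1/2/4/8 points,
positive for pathogenic codes and negative for benign codes — and the
arithmetic sum maps onto the five clinical tiers:

===============================  ==========
pathogenic (PV)                  total >= 10
likely pathogenic (LPV)          6 .. 9
uncertain significance (VUS)     -1 .. 5
likely benign (LBV)              -6 .. -2
benign (BV)                      total <= -7
===============================  ==========

``BA1`` is the one stand-alone benign criterion; it carries no point value
here and instead short-circuits the classification to BV (see
:func:`classify_variant`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import EvidenceParseError, ValidationError

__all__ = [
    "EvidenceCode",
    "ClassificationResult",
    "parse_evidence_code",
    "parse_evidence_list",
    "aggregate_points",
    "classify",
    "classify_variant",
    "CLASS_LABELS",
]

#: Five-tier class labels, ordered benign -> pathogenic.
CLASS_LABELS = ("BV", "LBV", "VUS", "LPV", "PV")

STRENGTH_POINTS = {
    "supporting": 1,
    "moderate": 2,
    "strong": 4,
    "very_strong": 8,
}

#: Default strength implied by the code family when no suffix is given.
FAMILY_DEFAULT_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone",
    "BS": "strong",
    "BP": "supporting",
}

SUFFIX_STRENGTH = {"P": "supporting", "M": "moderate", "S": "strong", "VS": "very_strong"}
STRENGTH_SUFFIX = {v: k for k, v in SUFFIX_STRENGTH.items()}

_TOKEN_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)([0-9]+)(?:_([A-Z]+))?$")
# trailing parenthetical comments, e.g. "BP7_S (RNA)", are annotation only
_COMMENT_RE = re.compile(r"\s*\([^()]*\)\s*$")


@dataclass(frozen=True)
class EvidenceCode:
    """One applied ACMG/AMP evidence criterion.

    Attributes
    ----------
    label:
        Normalized token, e.g. ``"PM2_P"`` (comments stripped).
    base:
        Code family plus number, e.g. ``"PM2"``; at most one code per base
        may be applied to a variant.
    direction:
        ``"pathogenic"`` or ``"benign"``.
    strength:
        ``"supporting"``, ``"moderate"``, ``"strong"``, ``"very_strong"``
        or ``"stand_alone"`` (BA family only).
    points:
        Signed point value; 0 for stand-alone codes, which do not enter
        point totals.
    """

    label: str
    base: str
    direction: str
    strength: str
    points: int

    def render(self) -> str:
        """Return the canonical token string for this code."""
        return self.label


@dataclass(frozen=True)
class ClassificationResult:
    """Aggregated points and five-tier label for one variant."""

    total_points: int
    label: str
    applied_codes: tuple[EvidenceCode, ...] = field(default_factory=tuple)
    #: True when a stand-alone benign code forced the BV label.
    stand_alone_applied: bool = False


def parse_evidence_code(token: str) -> EvidenceCode:
    """Parse a single ACMG/AMP token such as ``"PVS1"`` or ``"PM2_P"``.

    A trailing parenthetical comment (``"PVS1 (RNA)"``) is accepted and
    ignored.  The strength suffix, when present, overrides the family
    default.

    Raises
    ------
    EvidenceParseError
        If the token does not match the code grammar or carries an
        unknown strength suffix.
    """
    raw = token
    token = _COMMENT_RE.sub("", token.strip())
    m = _TOKEN_RE.match(token)
    if not m:
        raise EvidenceParseError(f"malformed ACMG/AMP evidence token: {raw!r}")
    family, number, suffix = m.groups()
    base = family + number
    direction = "pathogenic" if family.startswith("P") else "benign"
    if suffix is not None:
        if family == "BA":
            raise EvidenceParseError(
                f"stand-alone code {base} does not take a strength suffix: {raw!r}"
            )
        strength = SUFFIX_STRENGTH.get(suffix)
        if strength is None:
            raise EvidenceParseError(f"unknown strength suffix {suffix!r} in token {raw!r}")
    else:
        strength = FAMILY_DEFAULT_STRENGTH[family]
    if strength == "stand_alone":
        points = 0
    else:
        points = STRENGTH_POINTS[strength]
        if direction == "benign":
            points = -points
    return EvidenceCode(label=token, base=base, direction=direction, strength=strength, points=points)


def parse_evidence_list(text: str, sep: str = ";") -> list[EvidenceCode]:
    """Parse a separated list of tokens (``"PVS1; PM2_P; PM5_S"``).

    Empty input yields an empty list.  Both ``;`` and ``,`` are accepted
    in practice via *sep*; tokens are whitespace-stripped.
    """
    text = text.strip()
    if not text:
        return []
    return [parse_evidence_code(tok) for tok in text.split(sep) if tok.strip()]


def aggregate_points(codes: list[EvidenceCode]) -> int:
    """Sum the signed points of the applied codes.

    Stand-alone codes contribute nothing.  Applying two codes from the
    same base family (e.g. ``PS3`` together with ``PS3_P``) would double
    count one criterion and is rejected.
    """
    seen: set[str] = set()
    for code in codes:
        if code.base in seen:
            raise ValidationError(f"duplicate evidence base family: {code.base}")
        seen.add(code.base)
    return sum(c.points for c in codes)


def classify(total_points: int) -> str:
    """Map an aggregated point total to the five-tier class label."""
    if total_points >= 10:
        return "PV"
    if total_points >= 6:
        return "LPV"
    if total_points >= -1:
        return "VUS"
    if total_points >= -6:
        return "LBV"
    return "BV"


def classify_variant(codes: list[EvidenceCode]) -> ClassificationResult:
    """Aggregate a code set and classify the variant.

    A stand-alone benign code (BA1) forces the BV label regardless of the
    point total of the remaining codes; the result records that the
    short-circuit fired.
    """
    total = aggregate_points(codes)
    stand_alone = any(c.strength == "stand_alone" for c in codes)
    if stand_alone:
        label = "BV"
    else:
        label = classify(total)
    return ClassificationResult(
        total_points=total,
        label=label,
        applied_codes=tuple(codes),
        stand_alone_applied=stand_alone,
    )
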