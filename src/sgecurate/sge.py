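"""Integration of paired saturation-genome-editing (SGE) functional calls.

Two independent SGE screens of the BRCA2 C-terminal DNA-binding domain —
one in haploid human HAP1 cells, one in mouse embryonic stem (mES) cells —
each bin every assayed variant into seven functional categories, mapped
here onto signed points:

    pathogenic strong / moderate / supporting   ->  +4 / +2 / +1
    uncertain                                   ->   0
    benign supporting / moderate / strong       ->  -1 / -2 / -4

The sign of the category is the binary functional call (pathogenic,
benign, or uncertain at zero).  When the two screens agree in sign, the
pair supports a single integrated ACMG/AMP functional-evidence code: PS3
for concordant pathogenic calls, BS3 for concordant benign calls, applied
at the strength of the *stronger* of the two categories (so a pair at the
supporting level yields the downgraded PS3_P/BS3_P).  When the calls
disagree — opposite signs, or exactly one uncertain — no functional
evidence is assigned.  Two uncertain calls are uninformative rather than
discordant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Union

from .errors import ValidationError
from .evidence import ClassificationResult, EvidenceCode, classify_variant, parse_evidence_code

__all__ = [
    "SGECategory",
    "functional_call",
    "IntegratedFunctionalEvidence",
    "IntegrationOutcome",
    "integrate",
    "apply_integration",
]


class SGECategory(enum.Enum):
    """Seven-level functional result of one SGE dataset."""

    PATHOGENIC_STRONG = 4
    PATHOGENIC_MODERATE = 2
    PATHOGENIC_SUPPORTING = 1
    UNCERTAIN = 0
    BENIGN_SUPPORTING = -1
    BENIGN_MODERATE = -2
    BENIGN_STRONG = -4

    @property
    def points(self) -> int:
        return self.value

    @classmethod
    def coerce(cls, value: Union["SGECategory", int, str]) -> "SGECategory":
        """Accept a category, its signed point value, or its level name.

        Strings are matched case-insensitively and may be either a level
        name (``"benign_strong"``) or a signed integer (``"-4"``, with
        Unicode minus accepted).
        """
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            text = value.strip().replace("−", "-")
            try:
                value = int(text)
            except ValueError:
                try:
                    return cls[text.upper()]
                except KeyError:
                    raise ValidationError(f"unknown SGE category: {text!r}") from None
        try:
            return cls(int(value))
        except ValueError:
            raise ValidationError(f"invalid SGE point value: {value!r}") from None


def functional_call(category: SGECategory) -> str:
    """Binary sense of a category: ``pathogenic``/``benign``/``uncertain``."""
    if category.points > 0:
        return "pathogenic"
    if category.points < 0:
        return "benign"
    return "uncertain"


@dataclass(frozen=True)
class IntegratedFunctionalEvidence:
    """Outcome of comparing the two datasets for one variant.

    ``assigned_code`` is present exactly when the status is concordant;
    its direction matches the shared call and its strength is the larger
    of the two category magnitudes.
    """

    status: str  # concordant_pathogenic | concordant_benign | discordant | uninformative
    assigned_code: Optional[EvidenceCode] = None

    @property
    def concordant(self) -> bool:
        return self.status in ("concordant_pathogenic", "concordant_benign")


_MAGNITUDE_SUFFIX = {4: "", 2: "_M", 1: "_P"}


def integrate(hap1: SGECategory, mes: SGECategory) -> IntegratedFunctionalEvidence:
    """Decide concordance of an (HAP1, mES) category pair and assign evidence.

    Concordant-pathogenic pairs yield a PS3-family code and concordant
    benign pairs a BS3-family code, at the stronger of the two levels
    (|points| 4 -> strong, 2 -> moderate, 1 -> supporting).  Discordant
    pairs — including one-sided uncertain calls — receive no code; a
    both-uncertain pair is uninformative.
    """
    call1, call2 = functional_call(hap1), functional_call(mes)
    if call1 == "uncertain" and call2 == "uncertain":
        return IntegratedFunctionalEvidence(status="uninformative")
    if call1 != call2:
        return IntegratedFunctionalEvidence(status="discordant")
    magnitude = max(abs(hap1.points), abs(mes.points))
    family = "PS3" if call1 == "pathogenic" else "BS3"
    code = parse_evidence_code(family + _MAGNITUDE_SUFFIX[magnitude])
    return IntegratedFunctionalEvidence(status=f"concordant_{call1}", assigned_code=code)


@dataclass(frozen=True)
class IntegrationOutcome:
    """Pre- and post-integration classifications for one variant."""

    pre: ClassificationResult
    evidence: IntegratedFunctionalEvidence
    post: ClassificationResult

    @property
    def reclassified(self) -> bool:
        return self.pre.label != self.post.label


def apply_integration(
    codes: list[EvidenceCode], hap1: SGECategory, mes: SGECategory
) -> IntegrationOutcome:
    """Append the integrated PS3/BS3 code, if any, and reclassify.

    The incoming code set must not already contain a PS3/BS3-family code;
    the functional criterion would otherwise be double counted.
    """
    for code in codes:
        if code.base in ("PS3", "BS3"):
            raise ValidationError(
                f"evidence already contains functional code {code.label}; "
                "cannot integrate SGE results twice"
            )
    pre = classify_variant(codes)
    ev = integrate(hap1, mes)
    if ev.assigned_code is not None:
        post = classify_variant(list(codes) + [ev.assigned_code])
    else:
        post = pre
    return IntegrationOutcome(pre=pre, evidence=ev, post=post)
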