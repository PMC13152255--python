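"""Multifactorial likelihood analysis: Bayes posterior and IARC classes.

The multifactorial model combines a prior probability of pathogenicity
(looked up from an Align-GVGD grade or, for variants without a grade,
from the variant type) with a combined likelihood ratio (LR) — the
product of independent LR components derived from personal/family cancer
history, tumour pathology and co-occurrence with known pathogenic
variants.  On the odds scale,

    posterior odds = prior odds x combined LR,

equivalently ``posterior = prior*LR / (prior*LR + 1 - prior)``.

The posterior maps onto the IARC five-class scheme (class 5 pathogenic
down to class 1 neutral).  Because the posterior of a rare variant with
few observed carriers is dominated by its prior, a variant whose combined
LR falls inside the uninformative window [0.5, 2] is not assigned an
IARC class at all.

Boundary conventions (the published band edges are ambiguous at printed
precision) are: class 1 for posterior <= 0.001, class 2 up to 0.05
(exclusive), class 3 up to 0.95 (exclusive), class 4 up to 0.99
(inclusive), class 5 above 0.99.  These bands are exhaustive and
disjoint and reproduce every classified fixture row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import yaml

from .errors import ConfigError, ValidationError

__all__ = [
    "combine_lr",
    "posterior",
    "iarc_class",
    "MultifactorialResult",
    "evaluate",
    "PriorTable",
    "LR_EXCLUSION_WINDOW",
]

#: Combined-LR window treated as uninformative for IARC assignment.
LR_EXCLUSION_WINDOW = (0.5, 2.0)


def combine_lr(components: Iterable[float]) -> float:
    """Multiply independent LR components; an empty list is neutral (1.0)."""
    product = 1.0
    for x in components:
        x = float(x)
        if x < 0 or math.isnan(x):
            raise ValidationError(f"likelihood-ratio components must be >= 0, got {x}")
        product *= x
    return product


def posterior(prior: float, combined_lr: float) -> float:
    """Bayes posterior probability of pathogenicity.

    ``posterior = prior*LR / (prior*LR + (1 - prior))``.  The only
    indeterminate input is prior 1 with LR 0 (odds 0/0), which is
    rejected.
    """
    if not 0.0 <= prior <= 1.0:
        raise ValidationError(f"prior must be a probability, got {prior}")
    if combined_lr < 0:
        raise ValidationError(f"combined LR must be >= 0, got {combined_lr}")
    numerator = prior * combined_lr
    denominator = numerator + (1.0 - prior)
    if denominator == 0.0:
        raise ValidationError("indeterminate posterior: prior 1 with combined LR 0")
    return numerator / denominator


def iarc_class(
    posterior_probability: float,
    combined_lr: float,
    window: tuple[float, float] = LR_EXCLUSION_WINDOW,
) -> Optional[int]:
    """IARC class 1-5 for a posterior, or ``None`` when the LR is uninformative.

    The exclusion window is inclusive at both ends.
    """
    if not 0.0 <= posterior_probability <= 1.0:
        raise ValidationError(f"posterior must be a probability, got {posterior_probability}")
    lo, hi = window
    if lo <= combined_lr <= hi:
        return None
    p = posterior_probability
    if p <= 0.001:
        return 1
    if p < 0.05:
        return 2
    if p < 0.95:
        return 3
    if p <= 0.99:
        return 4
    return 5


@dataclass(frozen=True)
class MultifactorialResult:
    """Prior, combined LR, posterior and IARC class for one variant."""

    prior: float
    combined_lr: float
    posterior: float
    iarc: Optional[int]  # None == not assigned (LR in exclusion window)


def evaluate(
    prior: float,
    lr_components: Optional[Iterable[float]] = None,
    combined_lr: Optional[float] = None,
    window: tuple[float, float] = LR_EXCLUSION_WINDOW,
) -> MultifactorialResult:
    """Run the full multifactorial calculation for one variant.

    Exactly one of *lr_components* and *combined_lr* must be given.
    """
    if (lr_components is None) == (combined_lr is None):
        raise ValidationError("supply exactly one of lr_components and combined_lr")
    lr = combine_lr(lr_components) if lr_components is not None else float(combined_lr)
    if lr < 0:
        raise ValidationError(f"combined LR must be >= 0, got {lr}")
    post = posterior(prior, lr)
    return MultifactorialResult(prior=prior, combined_lr=lr, posterior=post, iarc=iarc_class(post, lr, window))


@dataclass(frozen=True)
class PriorTable:
    """Prior probabilities keyed by Align-GVGD grade and by variant type.

    The shipped defaults mirror the magnitude of published BRCA2 prior
    tables (missense graded C0 at 0.02 up to C65 at 0.81; truncating
    types near 0.96) but are configuration, not assertions about any
    particular database — supply your own YAML for production use.
    """

    align_gvgd_grade: dict = field(default_factory=dict)
    variant_type: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.align_gvgd_grade, self.variant_type):
            for key, value in table.items():
                if not 0.0 <= float(value) <= 1.0:
                    raise ConfigError(f"prior for {key!r} must be a probability, got {value}")

    def lookup(self, gvgd_grade: Optional[str] = None, variant_type: Optional[str] = None) -> float:
        """Resolve a prior; the Align-GVGD grade takes precedence."""
        if gvgd_grade:
            try:
                return float(self.align_gvgd_grade[gvgd_grade.strip().upper()])
            except KeyError:
                raise ConfigError(f"no prior for Align-GVGD grade {gvgd_grade!r}") from None
        if variant_type:
            try:
                return float(self.variant_type[variant_type.strip().lower()])
            except KeyError:
                raise ConfigError(f"no prior for variant type {variant_type!r}") from None
        raise ConfigError("neither an Align-GVGD grade nor a variant type was supplied")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PriorTable":
        return cls(
            align_gvgd_grade={str(k).upper(): float(v) for k, v in (mapping.get("align_gvgd_grade") or {}).items()},
            variant_type={str(k).lower(): float(v) for k, v in (mapping.get("variant_type") or {}).items()},
        )

    @classmethod
    def from_yaml(cls, path) -> "PriorTable":
        with open(path, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls.from_mapping(mapping)

    @classmethod
    def default(cls) -> "PriorTable":
        """Load the prior table shipped with the package."""
        ref = resources.files("sgecurate.data").joinpath("priors.yaml")
        mapping = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return cls.from_mapping(mapping)
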