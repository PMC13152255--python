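"""Synthetic cohorts with known ground truth.

The generator emulates the inputs the curation pipeline consumes, per
variant:

* a **true class** drawn from a five-tier mixture;
* an **evidence-code set** rejection-sampled from the code families seen
  in real BRCA2 curation (PVS1, PS1, PM2, PM5, PP1, PP3, BS1, BS2, BP4,
  BP7) so that its point total lands inside the true class's band;
* a **paired SGE result**: with probability ``sge_discordance_rate`` the
  pair is forced discordant (one dataset's sign flipped, or set to
  uncertain, mirroring the discordance modes seen in practice);
  otherwise both categories match the true class's sign, each dataset
  independently corrupted (sign flipped) with probability
  ``sge_error_rate``;
* **LR components** drawn lognormal, with a positive log-mean for
  pathogenic-truth variants and a negative one for benign-truth
  variants; VUS-truth variants mix the two groups evenly.

Everything is reproducible from the seed.  The generator produces the
*shape* of real cohorts, not their biology: evidence codes are sampled
independently of each other and of the SGE result, and LR components
carry no pedigree structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import agreement_category, rate_summary
from .errors import ConfigError, ValidationError
from .evidence import CLASS_LABELS, aggregate_points, classify, parse_evidence_code
from .io import PipelineResult, VariantRecord
from .sge import SGECategory, functional_call

__all__ = ["CohortConfig", "simulate_cohort", "recovery_report", "CLASS_BANDS"]

#: Point band (inclusive) targeted for each true class during evidence
#: generation.  PV and BV are open-ended in principle; the generator caps
#: them at what the code pool can produce.
CLASS_BANDS = {
    "PV": (10, 24),
    "LPV": (6, 9),
    "VUS": (-1, 5),
    "LBV": (-6, -2),
    "BV": (-12, -7),
}

# (family, candidate tokens) — restricted to families seen in BRCA2
# curation practice; PS3/BS3 are reserved for the integration step.
_CODE_POOL = (
    ("PVS1", ("PVS1", "PVS1_S")),
    ("PS1", ("PS1", "PS1_M", "PS1_P")),
    ("PM2", ("PM2", "PM2_P")),
    ("PM5", ("PM5", "PM5_S", "PM5_P")),
    ("PP1", ("PP1", "PP1_M", "PP1_S")),
    ("PP3", ("PP3",)),
    ("BS1", ("BS1", "BS1_M", "BS1_P")),
    ("BS2", ("BS2", "BS2_P")),
    ("BP4", ("BP4",)),
    ("BP7", ("BP7",)),
)

_CLASS_SIDE = {"PV": "pathogenic", "LPV": "pathogenic", "VUS": "uncertain", "LBV": "benign", "BV": "benign"}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults: 500 variants; a class mixture weighted toward VUS as in
    clinical referral series; a pairwise discordance rate of 0.169 (the
    fraction of assayed BRCA2 variants on which the two published SGE
    screens disagree); a per-dataset corruption rate of 0.1; three LR
    components per variant, lognormal with log-mean +/-0.6 and log-sd
    0.4 for the pathogenic/benign groups.
    """

    n_variants: int = 500
    class_mix: dict = field(
        default_factory=lambda: {"PV": 0.15, "LPV": 0.10, "VUS": 0.40, "LBV": 0.20, "BV": 0.15}
    )
    sge_discordance_rate: float = 0.169
    sge_error_rate: float = 0.10
    lr_lognormal_params: dict = field(
        default_factory=lambda: {"pathogenic": (0.6, 0.4), "benign": (-0.6, 0.4)}
    )
    n_lr_components: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigError("n_variants must be positive")
        if set(self.class_mix) != set(CLASS_LABELS):
            raise ConfigError(f"class_mix must cover exactly {CLASS_LABELS}")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"class_mix must sum to 1, got {total}")
        for name in ("sge_discordance_rate", "sge_error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {value}")
        mu_p = self.lr_lognormal_params["pathogenic"][0]
        mu_b = self.lr_lognormal_params["benign"][0]
        if not mu_p > 0 > mu_b:
            raise ConfigError("pathogenic log-mean must be positive and benign negative")
        if self.n_lr_components < 1:
            raise ConfigError("n_lr_components must be positive")


def _sample_evidence(rng: np.random.Generator, true_class: str, max_tries: int = 10000) -> list:
    lo, hi = CLASS_BANDS[true_class]
    side = _CLASS_SIDE[true_class]
    # inclusion probability biased toward the target direction to keep
    # rejection sampling cheap; VUS draws sparsely from both sides
    if side == "pathogenic":
        p_include = {"P": 0.55, "B": 0.10}
    elif side == "benign":
        p_include = {"P": 0.10, "B": 0.55}
    else:
        p_include = {"P": 0.25, "B": 0.25}
    for _ in range(max_tries):
        codes = []
        for family, tokens in _CODE_POOL:
            if rng.random() < p_include[family[0]]:
                codes.append(parse_evidence_code(tokens[rng.integers(len(tokens))]))
        if lo <= aggregate_points(codes) <= hi:
            return codes
    raise ConfigError(f"could not sample an evidence set in band {lo}..{hi} for {true_class}")


def _draw_category(rng: np.random.Generator, side: str) -> SGECategory:
    if side == "uncertain":
        return SGECategory.UNCERTAIN
    magnitude = int(rng.choice([1, 2, 4]))
    return SGECategory(magnitude if side == "pathogenic" else -magnitude)


def _flip(side: str, rng: np.random.Generator) -> str:
    if side == "pathogenic":
        return "benign"
    if side == "benign":
        return "pathogenic"
    return "pathogenic" if rng.random() < 0.5 else "benign"


def _sample_sge_pair(
    rng: np.random.Generator, side: str, discordance_rate: float, error_rate: float
) -> tuple[SGECategory, SGECategory, bool]:
    if rng.random() < discordance_rate:
        # forced discordant: one dataset keeps (or gets) the truth-sided
        # call, the other flips sign or drops to uncertain
        kept = _draw_category(rng, side if side != "uncertain" else _flip(side, rng))
        mode_uncertain = side != "uncertain" and rng.random() < 0.5
        other = SGECategory.UNCERTAIN if mode_uncertain else _draw_category(rng, _flip(functional_call(kept), rng))
        pair = (kept, other) if rng.random() < 0.5 else (other, kept)
        return pair[0], pair[1], True
    cats = []
    for _ in range(2):
        call_side = side
        if rng.random() < error_rate:
            call_side = _flip(side, rng)
        cats.append(_draw_category(rng, call_side))
    return cats[0], cats[1], False


def simulate_cohort(config: CohortConfig) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Generate a cohort and its ground-truth table.

    Returns parsed records (ready for :func:`sgecurate.io.run_pipeline`)
    and a truth DataFrame with columns ``variant_id``, ``true_class``,
    ``lr_group`` and ``forced_discordant``.
    """
    rng = np.random.default_rng(config.seed)
    labels = list(CLASS_LABELS)
    mix = np.array([config.class_mix[c] for c in labels])
    records: list[VariantRecord] = []
    truth_rows = []
    for i in range(config.n_variants):
        true_class = labels[rng.choice(len(labels), p=mix)]
        side = _CLASS_SIDE[true_class]
        codes = _sample_evidence(rng, true_class)
        hap1, mes, forced = _sample_sge_pair(
            rng, side, config.sge_discordance_rate, config.sge_error_rate
        )
        if side == "uncertain":
            group = "pathogenic" if rng.random() < 0.5 else "benign"
        else:
            group = side
        mu, sigma = config.lr_lognormal_params[group]
        components = tuple(float(x) for x in rng.lognormal(mu, sigma, config.n_lr_components))
        variant_id = f"sim{i + 1:05d}"
        records.append(
            VariantRecord(
                variant_id=variant_id,
                hgvs_c=f"c.{1000 + i}A>G",
                n_patients=int(1 + rng.poisson(1.0)),
                evidence=tuple(codes),
                sge_hap1=hap1,
                sge_mes=mes,
                variant_type="missense",
                lr_components=components,
            )
        )
        truth_rows.append(
            {
                "variant_id": variant_id,
                "true_class": true_class,
                "lr_group": group,
                "forced_discordant": forced,
            }
        )
    return records, pd.DataFrame(truth_rows)


def write_cohort(records: Sequence[VariantRecord], path) -> None:
    """Serialize simulated records to the canonical variant TSV."""
    rows = []
    for rec in records:
        rows.append(
            {
                "variant_id": rec.variant_id,
                "hgvs_c": rec.hgvs_c or "",
                "n_patients": rec.n_patients,
                "evidence": "; ".join(c.label for c in rec.evidence),
                "sge_hap1": rec.sge_hap1.points if rec.sge_hap1 is not None else "",
                "sge_mes": rec.sge_mes.points if rec.sge_mes is not None else "",
                "variant_type": rec.variant_type or "",
                "lr_components": "; ".join(f"{x:.6f}" for x in rec.lr_components)
                if rec.lr_components is not None
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def recovery_report(
    records: Sequence[VariantRecord],
    truth: pd.DataFrame,
    pipeline_result: PipelineResult,
) -> dict:
    """Compare pipeline output against the generator's ground truth.

    Reports the fraction of truth-pathogenic (PV/LPV) variants whose
    combined LR exceeds 1 and of truth-benign (LBV/BV) variants below 1;
    the confusion matrix of post-integration class versus true class;
    per-dataset major/minor/concordance rates of the SGE calls scored
    against the true class; and the observed discordant fraction.
    """
    report = pipeline_result.report
    ids = [rec.variant_id for rec in records]
    if list(truth["variant_id"]) != ids or list(report["variant_id"]) != ids:
        raise ValidationError("records, truth table and pipeline report must share variant ids")

    merged = report.merge(truth, on="variant_id", validate="one_to_one")
    true_side = merged["true_class"].map(_CLASS_SIDE)
    lr = pd.to_numeric(merged["combined_lr"], errors="coerce")

    path_mask = merged["true_class"].isin(["PV", "LPV"])
    benign_mask = merged["true_class"].isin(["LBV", "BV"])
    out: dict = {
        "lr_separation": {
            "pathogenic_gt1": float((lr[path_mask] > 1).mean()) if path_mask.any() else float("nan"),
            "benign_lt1": float((lr[benign_mask] < 1).mean()) if benign_mask.any() else float("nan"),
        },
        "confusion": pd.crosstab(merged["true_class"], merged["post_class"])
        .reindex(index=list(CLASS_LABELS), columns=list(CLASS_LABELS), fill_value=0),
        "discordant_fraction": float((merged["integration_status"] == "discordant").mean()),
    }

    by_id = {rec.variant_id: rec for rec in records}
    for dataset, attr in (("HAP1", "sge_hap1"), ("mES", "sge_mes")):
        categories = [
            agreement_category(side, functional_call(getattr(by_id[vid], attr)))
            for vid, side in zip(merged["variant_id"], true_side)
            if getattr(by_id[vid], attr) is not None
        ]
        if categories:
            summary = rate_summary(categories)
            out[f"{dataset.lower()}_vs_truth"] = {
                "n": summary.n,
                "rates_pct": summary.as_tuple(),
                "major_rate": categories.count("major_error") / len(categories),
            }
    return out
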