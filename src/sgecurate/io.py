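"""Variant-table IO and the end-to-end curation pipeline.

The exchange format is a UTF-8 tab-separated table with a header row.
Required columns: ``evidence`` (semicolon-separated ACMG/AMP tokens) and
an identifier (``variant_id``, falling back to ``hgvs_c``).  Optional
columns: ``hgvs_c``, ``hgvs_p``, ``n_patients``, ``sge_hap1``/``sge_mes``
(level names or signed points), ``gvgd_grade``, ``variant_type``,
``lr_components`` (semicolon-separated) or ``combined_lr``.  Unicode
minus signs (U+2212, as printed in many journals) are accepted on input;
output always uses ASCII.  HGVS strings are treated as opaque
identifiers — no transcript-aware validation is attempted.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import concordance, multifactorial
from .errors import ConfigError, SchemaError, ValidationError
from .evidence import EvidenceCode, parse_evidence_list
from .multifactorial import LR_EXCLUSION_WINDOW, PriorTable
from .sge import SGECategory, apply_integration, functional_call

logger = logging.getLogger("sgecurate")

__all__ = [
    "VariantRecord",
    "PipelineConfig",
    "read_variant_table",
    "write_report",
    "run_pipeline",
    "PipelineResult",
]

_HGVS_C_RE = re.compile(r"^c\.[0-9+*-]")


@dataclass(frozen=True)
class VariantRecord:
    """One row of the variant table, parsed."""

    variant_id: str
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    n_patients: int = 0
    evidence: tuple[EvidenceCode, ...] = field(default_factory=tuple)
    sge_hap1: Optional[SGECategory] = None
    sge_mes: Optional[SGECategory] = None
    gvgd_grade: Optional[str] = None
    variant_type: Optional[str] = None
    lr_components: Optional[tuple[float, ...]] = None
    combined_lr: Optional[float] = None


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline settings (prior table and LR exclusion window)."""

    priors: PriorTable = field(default_factory=PriorTable.default)
    lr_window: tuple[float, float] = LR_EXCLUSION_WINDOW

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
        priors = PriorTable.from_mapping(mapping.get("priors", {})) if "priors" in mapping else PriorTable.default()
        window = tuple(mapping.get("lr_exclusion_window", LR_EXCLUSION_WINDOW))
        if len(window) != 2 or not window[0] <= window[1]:
            raise ConfigError(f"invalid lr_exclusion_window: {window!r}")
        return cls(priors=priors, lr_window=(float(window[0]), float(window[1])))


def _normalize(cell: object) -> str:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ""
    return str(cell).strip().replace("−", "-")


def _parse_row(row: dict) -> VariantRecord:
    def cell(name: str) -> str:
        return _normalize(row.get(name, ""))

    variant_id = cell("variant_id") or cell("hgvs_c")
    try:
        hgvs_c = cell("hgvs_c") or (variant_id if variant_id.startswith("c.") else "")
        if hgvs_c and not _HGVS_C_RE.match(hgvs_c):
            raise ValidationError(f"implausible HGVS c. description: {hgvs_c!r}")
        lr_components_text = cell("lr_components")
        combined_lr_text = cell("combined_lr")
        if lr_components_text and combined_lr_text:
            raise ValidationError("supply either lr_components or combined_lr, not both")
        n_patients_text = cell("n_patients")
        n_patients = int(n_patients_text) if n_patients_text else 0
        if n_patients < 0:
            raise ValidationError(f"n_patients must be >= 0, got {n_patients}")
        return VariantRecord(
            variant_id=variant_id,
            hgvs_c=hgvs_c or None,
            hgvs_p=cell("hgvs_p") or None,
            n_patients=n_patients,
            evidence=tuple(parse_evidence_list(cell("evidence"))),
            sge_hap1=SGECategory.coerce(cell("sge_hap1")) if cell("sge_hap1") else None,
            sge_mes=SGECategory.coerce(cell("sge_mes")) if cell("sge_mes") else None,
            gvgd_grade=cell("gvgd_grade") or None,
            variant_type=cell("variant_type") or None,
            lr_components=tuple(float(x) for x in lr_components_text.split(";") if x.strip())
            if lr_components_text
            else None,
            combined_lr=float(combined_lr_text) if combined_lr_text else None,
        )
    except ValidationError:
        raise
    except ValueError as exc:
        raise ValidationError(f"{variant_id or '?'}: {exc}") from exc


def read_variant_table(path: Union[str, Path]) -> list[VariantRecord]:
    """Read a variant TSV into parsed records.

    Unknown columns are carried along silently (they may hold expected
    values for comparison); blank cells become absent fields.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = frame.where(frame.notna(), "")
    if "variant_id" not in frame.columns and "hgvs_c" not in frame.columns:
        raise SchemaError("variant table needs a 'variant_id' (or 'hgvs_c') column")
    if "evidence" not in frame.columns:
        raise SchemaError("variant table is missing the required 'evidence' column")
    records = []
    for index, row in enumerate(frame.to_dict(orient="records")):
        try:
            record = _parse_row(row)
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {index + 2}: {exc}") from exc
        if not record.variant_id:
            raise ValidationError(f"{path}, row {index + 2}: empty variant identifier")
        records.append(record)
    return records


@dataclass(frozen=True)
class PipelineResult:
    """Per-variant report plus cohort-level summary."""

    report: pd.DataFrame
    summary: dict


def run_pipeline(
    records: Sequence[VariantRecord],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Classify, integrate SGE evidence and (where possible) run the
    multifactorial analysis for every record.

    Per variant the report holds the pre-integration points/class, the
    integration status and any assigned PS3/BS3 code, the
    post-integration points/class, and — when LR inputs are present —
    the combined LR plus, when a prior can be resolved, the posterior
    and IARC class.

    The cohort summary counts class transitions and, over the variants
    whose SGE results are discordant, scores each dataset's functional
    calls against the pre-integration classification (major/minor/
    concordance rates and the Bhapkar comparison of the two datasets).
    """
    if config is None:
        config = PipelineConfig()
    rows = []
    transitions: Counter = Counter()
    discordant_pairs = []
    for rec in records:
        try:
            row: dict = {"variant_id": rec.variant_id}
            has_sge = rec.sge_hap1 is not None and rec.sge_mes is not None
            if has_sge:
                outcome = apply_integration(list(rec.evidence), rec.sge_hap1, rec.sge_mes)
                row.update(
                    pre_points=outcome.pre.total_points,
                    pre_class=outcome.pre.label,
                    integration_status=outcome.evidence.status,
                    assigned_evidence=outcome.evidence.assigned_code.label
                    if outcome.evidence.assigned_code
                    else "",
                    post_points=outcome.post.total_points,
                    post_class=outcome.post.label,
                )
                if outcome.reclassified:
                    transitions[f"{outcome.pre.label}->{outcome.post.label}"] += 1
                logger.debug(
                    "%s: %s -> %s (%s%s)",
                    rec.variant_id,
                    outcome.pre.label,
                    outcome.post.label,
                    outcome.evidence.status,
                    f", assigned {outcome.evidence.assigned_code.label}"
                    if outcome.evidence.assigned_code
                    else "",
                )
                if outcome.evidence.status == "discordant":
                    discordant_pairs.append(
                        (
                            rec.variant_id,
                            concordance.agreement_category(
                                outcome.pre.label, functional_call(rec.sge_hap1)
                            ),
                            concordance.agreement_category(
                                outcome.pre.label, functional_call(rec.sge_mes)
                            ),
                        )
                    )
            else:
                from .evidence import classify_variant

                result = classify_variant(list(rec.evidence))
                row.update(
                    pre_points=result.total_points,
                    pre_class=result.label,
                    integration_status="",
                    assigned_evidence="",
                    post_points=result.total_points,
                    post_class=result.label,
                )

            lr: Optional[float] = None
            if rec.lr_components is not None:
                lr = multifactorial.combine_lr(rec.lr_components)
            elif rec.combined_lr is not None:
                lr = rec.combined_lr
            if lr is not None:
                row["combined_lr"] = lr
                if rec.gvgd_grade or rec.variant_type:
                    prior = config.priors.lookup(rec.gvgd_grade, rec.variant_type)
                    mf = multifactorial.evaluate(prior, combined_lr=lr, window=config.lr_window)
                    row.update(
                        prior=mf.prior,
                        posterior=mf.posterior,
                        iarc_class=mf.iarc if mf.iarc is not None else "NA",
                    )
            rows.append(row)
        except (ValidationError, ConfigError) as exc:
            raise type(exc)(f"variant {rec.variant_id}: {exc}") from exc

    report = pd.DataFrame(rows)
    for column in ("combined_lr", "prior", "posterior", "iarc_class"):
        if column not in report.columns:
            report[column] = ""
    report = report.fillna("")

    summary: dict = {
        "n_variants": len(records),
        "transitions": dict(sorted(transitions.items())),
        "n_assigned_ps3": int((report["assigned_evidence"].astype(str).str.startswith("PS3")).sum()),
        "n_assigned_bs3": int((report["assigned_evidence"].astype(str).str.startswith("BS3")).sum()),
        "n_discordant": len(discordant_pairs),
    }
    if discordant_pairs:
        hap1_categories = [p[1] for p in discordant_pairs]
        mes_categories = [p[2] for p in discordant_pairs]
        table = concordance.crosstab(list(zip(hap1_categories, mes_categories)))
        bhapkar = concordance.bhapkar_test(table)
        summary["discordant_agreement"] = {
            "HAP1": concordance.rate_summary(hap1_categories).as_tuple(),
            "mES": concordance.rate_summary(mes_categories).as_tuple(),
            "bhapkar": {
                "statistic": bhapkar.statistic,
                "df": bhapkar.df,
                "p_value": bhapkar.p_value,
                "pair_table": table.to_numpy().tolist(),
            },
        }
    return PipelineResult(report=report, summary=summary)


_FLOAT_COLUMNS = ("combined_lr", "prior", "posterior")


def write_report(report: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a per-variant report deterministically.

    Probabilities and LRs are emitted at three decimals (the reporting
    precision used throughout); identical inputs produce identical
    bytes.
    """
    out = report.copy()
    for column in _FLOAT_COLUMNS:
        if column in out.columns:
            out[column] = out[column].map(
                lambda v: f"{v:.3f}" if isinstance(v, (int, float)) and v != "" else ""
            )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
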