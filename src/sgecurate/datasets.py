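"""Bundled fixture tables.

Two small TSVs ship with the package:

* ``table1.tsv`` — the 13 BRCA2 variants whose HAP1-SGE and mES-SGE
  functional results disagree, with their ACMG/AMP evidence, point
  totals, classifications, per-dataset SGE points and multifactorial
  results (combined LR, posterior, IARC class where assigned).
* ``table2.tsv`` — the 29 variants of uncertain significance with
  concordant SGE results, with their pre-integration evidence, SGE
  points, and the expected integrated code and final label.

Both are loaded either as raw :class:`pandas.DataFrame` (all printed
columns) or as parsed :class:`~sgecurate.io.VariantRecord` lists.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import VariantRecord, read_variant_table

__all__ = [
    "discordant_variants_frame",
    "concordant_vus_frame",
    "load_discordant_variants",
    "load_concordant_vus",
]


def _fixture_path(name: str):
    return resources.files("sgecurate.data").joinpath(name)


def discordant_variants_frame() -> pd.DataFrame:
    """The discordant-variant table as printed (13 rows)."""
    with resources.as_file(_fixture_path("table1.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")


def concordant_vus_frame() -> pd.DataFrame:
    """The concordant-VUS reassessment table as printed (29 rows)."""
    with resources.as_file(_fixture_path("table2.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")


def load_discordant_variants() -> list[VariantRecord]:
    """Parsed records for the 13 discordant variants."""
    with resources.as_file(_fixture_path("table1.tsv")) as path:
        return read_variant_table(path)


def load_concordant_vus() -> list[VariantRecord]:
    """Parsed records for the 29 concordant VUS."""
    with resources.as_file(_fixture_path("table2.tsv")) as path:
        return read_variant_table(path)
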