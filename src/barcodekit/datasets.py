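"""Packaged transcriptions of the study's in-text tables.

Three small TSVs ship with the package:

* the 98-specimen morphological/molecular label table (with the original
  table's flag marking specimens whose field identification was ambiguous
  or overturned);
* the two occurrence lists (historical records vs survey results) by
  family;
* the per-species interspecific/intraspecific K2P divergence table.

Labels are stored as printed — including stray parentheses and a year
typo — because the concordance classifier is expected to cope with real
tables, not sanitised ones.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .gap import GapRow
from .identify import parse_species_label

__all__ = ["table1_fixture", "occurrence_fixture", "divergence_fixture"]

_DATA = files("barcodekit") / "data"


def table1_fixture() -> pd.DataFrame:
    """The 98-row specimen table: id, labels, station, depth, flag."""
    df = pd.read_csv(str(_DATA / "table1_concordance.tsv"), sep="\t", dtype=str)
    df["flagged"] = df["flagged"].astype(int).astype(bool)
    return df


def occurrence_fixture() -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """(historical, survey) occurrence lists as (family, species_label) pairs."""
    df = pd.read_csv(str(_DATA / "table2_occurrence.tsv"), sep="\t", dtype=str)
    historical = [
        (r.family, r.species_label)
        for r in df[df.source == "historical"].itertuples()
    ]
    chinare = [
        (r.family, r.species_label)
        for r in df[df.source == "chinare"].itertuples()
    ]
    return historical, chinare


def divergence_fixture() -> list[GapRow]:
    """Per-species divergence rows (percent), with specimen counts.

    Divergences come from the packaged per-species table (fractions in the
    file, converted to percent here); the per-species specimen counts are
    derived from the specimen table's molecular labels. Species without an
    intraspecific entry (printed NA) carry None.
    """
    div = pd.read_csv(
        str(_DATA / "table4_divergence.tsv"), sep="\t", na_values=["NA"]
    )
    labels = table1_fixture()["molecular_label"]
    counts = labels.map(lambda s: parse_species_label(s).binomial).value_counts()
    rows = []
    for r in div.itertuples():
        rows.append(
            GapRow(
                species=r.species,
                n=int(counts.get(r.species, 0)),
                min_inter=100.0 * r.min_inter,
                mean_inter=100.0 * r.mean_inter,
                max_intra=None if pd.isna(r.max_intra) else 100.0 * r.max_intra,
                mean_intra=None if pd.isna(r.mean_intra) else 100.0 * r.mean_intra,
            )
        )
    return rows
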