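"""Reading and writing aligned barcode datasets.

A dataset is a FASTA alignment of equal-length barcode fragments plus a
tab-separated metadata table keyed by specimen id. Records keep the FASTA
order, which downstream stages rely on for deterministic output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "AlignmentLengthError",
    "MissingMetadataError",
    "read_dataset",
    "write_dataset",
    "alignment_length",
]

#: metadata columns in their canonical file order
METADATA_COLUMNS = [
    "specimen_id",
    "morphological_label",
    "genus",
    "family",
    "station",
    "depth_m",
]

_VALID_CHARS = set("ACGTRYSWKMBDHVN-")


class AlignmentLengthError(ValueError):
    """Sequences in one dataset do not share a single alignment length."""


class MissingMetadataError(KeyError):
    """A FASTA record has no row in the metadata table."""

    def __init__(self, specimen_id: str):
        super().__init__(specimen_id)
        self.specimen_id = specimen_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"no metadata row for specimen id {self.specimen_id!r}"


@dataclass
class BarcodeRecord:
    """One aligned barcode fragment with its taxonomy and haul metadata.

    ``morphological_label`` is the field identification (a binomial, or a
    genus-level "Genus sp." form); ``molecular_label`` is filled in once a
    reference-based identification has been made.
    """

    specimen_id: str
    sequence: str
    morphological_label: str = ""
    molecular_label: Optional[str] = None
    genus: str = ""
    family: str = ""
    station: Optional[str] = None
    depth_m: Optional[float] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"record {self.specimen_id!r} contains non-nucleotide "
                f"characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def alignment_length(records: list[BarcodeRecord]) -> int:
    """Common sequence length of ``records``; raises if lengths differ."""
    if not records:
        raise ValueError("empty record list")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise AlignmentLengthError(
            f"mixed sequence lengths in one dataset: {sorted(lengths)}"
        )
    return lengths.pop()


def _coerce_depth(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    depth = float(value)
    if depth < 0:
        raise ValueError(f"negative depth_m: {depth}")
    return depth


def read_dataset(fasta_path: str | Path, metadata_path: str | Path) -> list[BarcodeRecord]:
    """Read a FASTA alignment and its metadata table into BarcodeRecords.

    Records come back in FASTA order. Every FASTA id must have a metadata
    row; all sequences must share one alignment length; specimen ids must
    be unique.
    """
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not seqs:
        raise ValueError(f"no FASTA records in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = {"specimen_id", "morphological_label"} - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata lacks required columns: {sorted(missing_cols)}")
    if meta["specimen_id"].duplicated().any():
        dups = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen ids in metadata: {dups}")
    rows = meta.set_index("specimen_id")

    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for rec in seqs:
        sid = rec.id
        if sid in seen:
            raise ValueError(f"duplicate specimen id in FASTA: {sid!r}")
        seen.add(sid)
        if sid not in rows.index:
            raise MissingMetadataError(sid)
        row = rows.loc[sid]
        records.append(
            BarcodeRecord(
                specimen_id=sid,
                sequence=str(rec.seq),
                morphological_label=row.get("morphological_label", ""),
                molecular_label=row.get("molecular_label") or None,
                genus=row.get("genus", ""),
                family=row.get("family", ""),
                station=row.get("station") or None,
                depth_m=_coerce_depth(row.get("depth_m")),
            )
        )
    alignment_length(records)  # raises on mixed lengths
    return records


def write_dataset(
    records: list[BarcodeRecord],
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write records to FASTA + metadata TSV (inverse of :func:`read_dataset`)."""
    alignment_length(records)
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "morphological_label": r.morphological_label,
                "molecular_label": r.molecular_label or "",
                "genus": r.genus,
                "family": r.family,
                "station": r.station or "",
                "depth_m": "" if r.depth_m is None else r.depth_m,
            }
        )
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)
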