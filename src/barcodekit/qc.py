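"""Barcode quality control and alignment-level statistics.

Protein-coding barcodes from functional mitochondrial genes carry no
internal stop codons in their reading frame; gaps or stops are the classic
signature of a pseudogene (numt) or an alignment problem. QC here checks
each sequence under the vertebrate mitochondrial genetic code
(NCBI translation table 2, where AGA/AGG are stops in addition to TAA/TAG)
and auto-detects the frame when it is not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .seqio import BarcodeRecord, alignment_length

__all__ = [
    "QCReport",
    "AlignmentStats",
    "check_coding_integrity",
    "alignment_stats",
    "MITO_STOP_CODONS",
]

#: stop codons of the vertebrate mitochondrial code (table 2)
MITO_STOP_CODONS = frozenset(
    CodonTable.unambiguous_dna_by_id[2].stop_codons
)

_UNAMBIGUOUS = "ACGT"


@dataclass(frozen=True)
class QCReport:
    specimen_id: str
    length: int
    has_gap: bool
    has_internal_stop: bool
    chosen_frame: int
    ambiguous_site_count: int


@dataclass(frozen=True)
class AlignmentStats:
    """Composition and site-variability summary of one alignment.

    ``base_percent`` holds the per-sequence mean percentage of each
    unambiguous base; ambiguity codes and gaps are excluded from the
    denominator, so the four values sum to 100.
    """

    base_percent: dict[str, float]
    polymorphic_sites: int
    parsimony_informative_sites: int
    length: int


def _internal_stop_count(sequence: str, frame: int) -> int:
    """Stops among complete codons in ``frame``.

    A terminal stop whose codon ends exactly at the sequence end is not
    counted: a genuine terminator is not an abnormality, and mid-gene
    fragments never reach one anyway.
    """
    n = 0
    seq_len = len(sequence)
    for start in range(frame, seq_len - 2, 3):
        codon = sequence[start : start + 3]
        if codon in MITO_STOP_CODONS and start + 3 < seq_len:
            n += 1
    return n


def check_coding_integrity(record: BarcodeRecord, frame: Optional[int] = None) -> QCReport:
    """Report gaps, ambiguities and internal stop codons for one record.

    If ``frame`` is None the frame minimising internal stops is chosen,
    ties broken by the lowest frame index. Codons containing gaps or
    ambiguity codes never match a stop codon and are effectively skipped.
    """
    seq = record.sequence
    if not seq:
        raise ValueError(f"record {record.specimen_id!r} has an empty sequence")
    if frame is None:
        stops_by_frame = [_internal_stop_count(seq, f) for f in (0, 1, 2)]
        chosen = int(np.argmin(stops_by_frame))  # argmin keeps lowest index on ties
        n_stops = stops_by_frame[chosen]
    else:
        if frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
        chosen = frame
        n_stops = _internal_stop_count(seq, frame)
    return QCReport(
        specimen_id=record.specimen_id,
        length=len(seq),
        has_gap="-" in seq,
        has_internal_stop=n_stops > 0,
        chosen_frame=chosen,
        ambiguous_site_count=sum(c not in "ACGT-" for c in seq),
    )


def alignment_stats(records: list[BarcodeRecord]) -> AlignmentStats:
    """Base composition, polymorphic and parsimony-informative site counts.

    A column is polymorphic when it holds at least two distinct unambiguous
    bases, and parsimony informative when at least two distinct bases each
    occur in at least two sequences. Ambiguity codes and gaps are treated
    as missing throughout.
    """
    if len(records) < 2:
        raise ValueError("alignment_stats needs at least two records")
    length = alignment_length(records)

    mat = np.array([list(r.sequence) for r in records])
    # per-sequence composition over unambiguous sites, then mean across sequences
    percents = {}
    counts = np.stack([(mat == b).sum(axis=1) for b in _UNAMBIGUOUS], axis=1)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a sequence has no unambiguous bases")
    per_seq = 100.0 * counts / totals[:, None]
    for j, b in enumerate(_UNAMBIGUOUS):
        percents[b] = float(per_seq[:, j].mean())

    polymorphic = 0
    informative = 0
    for col in mat.T:
        vals, n = np.unique(col[np.isin(col, list(_UNAMBIGUOUS))], return_counts=True)
        if len(vals) >= 2:
            polymorphic += 1
            if (n >= 2).sum() >= 2:
                informative += 1
    return AlignmentStats(
        base_percent=percents,
        polymorphic_sites=polymorphic,
        parsimony_informative_sites=informative,
        length=length,
    )
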