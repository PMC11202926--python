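"""Kimura two-parameter distances and divergence summaries.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T) from transversions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the observed transition and transversion proportions over the
sites comparable in a pair (pairwise deletion of gaps and ambiguity codes).
The estimator is undefined ("saturated") when 1 - 2P - Q <= 0 or
1 - 2Q <= 0; such pairs are flagged rather than silently dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import BarcodeRecord, alignment_length

__all__ = [
    "PairCounts",
    "DistanceMatrix",
    "RankSummary",
    "UndefinedDistanceError",
    "count_site_patterns",
    "k2p",
    "p_distance",
    "distance_matrix",
    "rank_summaries",
    "species_label",
    "write_matrix",
    "read_matrix",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = (0, 2)  # A, G

Rank = Literal["within_species", "within_genus", "within_family"]


class UndefinedDistanceError(ValueError):
    """K2P distance undefined: no comparable sites or saturated divergence."""


@dataclass(frozen=True)
class PairCounts:
    """Comparable-site count and observed substitution proportions of a pair."""

    compared_sites: int
    P: float  # transition proportion
    Q: float  # transversion proportion


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to int codes: A,C,G,T -> 0..3; gap/ambiguity -> -1."""
    out = np.full(len(sequence), -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = code
    return out


def _pair_counts_encoded(a: np.ndarray, b: np.ndarray) -> PairCounts:
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites in pair")
    av, bv = a[valid], b[valid]
    diff = av != bv
    same_class = np.isin(av, _PURINES) == np.isin(bv, _PURINES)
    transitions = int((diff & same_class).sum())
    transversions = int((diff & ~same_class).sum())
    return PairCounts(n, transitions / n, transversions / n)


def count_site_patterns(a: str, b: str) -> PairCounts:
    """Count comparable sites, transitions and transversions for a pair.

    Sites where either sequence holds a gap or ambiguity code are excluded
    (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    return _pair_counts_encoded(encode(a.upper()), encode(b.upper()))


def k2p(counts: PairCounts) -> float:
    """K2P distance (as a fraction) from observed pair counts."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise UndefinedDistanceError(
            f"saturated pair: P={counts.P:.4f}, Q={counts.Q:.4f}"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(counts: PairCounts) -> float:
    """Uncorrected proportion of differing comparable sites."""
    return counts.P + counts.Q


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distance matrix over specimens.

    Distances are fractions; undefined (saturated) entries are NaN.
    ``compared_sites[i, j]`` records the pairwise-deletion site count.
    """

    ids: list[str]
    d: np.ndarray
    compared_sites: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if self.compared_sites is None:
            self.compared_sites = np.zeros((n, n), dtype=int)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isnan(self.d))
        return [(self.ids[a], self.ids[b]) for a, b in zip(i, j) if a < b]

    def pair(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.ids.index(id_a), self.ids.index(id_b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]


def distance_matrix(records: Sequence[BarcodeRecord]) -> DistanceMatrix:
    """All-pairs K2P distances with pairwise deletion; saturated pairs -> NaN."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    alignment_length(list(records))
    coded = [encode(r.sequence) for r in records]
    n = len(records)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = int((coded[i] >= 0).sum())
        for j in range(i + 1, n):
            counts = _pair_counts_encoded(coded[i], coded[j])
            sites[i, j] = sites[j, i] = counts.compared_sites
            try:
                dij = k2p(counts)
            except UndefinedDistanceError:
                dij = np.nan
            d[i, j] = d[j, i] = dij
    return DistanceMatrix([r.specimen_id for r in records], d, sites)


@dataclass(frozen=True)
class RankSummary:
    """Percent K2P divergence summary for one taxonomic comparison level."""

    rank: Rank
    n_pairs: int
    max: float
    min: float
    mean: float
    se: float


def species_label(record: BarcodeRecord) -> str:
    """Species assignment of a record: molecular label when present."""
    return record.molecular_label or record.morphological_label


def _pair_rank(a: BarcodeRecord, b: BarcodeRecord) -> Optional[Rank]:
    if species_label(a) == species_label(b):
        return "within_species"
    if a.genus and a.genus == b.genus:
        return "within_genus"
    if a.family and a.family == b.family:
        return "within_family"
    return None


def rank_summaries(
    m: DistanceMatrix, taxonomy: Sequence[BarcodeRecord]
) -> list[RankSummary]:
    """Divergence summaries per taxonomic level, in percent.

    Each pair contributes to exactly one level — its lowest shared rank:
    conspecific pairs to within_species, congeneric heterospecific to
    within_genus, confamilial heterogeneric to within_family. Pairs sharing
    no family, and saturated (NaN) pairs, are excluded; excluded saturated
    pairs raise a warning. SE is the standard error of the mean over pairs.
    """
    by_id = {r.specimen_id: r for r in taxonomy}
    missing = [i for i in m.ids if i not in by_id]
    if missing:
        raise ValueError(f"taxonomy lacks records for: {missing}")
    buckets: dict[Rank, list[float]] = {
        "within_species": [],
        "within_genus": [],
        "within_family": [],
    }
    n_undefined = 0
    n = len(m.ids)
    for i in range(n):
        for j in range(i + 1, n):
            rank = _pair_rank(by_id[m.ids[i]], by_id[m.ids[j]])
            if rank is None:
                continue
            dij = m.d[i, j]
            if np.isnan(dij):
                n_undefined += 1
                continue
            buckets[rank].append(dij)
    if n_undefined:
        warnings.warn(
            f"{n_undefined} saturated pair(s) excluded from rank summaries",
            stacklevel=2,
        )
    out = []
    for rank, vals in buckets.items():
        if not vals:
            continue
        arr = 100.0 * np.asarray(vals)
        se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        out.append(
            RankSummary(
                rank=rank,
                n_pairs=len(arr),
                max=float(arr.max()),
                min=float(arr.min()),
                mean=float(arr.mean()),
                se=se,
            )
        )
    return out


def write_matrix(m: DistanceMatrix, path: str | Path) -> None:
    """Square tab-separated matrix with id header row and column."""
    pd.DataFrame(m.d, index=m.ids, columns=m.ids).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError("matrix row ids differ from column ids")
    return DistanceMatrix(ids, df.to_numpy(dtype=float))
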