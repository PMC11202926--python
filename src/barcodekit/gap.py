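"""Barcoding-gap analysis and distance-threshold species partitioning.

Two questions are asked of a barcode distance matrix. First, is there a
usable barcoding gap — are conspecific divergences well separated from
heterospecific ones? The classic operational criterion requires mean
interspecific divergence at least ten times the mean intraspecific
divergence, plus no species whose intraspecific spread reaches into
another's nearest-neighbour distance. Second, what species partition does
the distance structure itself suggest? A single-linkage threshold sweep
enumerates every candidate partition and ranks them by the relative width
of the distance gap each threshold sits in — a deliberately simple,
fully deterministic take on automatic gap-based partitioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .distances import DistanceMatrix

__all__ = [
    "GapRow",
    "GapVerdict",
    "Partition",
    "SplitLumpReport",
    "gap_table",
    "tenfold_criterion",
    "overlap_report",
    "threshold_sweep",
    "split_lump_report",
]


@dataclass(frozen=True)
class GapRow:
    """Per-species divergence summary (percent K2P).

    ``min_inter`` is the distance to the nearest heterospecific specimen;
    ``mean_inter`` the mean over all heterospecific pairs. Intraspecific
    fields are None for singletons. ``nearest_neighbor`` names the species
    of the closest heterospecific specimen (lexicographic on ties).
    """

    species: str
    n: int
    min_inter: float
    mean_inter: float
    max_intra: Optional[float]
    mean_intra: Optional[float]
    nearest_neighbor: Optional[str] = None


@dataclass(frozen=True)
class GapVerdict:
    """Outcome of the barcoding-gap test over a set of per-species rows."""

    ratio: float
    passes_tenfold: bool
    overlaps: tuple[tuple[str, str], ...]
    gap_valid: bool
    indeterminate: bool = False


@dataclass(frozen=True)
class Partition:
    """A specimen-to-unit assignment from one clustering threshold."""

    assignment: Mapping[str, int]
    n_units: int
    threshold: float
    gap_score: float


@dataclass(frozen=True)
class SplitLumpReport:
    """Species split across units, and units lumping several species."""

    splits: Mapping[str, tuple[int, ...]]
    lumps: Mapping[int, tuple[str, ...]]

    @property
    def concordant(self) -> bool:
        return not self.splits and not self.lumps


def _check_labels(m: DistanceMatrix, species_labels: Mapping[str, str]) -> list[str]:
    missing = [i for i in m.ids if i not in species_labels]
    if missing:
        raise ValueError(f"species labels missing for: {missing}")
    return [species_labels[i] for i in m.ids]


def gap_table(m: DistanceMatrix, species_labels: Mapping[str, str]) -> list[GapRow]:
    """One row per species: nearest-neighbour and mean inter/intra divergence.

    Values in percent. Saturated (NaN) pairs are excluded. Requires at
    least two species; rows are sorted by species name.
    """
    labels = np.array(_check_labels(m, species_labels))
    species = sorted(set(labels))
    if len(species) < 2:
        raise ValueError("gap_table needs at least two species (no interspecific pairs)")
    rows = []
    for sp in species:
        mask = labels == sp
        inter_block = m.d[np.ix_(mask, ~mask)]
        inter = inter_block[~np.isnan(inter_block)]
        if inter.size == 0:
            raise ValueError(f"species {sp!r} has no defined interspecific distances")
        # nearest heterospecific specimen and its species (lexicographic ties)
        flat = np.nanmin(inter_block)
        other_labels = labels[~mask]
        at_min = np.where(np.isclose(inter_block, flat))[1]
        neighbor = min(other_labels[k] for k in at_min)
        intra_block = m.d[np.ix_(mask, mask)]
        iu = np.triu_indices(int(mask.sum()), k=1)
        intra = intra_block[iu]
        intra = intra[~np.isnan(intra)]
        rows.append(
            GapRow(
                species=sp,
                n=int(mask.sum()),
                min_inter=100.0 * float(flat),
                mean_inter=100.0 * float(inter.mean()),
                max_intra=100.0 * float(intra.max()) if intra.size else None,
                mean_intra=100.0 * float(intra.mean()) if intra.size else None,
                nearest_neighbor=neighbor,
            )
        )
    return rows


def tenfold_criterion(
    mean_inter: float, mean_intra: float, ratio_required: float = 10.0
) -> tuple[float, bool]:
    """Ratio of mean interspecific to mean intraspecific divergence.

    Passes when the ratio reaches ``ratio_required`` (default 10). A zero
    intraspecific mean passes with an infinite ratio.
    """
    if mean_inter < 0 or mean_intra < 0:
        raise ValueError("divergence means must be non-negative")
    if mean_intra == 0:
        return math.inf, True
    ratio = mean_inter / mean_intra
    return ratio, ratio >= ratio_required


def overlap_report(
    rows: Sequence[GapRow],
    ratio_required: float = 10.0,
    intra_weighting: str = "pairs",
) -> GapVerdict:
    """Gap verdict over per-species rows: 10x ratio plus overlap scan.

    An overlap is any ordered species pair (i, j), i == j allowed, where
    the intraspecific spread of i reaches past the nearest-neighbour
    distance of j (max_intra_i > min_inter_j). The ratio compares the mean
    of per-species nearest-neighbour distances against the mean
    intraspecific divergence, the latter weighted per conspecific pair
    (``intra_weighting="pairs"``) or per species (``"species"``). With no
    multi-specimen species the verdict is indeterminate.
    """
    if len(rows) < 2:
        raise ValueError("overlap_report needs at least two rows")
    mean_min_inter = float(np.mean([r.min_inter for r in rows]))
    with_intra = [r for r in rows if r.mean_intra is not None]
    if not with_intra:
        return GapVerdict(math.nan, False, (), False, indeterminate=True)
    if intra_weighting == "pairs":
        weights = np.array([r.n * (r.n - 1) / 2 for r in with_intra])
        mean_intra = float(
            np.average([r.mean_intra for r in with_intra], weights=weights)
        )
    elif intra_weighting == "species":
        mean_intra = float(np.mean([r.mean_intra for r in with_intra]))
    else:
        raise ValueError(f"unknown intra_weighting {intra_weighting!r}")
    ratio, passes = tenfold_criterion(mean_min_inter, mean_intra, ratio_required)
    overlaps = []
    for ri in rows:
        if ri.max_intra is None:
            continue
        for rj in rows:
            if ri.max_intra > rj.min_inter:
                overlaps.append((ri.species, rj.species))
    overlaps.sort()
    return GapVerdict(
        ratio=ratio,
        passes_tenfold=passes,
        overlaps=tuple(overlaps),
        gap_valid=passes and not overlaps,
    )


def _gap_score(d: np.ndarray, units: np.ndarray, resolution: float) -> float:
    """Relative width of the empty distance interval separating within-unit
    from between-unit distances; 0 when either side has no pairs.

    ``d_lo`` is floored at ``resolution`` (the smallest nonzero pairwise
    distance): distances are quantised by substitution counts, so a gap
    bounded below by less than one substitution carries no evidence and
    would otherwise hand degenerate near-singleton partitions a perfect
    score whenever two conspecific sequences happen to be identical.
    """
    same = units[:, None] == units[None, :]
    iu = np.triu_indices(len(units), k=1)
    within = d[iu][same[iu]]
    between = d[iu][~same[iu]]
    if within.size == 0 or between.size == 0:
        return 0.0
    d_lo = max(float(within.max()), resolution)
    d_hi = float(between.min())
    if d_hi <= 0:
        return 0.0
    return (d_hi - d_lo) / d_hi


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels to contiguous ints in order of appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for k, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[k] = mapping[lab]
    return out


def threshold_sweep(m: DistanceMatrix) -> list[Partition]:
    """Enumerate single-linkage partitions over all candidate thresholds.

    Candidate thresholds are the midpoints between consecutive distinct
    single-linkage merge heights, plus one below the smallest and one above
    the largest height. Duplicate partitions are dropped; the result is
    ranked by gap_score descending, ties broken by fewer units. Partitions
    are nested: a higher threshold never splits a unit formed at a lower one.
    """
    if len(m) < 2:
        raise ValueError("threshold_sweep needs at least two specimens")
    cond = m.condensed()
    if np.isnan(cond).any():
        raise ValueError(
            f"undefined distances present: {m.undefined_pairs}"
        )
    Z = linkage(cond, method="single")
    nonzero = cond[cond > 0]
    resolution = float(nonzero.min()) if nonzero.size else 0.0
    heights = np.unique(Z[:, 2])
    candidates = [heights[0] / 2.0 if heights[0] > 0 else -1.0]
    candidates += [(a + b) / 2.0 for a, b in zip(heights[:-1], heights[1:])]
    candidates.append(heights[-1] + max(heights[-1], 1.0))
    seen: set[tuple[int, ...]] = set()
    partitions = []
    for t in candidates:
        units = _canonical(fcluster(Z, t=t, criterion="distance"))
        key = tuple(units)
        if key in seen:
            continue
        seen.add(key)
        partitions.append(
            Partition(
                assignment=dict(zip(m.ids, (int(u) for u in units))),
                n_units=int(units.max()) + 1,
                threshold=float(t),
                gap_score=_gap_score(m.d, units, resolution),
            )
        )
    partitions.sort(key=lambda p: (-p.gap_score, p.n_units))
    return partitions


def split_lump_report(
    p: Partition, species_labels: Mapping[str, str]
) -> SplitLumpReport:
    """Compare a molecular partition against nominal species labels.

    Splits: species whose specimens land in more than one unit. Lumps:
    units containing specimens of more than one species.
    """
    missing = [i for i in p.assignment if i not in species_labels]
    if missing:
        raise ValueError(f"species labels missing for: {missing}")
    by_species: dict[str, set[int]] = {}
    by_unit: dict[int, set[str]] = {}
    for sid, unit in p.assignment.items():
        sp = species_labels[sid]
        by_species.setdefault(sp, set()).add(unit)
        by_unit.setdefault(unit, set()).add(sp)
    splits = {
        sp: tuple(sorted(units)) for sp, units in sorted(by_species.items())
        if len(units) > 1
    }
    lumps = {
        unit: tuple(sorted(sps)) for unit, sps in sorted(by_unit.items())
        if len(sps) > 1
    }
    return SplitLumpReport(splits=splits, lumps=lumps)
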