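"""Reference-library identification and taxonomic concordance.

Queries are matched against a local library of labelled, aligned barcodes
by percent identity (1 - p-distance over pairwise-deleted sites); a match
at or above the threshold — 98% by default — counts as identified.

Concordance between a field (morphological) identification and the
molecular one is classified per specimen:

* ``matched`` — same genus and species epithet;
* ``refined`` — the field label was genus-level only ("Genus sp.") and the
  molecular label is a congeneric binomial, i.e. molecular taxonomy added
  resolution;
* ``invalid`` — anything else: the field identification is contradicted.

Label parsing strips taxonomic authority strings ("(Regan, 1913)",
"Günther, 1878") and tolerates the stray punctuation that real specimen
tables contain.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .distances import count_site_patterns, p_distance

__all__ = [
    "ParsedLabel",
    "LabelParseError",
    "ReferenceHit",
    "ConcordanceRecord",
    "ConcordanceSummary",
    "OccurrenceOverlap",
    "parse_species_label",
    "identify",
    "classify_concordance",
    "classify_records",
    "concordance_summary",
    "occurrence_overlap",
]

_GENUS_RE = re.compile(r"^[A-Z][a-zä-ü]+$")
_EPITHET_RE = re.compile(r"^[a-zä-ü]+(-[a-zä-ü]+)?$")
_SP_RE = re.compile(r"^spp?\.?(\d+)?$")


class LabelParseError(ValueError):
    def __init__(self, label: str):
        super().__init__(f"cannot parse taxonomic label: {label!r}")
        self.label = label


@dataclass(frozen=True)
class ParsedLabel:
    """Genus and (optional) species epithet of a cleaned taxonomic label."""

    genus: str
    epithet: Optional[str]

    @property
    def is_binomial(self) -> bool:
        return self.epithet is not None

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.epithet}" if self.epithet else f"{self.genus} sp."


def parse_species_label(label: str) -> ParsedLabel:
    """Extract genus and epithet, discarding authorities and punctuation.

    Genus-level labels ("Bathylagus sp.", "Coryphaenoides sp.2",
    "Trematomus spp.") yield epithet None. Authority surnames are
    capitalised and therefore never mistaken for epithets.
    """
    cleaned = re.sub(r"\s+", " ", label.replace("*", " ")).strip()
    tokens = [t.strip("(),;") for t in cleaned.split()]
    tokens = [t for t in tokens if t]
    genus: Optional[str] = None
    epithet: Optional[str] = None
    for tok in tokens:
        if genus is None:
            if _GENUS_RE.match(tok):
                genus = tok
            continue
        if _SP_RE.match(tok):
            break  # genus-level label; stop before trailing numerals
        if _EPITHET_RE.match(tok):
            epithet = tok
            break
    if genus is None:
        raise LabelParseError(label)
    return ParsedLabel(genus=genus, epithet=epithet)


@dataclass(frozen=True)
class ReferenceHit:
    query_id: str
    best_reference_label: str
    identity: float  # percent
    status: str  # "identified" | "unidentified"


def identify(
    query: str,
    references: Iterable[tuple[str, str]],
    threshold: float = 98.0,
    query_id: str = "query",
) -> ReferenceHit:
    """Best reference match by percent identity over comparable sites.

    ``references`` is an iterable of (label, aligned sequence) pairs of
    the query's alignment length. Ties on identity go to the
    lexicographically smallest label. Status is "identified" when the best
    identity reaches ``threshold`` (percent).
    """
    best: Optional[tuple[float, str]] = None
    n_refs = 0
    for label, seq in references:
        n_refs += 1
        identity = 100.0 * (1.0 - p_distance(count_site_patterns(query, seq)))
        if best is None or identity > best[0] or (
            identity == best[0] and label < best[1]
        ):
            best = (identity, label)
    if n_refs == 0:
        raise ValueError("empty reference set")
    identity, label = best
    return ReferenceHit(
        query_id=query_id,
        best_reference_label=label,
        identity=identity,
        status="identified" if identity >= threshold else "unidentified",
    )


@dataclass(frozen=True)
class ConcordanceRecord:
    specimen_id: str
    morph_label: str
    mol_label: str
    klass: str  # "matched" | "refined" | "invalid"


def classify_concordance(morph_label: str, mol_label: str) -> str:
    """Classify a morphological/molecular label pair (rules in module docs)."""
    morph = parse_species_label(morph_label)
    mol = parse_species_label(mol_label)
    if morph.is_binomial and mol.is_binomial and morph == mol:
        return "matched"
    if not morph.is_binomial and mol.is_binomial and morph.genus == mol.genus:
        return "refined"
    return "invalid"


def classify_records(
    rows: Iterable[tuple[str, str, str]]
) -> list[ConcordanceRecord]:
    """Classify (specimen_id, morph_label, mol_label) triples."""
    return [
        ConcordanceRecord(sid, morph, mol, classify_concordance(morph, mol))
        for sid, morph, mol in rows
    ]


@dataclass(frozen=True)
class ConcordanceSummary:
    n: int
    counts: dict[str, int]
    percent: dict[str, float]  # of n, rounded to 2 decimals


def concordance_summary(records: Sequence[ConcordanceRecord]) -> ConcordanceSummary:
    """Counts and percentages per concordance class."""
    if not records:
        raise ValueError("no concordance records")
    counts = Counter(r.klass for r in records)
    n = len(records)
    out_counts = {k: counts.get(k, 0) for k in ("matched", "refined", "invalid")}
    return ConcordanceSummary(
        n=n,
        counts=out_counts,
        percent={k: round(100.0 * v / n, 2) for k, v in out_counts.items()},
    )


@dataclass(frozen=True)
class OccurrenceOverlap:
    """Shared taxa between two occurrence lists, per rank."""

    shared_species: frozenset[str]
    shared_genera: frozenset[str]
    shared_families: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "species": len(self.shared_species),
            "genera": len(self.shared_genera),
            "families": len(self.shared_families),
        }


def _rank_sets(entries: Iterable[tuple[str, str]]):
    species, genera, families = set(), set(), set()
    for family, label in entries:
        parsed = parse_species_label(label)
        families.add(family)
        genera.add(parsed.genus)
        if parsed.is_binomial:
            species.add(parsed.binomial)
        # genus-level ("sp."/"spp.") entries count at genus rank only
    return species, genera, families


def occurrence_overlap(
    list_a: Iterable[tuple[str, str]], list_b: Iterable[tuple[str, str]]
) -> OccurrenceOverlap:
    """Shared species, genera and families between two occurrence lists.

    Entries are (family, species_label) pairs; labels may be binomials or
    genus-level "Genus sp(p)." forms. Species are shared by exact binomial;
    a genus-level entry matches congeners at the genus rank only.
    """
    sp_a, gen_a, fam_a = _rank_sets(list_a)
    sp_b, gen_b, fam_b = _rank_sets(list_b)
    return OccurrenceOverlap(
        shared_species=frozenset(sp_a & sp_b),
        shared_genera=frozenset(gen_a & gen_b),
        shared_families=frozenset(fam_a & fam_b),
    )
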