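"""Conservation classification against a reference mature-miRNA catalog.

A locus is *conserved* if its mature sequence (allowing +/-1 nt end
variants taken from the precursor context and up to ``max_mismatch``
ungapped mismatches) matches any catalog entry outside the focal clade,
*clade-specific* if it only matches entries from other species of the
focal clade, and *species-specific* if it matches nothing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .types import MirnaLocus

CLASSES = ("conserved", "clade_specific", "species_specific")


@dataclass(frozen=True)
class CatalogEntry:
    mature: str      # DNA alphabet, uppercase
    name: str        # family-style name, e.g. "miR397"
    species: str


@dataclass
class ReferenceCatalog:
    entries: list[CatalogEntry]
    clade_map: dict[str, str]
    focal_clade: str

    def __post_init__(self) -> None:
        self.entries = [CatalogEntry(e.mature.upper().replace("U", "T"),
                                     e.name, e.species) for e in self.entries]
        missing = {e.species for e in self.entries} - set(self.clade_map)
        if missing:
            raise ValueError(f"species without clade label: {sorted(missing)}")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def query_variants(locus: MirnaLocus, flank: int = 1) -> set[str]:
    """The mature sequence plus all end extensions/truncations/shifts by
    up to ``flank`` nt drawn from the precursor context."""
    pre = locus.precursor_seq
    if locus.precursor.strand == locus.mature.strand == "+":
        off = locus.mature.start - locus.precursor.start
    else:
        off = locus.precursor.end - locus.mature.end
    m = len(locus.mature_seq)
    out = set()
    for d5 in range(-flank, flank + 1):
        for d3 in range(-flank, flank + 1):
            lo, hi = off + d5, off + m + d3
            if 0 <= lo < hi <= len(pre):
                out.add(pre[lo:hi])
    return out


def classify(locus: MirnaLocus, catalog: ReferenceCatalog,
             flank: int = 1, max_mismatch: int = 2,
             rename_family: bool = True) -> tuple[str, list[str]]:
    """Classify one locus; returns (class, matched catalog family names).

    With ``rename_family`` the locus family is renamed to the best-matching
    known family (fewest mismatches; alphabetical tie-break).
    """
    if not catalog.entries:
        warnings.warn("empty reference catalog: everything is species-specific")
        locus.conservation_class = "species_specific"
        return "species_specific", []
    queries = query_variants(locus, flank)
    hits: list[tuple[int, CatalogEntry]] = []
    for entry in catalog.entries:
        best = min((_hamming(q, entry.mature) for q in queries
                    if len(q) == len(entry.mature)), default=None)
        if best is not None and best <= max_mismatch:
            hits.append((best, entry))
    if not hits:
        cls: str = "species_specific"
    elif all(catalog.clade_map[e.species] == catalog.focal_clade for _, e in hits):
        cls = "clade_specific"
    else:
        cls = "conserved"
    matched = sorted({e.name for _, e in hits})
    locus.conservation_class = cls
    locus.matched_families = matched
    if rename_family and hits:
        best_mm = min(h[0] for h in hits)
        locus.family = sorted(e.name for mm, e in hits if mm == best_mm)[0]
    return cls, matched


def classify_all(loci: Iterable[MirnaLocus], catalog: ReferenceCatalog,
                 flank: int = 1, max_mismatch: int = 2) -> None:
    for locus in loci:
        classify(locus, catalog, flank=flank, max_mismatch=max_mismatch)


def family_census(loci: Sequence[MirnaLocus]) -> dict[str, dict]:
    """Per-class counts/proportions and per-family member counts."""
    if any(l.conservation_class is None for l in loci):
        raise ValueError("classify all loci first")
    n = len(loci)
    by_class = Counter(l.conservation_class for l in loci)
    by_family = Counter(l.family for l in loci)
    return {
        "class_counts": {c: by_class.get(c, 0) for c in CLASSES},
        "class_proportions": {c: by_class.get(c, 0) / n for c in CLASSES},
        "family_members": dict(sorted(by_family.items())),
        "n_loci": n,
        "n_families": len(by_family),
    }
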