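"""Core domain containers shared across the pipeline.

Coordinates are 0-based half-open on the forward genome strand throughout
the library; conversion to 1-based inclusive happens only at GFF/BED
boundaries (see :mod:`mirnet.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)

    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (strand-aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ReadStack:
    """A collapsed small-RNA sequence with per-library counts.

    ``placements`` stays empty until :func:`mirnet.discovery.map_stacks`.
    """

    sequence: str
    per_library_counts: dict[str, int] = field(default_factory=dict)
    placements: list[GenomicInterval] = field(default_factory=list)
    multimapped: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if any(c < 0 for c in self.per_library_counts.values()):
            raise ValueError("negative read count")

    @property
    def total_count(self) -> int:
        return sum(self.per_library_counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HairpinCandidate:
    """A folded genomic window considered as a putative pre-miRNA."""

    window: GenomicInterval
    sequence: str
    structure: str | None = None
    stacks_in_window: list[ReadStack] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")


@dataclass
class MirnaLocus:
    """An accepted miRNA locus: hairpin, mature/star arms and annotation."""

    id: str
    precursor: GenomicInterval
    precursor_seq: str
    structure: str
    mature: GenomicInterval
    mature_seq: str
    star: GenomicInterval
    star_seq: str
    arm: str  # "5p" | "3p"
    precision: float
    duplex_mismatches: int
    asymmetric_bulge: int
    total_reads: int
    family: str | None = None
    conservation_class: str | None = None
    matched_families: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.precursor.contains(self.mature) or not self.precursor.contains(self.star):
            raise ValueError(f"{self.id}: mature/star outside precursor")
        if self.mature.overlaps(self.star):
            raise ValueError(f"{self.id}: mature and star overlap")
        if not (0.0 <= self.precision <= 1.0):
            raise ValueError(f"{self.id}: precision {self.precision} outside [0,1]")
        if not (20 <= len(self.mature) <= 24):
            raise ValueError(f"{self.id}: mature length {len(self.mature)}")


class ExpressionMatrix:
    """Entities x samples abundance table with tissue/replicate metadata.

    Parameters
    ----------
    values
        DataFrame indexed by entity id; columns are sample ids.
    samples
        Mapping sample id -> (tissue, replicate) labels.
    unit
        One of ``RPM``, ``FPKM``, ``raw``.
    """

    UNITS = ("RPM", "FPKM", "raw")

    def __init__(self, values: pd.DataFrame, samples: Mapping[str, tuple[str, str]],
                 unit: str) -> None:
        if unit not in self.UNITS:
            raise ValueError(f"unit must be one of {self.UNITS}")
        if (values.values < 0).any():
            raise ValueError("negative abundance values")
        if len(set(values.columns)) != len(values.columns):
            raise ValueError("duplicate sample ids")
        missing = set(values.columns) - set(samples)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.values = values
        self.samples = dict(samples)
        self.unit = unit

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for sid in self.values.columns:
            t = self.samples[sid][0]
            if t not in seen:
                seen.append(t)
        return seen

    def tissue_means(self) -> pd.DataFrame:
        """Average replicates within each tissue (columns ordered as seen)."""
        groups = {t: [s for s in self.values.columns if self.samples[s][0] == t]
                  for t in self.tissues}
        return pd.DataFrame(
            {t: self.values[cols].mean(axis=1) for t, cols in groups.items()})

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready frame with a two-row header encoded in column names."""
        out = self.values.copy()
        out.columns = [f"{s}|{self.samples[s][0]}|{self.samples[s][1]}"
                       for s in out.columns]
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        samples = {}
        cols = []
        for c in frame.columns:
            sid, tissue, rep = c.split("|")
            samples[sid] = (tissue, rep)
            cols.append(sid)
        values = frame.copy()
        values.columns = cols
        return cls(values, samples, unit)


@dataclass
class TargetEvidence:
    """One miRNA-transcript pair with all supporting evidence."""

    mirna_id: str
    transcript_id: str
    site_start: int           # 0-based on transcript
    site_end: int
    expectation: float | None = None
    energy_ratio: float | None = None
    degradome_category: int | None = None  # 0..4, None = no signal
    cleavage_pos: int | None = None        # 1-based transcript coordinate
    methods: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = self.methods - {"expectation", "hybrid", "degradome"}
        if bad:
            raise ValueError(f"unknown methods {bad}")
        if (self.cleavage_pos is None) != (self.degradome_category is None):
            raise ValueError("cleavage_pos set iff degradome_category set")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.transcript_id)


@dataclass(frozen=True)
class RegulatoryInteraction:
    """Typed directed edge: TMI (TF->miRNA), MTI (miRNA->target), TTI (TF->target)."""

    kind: str
    source: str
    target: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("TMI", "MTI", "TTI"):
            raise ValueError(f"bad interaction kind {self.kind!r}")


@dataclass(frozen=True)
class FflMotif:
    """A TF -> miRNA -> target feed-forward loop (TF->target edge closes it)."""

    tf: str
    mirna: str
    target: str


@dataclass
class Pwm:
    """Position weight matrix with background base frequencies (order ACGT)."""

    tf_id: str
    matrix: np.ndarray  # positions x 4, rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be positions x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class SyntenyBlock:
    """A chain of collinear homologous gene pairs between two chromosomes."""

    id: str
    chrom_a: str
    chrom_b: str
    anchors: tuple[tuple[str, str], ...]  # ordered (gene_a, gene_b) pairs
    orientation: str  # "same" | "inverted"

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class CorrelationRecord:
    mirna_id: str
    transcript_id: str
    r: float
    p: float
    n: int
    bin: str | None = None
    degenerate: bool = False  # zero-variance profile; excluded from summaries

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
                raise ValueError(f"r={self.r} outside [-1,1]")
            if not (0.0 <= self.p <= 1.0):
                raise ValueError(f"p={self.p} outside [0,1]")
        if self.n < 3:
            raise ValueError("need >= 3 tissue points")


def sorted_loci(loci: Iterable[MirnaLocus]) -> list[MirnaLocus]:
    return sorted(loci, key=lambda l: (l.precursor.chrom, l.precursor.start, l.id))
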