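"""Raw sRNA read cleaning, structural-RNA removal and length profiling.

Cleaning removes the 3' adapter at its first occurrence (a terminal
partial-adapter match of at least ``min_overlap`` nt also counts), drops
junk reads — any non-ACGT base or >= 80% single-nucleotide composition,
which covers polyA tags — and enforces the 18–30 nt length window. Reads
matching a structural ncRNA (tRNA/rRNA/snRNA/snoRNA) on either strand
with at most one mismatch are filtered before miRNA prediction, which
itself uses only 19–25 nt reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .types import ReadStack, revcomp

_ACGT = set("ACGT")


@dataclass
class CleanSummary:
    raw_reads: int = 0
    clean_reads: int = 0
    dropped: Counter = field(default_factory=Counter)  # reason -> reads


def _is_junk(seq: str, mono_fraction: float = 0.8) -> bool:
    if set(seq) - _ACGT:
        return True
    most = max(seq.count(b) for b in "ACGT")
    return most >= mono_fraction * len(seq)


def trim_adapter(seq: str, adapter: str, min_overlap: int = 5) -> str:
    """Trim at the first full adapter occurrence, else at a terminal match
    of an adapter prefix of length >= ``min_overlap``."""
    i = seq.find(adapter)
    if i >= 0:
        return seq[:i]
    max_ov = min(len(adapter) - 1, len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return seq[:-ov]
    return seq


def clean_reads(
    raw: str | Iterable[tuple[str, str]],
    adapter: str | None,
    min_len: int = 18,
    max_len: int = 30,
    library_id: str = "lib",
) -> tuple[list[ReadStack], CleanSummary]:
    """Clean a FASTQ file (path) or an iterable of (id, sequence) records
    and collapse the survivors to unique-sequence read stacks.

    Pass ``adapter=None`` to disable adapter trimming explicitly; an empty
    adapter string is rejected.
    """
    if adapter == "":
        raise ValueError("adapter must be non-empty or None to disable trimming")
    summary = CleanSummary()
    counter: Counter[str] = Counter()
    for idx, (rid, seq) in enumerate(_iter_reads(raw)):
        if seq is None:
            raise ValueError(f"unreadable FASTQ record at index {idx}")
        summary.raw_reads += 1
        seq = seq.upper().replace("U", "T")
        if adapter is not None:
            seq = trim_adapter(seq, adapter.upper())
        if _is_junk(seq) if seq else True:
            summary.dropped["junk"] += 1
            continue
        if len(seq) < min_len:
            summary.dropped["too_short"] += 1
            continue
        if len(seq) > max_len:
            summary.dropped["too_long"] += 1
            continue
        counter[seq] += 1
        summary.clean_reads += 1
    stacks = [ReadStack(s, {library_id: n}) for s, n in sorted(counter.items())]
    return stacks, summary


def _iter_reads(raw) -> Iterator[tuple[str, str]]:
    if isinstance(raw, str):
        for rec in SeqIO.parse(raw, "fastq"):
            yield rec.id, str(rec.seq)
    else:
        yield from raw


def filter_structural_rna(
    stacks: list[ReadStack],
    ncrna: Mapping[str, str],
    max_mismatch: int = 1,
) -> list[ReadStack]:
    """Drop stacks within ``max_mismatch`` of any ncRNA window, either strand.

    Uses a half-seed index (pigeonhole: a <=1-mismatch match preserves one
    exact half), so desk-scale inputs stay near-linear. An empty ncRNA set
    passes everything through with a warning.
    """
    if not ncrna:
        import warnings
        warnings.warn("empty ncRNA set: structural-RNA filter is a no-op")
        return list(stacks)
    lengths = sorted({len(s.sequence) for s in stacks})
    refs = [seq.upper().replace("U", "T") for seq in ncrna.values()]
    index: dict[int, dict[str, list[str]]] = {}
    for L in lengths:
        half = L // 2
        idx: dict[str, list[str]] = {}
        for ref in refs:
            for i in range(len(ref) - L + 1):
                win = ref[i:i + L]
                idx.setdefault(win[:half], []).append(win)
                idx.setdefault(win[half:], []).append(win)
        index[L] = idx

    def hits(seq: str) -> bool:
        L = len(seq)
        half = L // 2
        cands = index[L].get(seq[:half], []) + index[L].get(seq[half:], [])
        return any(_hamming_le(seq, win, max_mismatch) for win in cands)

    kept = []
    for st in stacks:
        if hits(st.sequence) or hits(revcomp(st.sequence)):
            continue
        kept.append(st)
    return kept


def _hamming_le(a: str, b: str, k: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return False
    return True


def length_profile(stacks: list[ReadStack], mode: str = "clean",
                   min_len: int = 18, max_len: int = 30) -> dict[int, float]:
    """Relative frequency of read lengths.

    ``clean`` weights each stack by its total count; ``unique`` counts each
    distinct sequence once (the clean-vs-unique contrast separates the
    read-stacking miRNA peak at 21 nt from the diverse siRNA peak at 24).
    """
    if not stacks:
        raise ValueError("empty stack collection")
    if mode not in ("clean", "unique"):
        raise ValueError(f"unknown mode {mode!r}")
    weights = Counter()
    for st in stacks:
        weights[len(st.sequence)] += st.total_count if mode == "clean" else 1
    total = sum(weights.values())
    return {L: weights.get(L, 0) / total for L in range(min_len, max_len + 1)}


def select_prediction_reads(stacks: list[ReadStack],
                            min_len: int = 19, max_len: int = 25) -> list[ReadStack]:
    """The 19–25 nt subset fed to miRNA prediction; counts are untouched."""
    return [st for st in stacks if min_len <= len(st.sequence) <= max_len]
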