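"""Genomic context of miRNA loci: clusters and synteny blocks.

Clusters are single-linkage chains of loci on one chromosome whose
start-to-start distance stays within a gap cap (default 10 kb); a span
mode constrains the whole cluster region instead. Synteny blocks are
chains of collinear homologous gene-pair anchors extracted by repeated
longest-chain dynamic programming, and miRNA loci are assigned to block
spans by interval intersection; two same-family loci on the two sides of
one block form a syntenic pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .types import GenomicInterval, MirnaLocus, SyntenyBlock


# ------------------------------------------------------------------ clusters


def find_clusters(loci: Sequence[MirnaLocus], max_gap: int = 10_000,
                  mode: str = "gap") -> list[list[MirnaLocus]]:
    """Chain loci into clusters of >= 2 members per chromosome.

    ``gap`` mode chains consecutive loci whose start-to-start distance is
    <= ``max_gap`` (transitive); ``span`` mode additionally requires the
    whole cluster region to stay within ``max_gap``.
    """
    if mode not in ("gap", "span"):
        raise ValueError(f"unknown cluster mode {mode!r}")
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.precursor.chrom, []).append(loc)
    clusters = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.precursor.start, l.id))
        current = [ordered[0]]
        for loc in ordered[1:]:
            gap_ok = loc.precursor.start - current[-1].precursor.start <= max_gap
            span_ok = (mode == "gap"
                       or loc.precursor.start - current[0].precursor.start <= max_gap)
            if gap_ok and span_ok:
                current.append(loc)
            else:
                if len(current) >= 2:
                    clusters.append(current)
                current = [loc]
        if len(current) >= 2:
            clusters.append(current)
    return clusters


# ------------------------------------------------------------ synteny blocks


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    rank_a: int
    gene_b: str
    rank_b: int


def _chain_dp(anchors: list[Anchor], direction: int, max_gap: int
              ) -> list[int]:
    """Longest collinear chain (O(n^2) DP) over anchors sorted by rank_a.

    ``direction`` +1 chains ascending rank_b, -1 descending. Ties prefer
    the lexicographically smallest index sequence. Returns anchor indices.
    """
    n = len(anchors)
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if anchors[j].rank_a >= anchors[i].rank_a:
                continue
            if anchors[i].rank_a - anchors[j].rank_a > max_gap:
                continue
            db = direction * (anchors[i].rank_b - anchors[j].rank_b)
            if db <= 0 or abs(anchors[i].rank_b - anchors[j].rank_b) > max_gap:
                continue
            if best[j] + 1 > best[i]:
                best[i], prev[i] = best[j] + 1, j
    if not n:
        return []
    end = max(range(n), key=lambda i: (best[i], -i))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def detect_blocks(anchors: pd.DataFrame, min_anchors: int = 5,
                  max_anchor_gap: int = 25,
                  known_genes: set[str] | None = None) -> list[SyntenyBlock]:
    """Extract collinearity blocks from a homolog-pair anchor table.

    ``anchors`` columns: chrom_a, gene_a, rank_a, chrom_b, gene_b, rank_b
    (ordinal gene positions per chromosome). Per chromosome pair, the
    longest collinear chain (either orientation) is extracted, its anchors
    removed, and the process repeats until the best chain falls below
    ``min_anchors``.
    """
    if known_genes is not None:
        unknown = (set(anchors["gene_a"]) | set(anchors["gene_b"])) - known_genes
        if unknown:
            raise ValueError(f"anchors reference unknown genes: {sorted(unknown)[:5]}")
    blocks: list[SyntenyBlock] = []
    bi = 0
    for (ca, cb), sub in sorted(anchors.groupby(["chrom_a", "chrom_b"]),
                                key=lambda kv: kv[0]):
        pool = [Anchor(r.gene_a, int(r.rank_a), r.gene_b, int(r.rank_b))
                for r in sub.itertuples(index=False)]
        pool.sort(key=lambda a: (a.rank_a, a.rank_b))
        while True:
            up = _chain_dp(pool, +1, max_anchor_gap)
            down = _chain_dp(pool, -1, max_anchor_gap)
            chain, orient = ((up, "same") if len(up) >= len(down)
                             else (down, "inverted"))
            if len(chain) < min_anchors:
                break
            bi += 1
            chosen = [pool[i] for i in chain]
            blocks.append(SyntenyBlock(
                id=f"block{bi:03d}", chrom_a=ca, chrom_b=cb,
                anchors=tuple((a.gene_a, a.gene_b) for a in chosen),
                orientation=orient))
            drop = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in drop]
    return blocks


# -------------------------------------------------------------- block spans


def block_spans(block: SyntenyBlock,
                gene_positions: Mapping[str, GenomicInterval]
                ) -> tuple[GenomicInterval, GenomicInterval]:
    """Genomic spans of the two block sides, from anchor gene coordinates."""

    def span(genes: list[str], chrom: str) -> GenomicInterval:
        ivs = [gene_positions[g] for g in genes]
        return GenomicInterval(chrom, min(iv.start for iv in ivs),
                               max(iv.end for iv in ivs))

    return (span([a for a, _ in block.anchors], block.chrom_a),
            span([b for _, b in block.anchors], block.chrom_b))


def place_mirnas_in_blocks(
    loci: Sequence[MirnaLocus],
    blocks: Sequence[SyntenyBlock],
    gene_positions: Mapping[str, GenomicInterval],
) -> tuple[dict[str, list[str]], list[tuple[str, str, str]]]:
    """Assign loci to block sides and pair syntenic family members.

    Returns (locus id -> list of "block:side" memberships,
    syntenic pairs as (locus a, locus b, block id)) where the two loci
    share a family and sit in the two sides of one block.
    """
    membership: dict[str, list[str]] = {loc.id: [] for loc in loci}
    pairs: list[tuple[str, str, str]] = []
    for block in blocks:
        span_a, span_b = block_spans(block, gene_positions)
        in_a = [l for l in loci if l.precursor.overlaps(span_a)]
        in_b = [l for l in loci if l.precursor.overlaps(span_b)]
        for l in in_a:
            membership[l.id].append(f"{block.id}:A")
        for l in in_b:
            membership[l.id].append(f"{block.id}:B")
        for la in in_a:
            for lb in in_b:
                if la.id != lb.id and la.family == lb.family:
                    pairs.append((la.id, lb.id, block.id))
    return membership, pairs
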