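"""miRNA locus discovery from mapped read stacks.

The stages mirror the classic plant small-RNA annotation flow: exact-match
mapping of read stacks to the genome, excision of flanking windows as
precursor candidates, secondary-structure folding, duplex calling from the
read signature, and acceptance under codified plant miRNA criteria
(precision of read processing, mature length, duplex mismatches and bulge
asymmetry, minimum read support).

The duplex geometry convention: the mature/star duplex carries 2-nt 3'
overhangs, so the star interval is the span of the mature's base-pairing
partners extended by 2 nt at its 3' (right, sense-precursor) edge.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fold import FoldEngine, default_engine, pair_table
from .types import (GenomicInterval, HairpinCandidate, MirnaLocus, ReadStack,
                    revcomp)

SEED_K = 18  # all prediction reads are >= 19 nt


# -------------------------------------------------------------------- mapping


def map_stacks(stacks: list[ReadStack], genome: Mapping[str, str],
               max_hits: int = 20) -> list[ReadStack]:
    """Record exact-match genomic placements (both strands) on each stack.

    Stacks with more than ``max_hits`` placements are flagged multi-mapped.
    A single pass over the genome against an index of stack 18-mer prefixes
    keeps this linear in genome size.
    """
    needed: dict[str, list[tuple[int, str, str]]] = {}
    for i, st in enumerate(stacks):
        st.placements = []
        st.multimapped = False
        fwd = st.sequence
        rev = revcomp(fwd)
        needed.setdefault(fwd[:SEED_K], []).append((i, "+", fwd))
        needed.setdefault(rev[:SEED_K], []).append((i, "-", rev))
    for chrom in sorted(genome):
        g = genome[chrom].upper()
        for pos in range(len(g) - SEED_K + 1):
            cands = needed.get(g[pos:pos + SEED_K])
            if not cands:
                continue
            for i, strand, target in cands:
                if g[pos:pos + len(target)] == target:
                    stacks[i].placements.append(
                        GenomicInterval(chrom, pos, pos + len(target), strand))
    for st in stacks:
        if len(st.placements) > max_hits:
            st.multimapped = True
    return stacks


# ------------------------------------------------------------------- excision


def excise_candidates(
    stacks: list[ReadStack],
    genome: Mapping[str, str],
    flank: int = 250,
    max_window: int = 300,
    min_stack_count: int = 5,
) -> list[HairpinCandidate]:
    """Excise precursor candidate windows around placed stacks.

    Each qualifying placement seeds two windows, ``[start-flank, end)`` and
    ``[start, end+flank)``; overlapping windows on one chrom/strand are
    merged left-to-right while the merged span stays within ``max_window``
    (the cap keeps folded candidates at pre-miRNA scale). Windows clipped
    at a chromosome edge are flagged truncated.
    """
    seeds: dict[tuple[str, str], list[tuple[int, int]]] = {}
    placed: dict[tuple[str, str], list[tuple[int, int, ReadStack]]] = {}
    for st in stacks:
        for p in st.placements:
            placed.setdefault((p.chrom, p.strand), []).append((p.start, p.end, st))
        if st.multimapped or st.total_count < min_stack_count:
            continue
        for p in st.placements:
            key = (p.chrom, p.strand)
            seeds.setdefault(key, []).append((p.start - flank, p.end))
            seeds.setdefault(key, []).append((p.start, p.end + flank))

    out: list[HairpinCandidate] = []
    for (chrom, strand), wins in sorted(seeds.items()):
        glen = len(genome[chrom])
        merged: list[list[int]] = []
        for s, e in sorted(set(wins)):
            if merged and s <= merged[-1][1] and max(e, merged[-1][1]) - merged[-1][0] <= max_window:
                merged[-1][1] = max(e, merged[-1][1])
            else:
                merged.append([s, e])
        plist = sorted(placed.get((chrom, strand), []))
        starts = [p[0] for p in plist]
        for s, e in merged:
            truncated = s < 0 or e > glen
            s, e = max(0, s), min(glen, e)
            if e <= s:
                continue
            seq = genome[chrom][s:e]
            if strand == "-":
                seq = revcomp(seq)
            inside = []
            for k in range(bisect_left(starts, s), len(plist)):
                ps, pe, st = plist[k]
                if ps >= e:
                    break
                if pe <= e:
                    inside.append(st)
            out.append(HairpinCandidate(
                window=GenomicInterval(chrom, s, e, strand), sequence=seq,
                stacks_in_window=inside, truncated=truncated))
    return out


# -------------------------------------------------------------- duplex calls


@dataclass
class Rejection:
    reason: str
    candidate: HairpinCandidate | None = None


@dataclass
class DuplexCall:
    candidate: HairpinCandidate
    mature_local: tuple[int, int]
    star_local: tuple[int, int]
    mature_seq: str
    star_seq: str
    arm: str
    precision: float
    duplex_mismatches: int
    asymmetric_bulge: int
    total_reads: int
    star_reads: int = 0


def _local_span(window: GenomicInterval, p: GenomicInterval) -> tuple[int, int]:
    """Placement -> sense-strand local coordinates within the window."""
    if window.strand == "+":
        return p.start - window.start, p.end - window.start
    return window.end - p.end, window.end - p.start


def _genomic_span(window: GenomicInterval, lo: int, hi: int) -> GenomicInterval:
    if window.strand == "+":
        return GenomicInterval(window.chrom, window.start + lo,
                               window.start + hi, "+")
    return GenomicInterval(window.chrom, window.end - hi,
                           window.end - lo, "-")


def signature_precision_bound(candidate: HairpinCandidate,
                              shift_tol: int = 1) -> float:
    """Upper bound on achievable precision from the read signature alone.

    Sums counts around the two strongest 5'-end positions (the best case:
    mature and star both sit there), so no window rejected by this bound
    could have passed the precision criterion. Used to skip folding of
    dispersed (siRNA-like) windows.
    """
    win = candidate.window
    pos_counts: dict[int, int] = {}
    total = 0
    for st in candidate.stacks_in_window:
        for p in st.placements:
            if win.contains(p) and p.strand == win.strand:
                lo, _ = _local_span(win, p)
                pos_counts[lo] = pos_counts.get(lo, 0) + st.total_count
                total += st.total_count
                break
    if not pos_counts:
        return 0.0

    def around(center: int) -> int:
        return sum(c for q, c in pos_counts.items() if abs(q - center) <= shift_tol)

    best = sorted(pos_counts, key=lambda q: (-around(q), q))
    top = around(best[0])
    second = max((around(q) for q in best[1:]
                  if abs(q - best[0]) > shift_tol), default=0)
    return min(1.0, (top + second) / total) if total else 0.0


def call_duplex(candidate: HairpinCandidate,
                shift_tol: int = 1,
                engine: FoldEngine | None = None,
                cluster_gap: int = 8) -> DuplexCall | Rejection:
    """Call mature/star from the read signature and the folded structure.

    The mature is the most abundant stack inside the window. Its pairing
    partners, clustered to the dominant contiguous run (stray pairings
    into flanks or the loop are ignored and scored as mismatches), give
    the star via the 2-nt 3' overhang rule. Precision counts reads whose
    5' ends sit within ``shift_tol`` nt of the mature or star 5' end.
    """
    if not candidate.stacks_in_window:
        return Rejection("no_reads", candidate)
    if candidate.structure is None:
        if len(candidate.sequence) < 40:
            return Rejection("window_too_short", candidate)
        try:
            candidate.structure, _ = (engine or default_engine()).fold(candidate.sequence)
        except ValueError:
            return Rejection("unfoldable", candidate)
    try:
        pt = pair_table(candidate.structure)
    except ValueError:
        return Rejection("unbalanced_structure", candidate)

    win = candidate.window
    mature_stack = max(candidate.stacks_in_window, key=lambda s: s.total_count)
    spans = [_local_span(win, p) for p in mature_stack.placements
             if win.contains(p) and p.strand == win.strand]
    if not spans:
        return Rejection("mature_not_in_window", candidate)
    mlo, mhi = spans[0]

    # the mature's final 2 nt are its 3' overhang: unpaired in the duplex
    # model, so they contribute no partners to the star derivation
    partners = sorted(pt[i] for i in range(mlo, mhi - 2) if pt[i] >= 0)
    if len(partners) < 8:
        return Rejection("no_star", candidate)
    if any(mlo <= j < mhi for j in partners):
        return Rejection("spans_loop", candidate)

    clusters: list[list[int]] = [[partners[0]]]
    for j in partners[1:]:
        if j - clusters[-1][-1] > cluster_gap:
            clusters.append([])
        clusters[-1].append(j)
    main = max(clusters, key=len)
    if len(main) < 0.6 * len(partners):
        return Rejection("ambiguous_pairing", candidate)
    # overhang-base partners count only when they abut the star span
    # (junction bulges shift a terminal pair onto the overhang; distant
    # partners are loop/flank artifacts)
    lo_p, hi_p = main[0], main[-1]
    for i in (mhi - 2, mhi - 1):
        j = pt[i]
        if j >= 0 and lo_p - 2 <= j <= hi_p + 2:
            lo_p, hi_p = min(lo_p, j), max(hi_p, j)
    slo, shi = lo_p, hi_p + 1 + 2  # +2 = star 3' overhang
    shi = min(shi, len(candidate.sequence))
    if not (shi <= mlo or slo >= mhi):
        return Rejection("arms_overlap", candidate)

    main_set = set(main)
    mismatches = 0
    pairs = []  # (mature pos, partner) restricted to the main cluster
    for i in range(mlo, mhi - 2):  # final 2 nt are the mature 3' overhang
        if pt[i] in main_set:
            pairs.append((i, pt[i]))
        else:
            mismatches += 1
    bulge = 0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        bulge += abs((i2 - i1 - 1) - (j1 - j2 - 1))

    total = near_mature = star_reads = 0
    for st in candidate.stacks_in_window:
        for p in st.placements:
            if not (win.contains(p) and p.strand == win.strand):
                continue
            lo, _hi = _local_span(win, p)
            total += st.total_count
            if abs(lo - mlo) <= shift_tol or abs(lo - slo) <= shift_tol:
                near_mature += st.total_count
            if abs(lo - slo) <= shift_tol:
                star_reads += st.total_count
            break
    precision = near_mature / total if total else 0.0

    seq = candidate.sequence
    return DuplexCall(
        candidate=candidate, mature_local=(mlo, mhi), star_local=(slo, shi),
        mature_seq=seq[mlo:mhi], star_seq=seq[slo:shi],
        arm="5p" if mlo < slo else "3p",
        precision=precision, duplex_mismatches=mismatches,
        asymmetric_bulge=bulge, total_reads=total, star_reads=star_reads)


# ------------------------------------------------------------------ criteria


@dataclass
class Criteria:
    """Plant miRNA acceptance thresholds (all configurable)."""

    min_precision: float = 0.75
    min_mature_len: int = 20
    max_mature_len: int = 24
    max_duplex_mismatches: int = 5
    max_asymmetric_bulge: int = 3
    min_total_reads: int = 10
    min_star_reads: int = 1  # miR* read evidence, per the plant criteria
    family_mismatches: int = 2  # mature-sequence distance for co-familying


def apply_criteria(call: DuplexCall, thresholds: Criteria | None = None
                   ) -> tuple[bool, str]:
    """Accept/reject a called duplex; returns (accepted, reason)."""
    t = thresholds or Criteria()
    m = call.mature_local[1] - call.mature_local[0]
    if not (t.min_mature_len <= m <= t.max_mature_len):
        return False, "mature_length"
    if call.precision < t.min_precision:
        return False, "precision"
    if call.duplex_mismatches > t.max_duplex_mismatches:
        return False, "duplex_mismatches"
    if call.asymmetric_bulge > t.max_asymmetric_bulge:
        return False, "asymmetric_bulge"
    if call.total_reads < t.min_total_reads:
        return False, "read_support"
    if call.star_reads < t.min_star_reads:
        return False, "star_support"
    return True, "ok"


def _extend_hairpin(pt: list[int], lo: int, hi: int,
                    max_skip: int = 4) -> tuple[int, int]:
    """Extend a duplex span outward along enclosing base pairs (the lower
    stem), tolerating up to ``max_skip`` consecutive unpaired positions;
    this recovers the full precursor extent from the structure."""
    left, right = lo, hi - 1
    i, skips = lo - 1, 0
    while i >= 0 and skips <= max_skip:
        if pt[i] > right:
            left, right = i, pt[i]
            skips = 0
        else:
            skips += 1
        i -= 1
    return left, right + 1


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) if len(a) == len(b) else 99


def assign_families(loci: list[MirnaLocus], max_mismatch: int = 2) -> None:
    """Co-family loci whose matures are within ``max_mismatch`` (equal
    length, ungapped); sequential MIRFAM names in genomic order."""
    parent = list(range(len(loci)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            if _hamming(loci[i].mature_seq, loci[j].mature_seq) <= max_mismatch:
                parent[find(i)] = find(j)
    names: dict[int, str] = {}
    for i, loc in enumerate(loci):
        root = find(i)
        if root not in names:
            names[root] = f"MIRFAM{len(names) + 1:03d}"
        loc.family = names[root]


def discover_loci(
    stacks: list[ReadStack],
    genome: Mapping[str, str],
    thresholds: Criteria | None = None,
    engine: FoldEngine | None = None,
    flank: int = 250,
    max_window: int = 300,
    min_stack_count: int = 5,
    max_hits: int = 20,
    mapped: bool = False,
) -> tuple[list[MirnaLocus], list[Rejection]]:
    """Full discovery: map, excise, fold, call, filter, name.

    Accepted calls seeded by the same mature position are deduplicated to
    the highest-precision one; loci get sequential ids (``mir-0001`` ...)
    in genomic order and family names by mature-sequence similarity.
    """
    t = thresholds or Criteria()
    if not mapped:
        map_stacks(stacks, genome, max_hits=max_hits)
    cands = excise_candidates(stacks, genome, flank=flank,
                              max_window=max_window,
                              min_stack_count=min_stack_count)
    accepted: list[tuple[DuplexCall, GenomicInterval]] = []
    rejections: list[Rejection] = []
    for cand in cands:
        if signature_precision_bound(cand) < t.min_precision:
            rejections.append(Rejection("precision", cand))
            continue
        call = call_duplex(cand, engine=engine)
        if isinstance(call, Rejection):
            rejections.append(call)
            continue
        ok, reason = apply_criteria(call, t)
        if not ok:
            rejections.append(Rejection(reason, cand))
            continue
        accepted.append((call, _genomic_span(cand.window, *call.mature_local)))

    # deduplicate calls whose duplex spans overlap, on either strand: the
    # mature/star duplex is near-palindromic, so one hairpin can surface
    # as calls on both strands or as a star-led call from a second window;
    # keep the highest-precision call per genomic region
    def duplex_span(cm) -> GenomicInterval:
        call, _iv = cm
        lo = min(call.mature_local[0], call.star_local[0])
        hi = max(call.mature_local[1], call.star_local[1])
        g = _genomic_span(call.candidate.window, lo, hi)
        return GenomicInterval(g.chrom, g.start, g.end)  # strand-agnostic

    accepted.sort(key=lambda cm: (duplex_span(cm).chrom, duplex_span(cm).start))
    calls: list[tuple[DuplexCall, GenomicInterval]] = []
    for cm in accepted:
        if calls and duplex_span(calls[-1]).overlaps(duplex_span(cm)):
            # read support separates a true hairpin from its antisense
            # twin, which only the palindromic read subset maps to
            if (cm[0].total_reads, cm[0].precision) > \
                    (calls[-1][0].total_reads, calls[-1][0].precision):
                calls[-1] = cm
        else:
            calls.append(cm)
    calls.sort(key=lambda cm: (cm[1].chrom, cm[1].start, cm[1].strand))
    loci: list[MirnaLocus] = []
    for n, (call, mat_iv) in enumerate(calls, 1):
        win = call.candidate.window
        pt = pair_table(call.candidate.structure)
        lo = min(call.mature_local[0], call.star_local[0])
        hi = max(call.mature_local[1], call.star_local[1])
        lo, hi = _extend_hairpin(pt, lo, hi)
        loci.append(MirnaLocus(
            id=f"mir-{n:04d}",
            precursor=_genomic_span(win, lo, hi),
            precursor_seq=call.candidate.sequence[lo:hi],
            structure=call.candidate.structure[lo:hi],
            mature=mat_iv, mature_seq=call.mature_seq,
            star=_genomic_span(win, *call.star_local), star_seq=call.star_seq,
            arm=call.arm, precision=call.precision,
            duplex_mismatches=call.duplex_mismatches,
            asymmetric_bulge=call.asymmetric_bulge,
            total_reads=call.total_reads))
    assign_families(loci, t.family_mismatches)
    return loci, rejections


# ------------------------------------------------------------------ summary


def summarize_loci(loci: Sequence[MirnaLocus]) -> dict[str, dict]:
    """Relative-frequency tables: precursor length, mature length, first nt."""
    if not loci:
        raise ValueError("no accepted loci to summarize")
    n = len(loci)
    pre_lens: dict[int, int] = {}
    mat_lens: dict[int, int] = {}
    first_nt = {b: 0 for b in "ACGU"}
    for loc in loci:
        pre_lens[len(loc.precursor)] = pre_lens.get(len(loc.precursor), 0) + 1
        mat_lens[len(loc.mature)] = mat_lens.get(len(loc.mature), 0) + 1
        first_nt[loc.mature_seq[0].replace("T", "U")] += 1
    return {
        "precursor_length": {k: v / n for k, v in sorted(pre_lens.items())},
        "mature_length": {k: v / n for k, v in sorted(mat_lens.items())},
        "first_nt": {k: v / n for k, v in first_nt.items()},
    }
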