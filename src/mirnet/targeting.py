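"""miRNA target prediction, degradome validation and consensus.

Three evidence routes per miRNA-transcript pair:

* ``expectation`` — a complementarity penalty over the aligned site
  (mismatch 1, G:U wobble 0.5, gap 2; all penalties doubled over miRNA
  positions 2–13, the core), kept at expectation <= 3.0;
* ``hybrid`` — duplex stacking energy from a reduced 16-entry
  nearest-neighbor table, expressed as the ratio to the miRNA's perfect
  complement and kept at ratio >= 0.75;
* ``degradome`` — the 5'-end read density at the predicted cleavage site
  (the transcript base opposite miRNA positions 10–11) classified into
  categories 0–4; categories 0–2 count as validation.

The union keeps pairs with any method, the intersection pairs with at
least two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import TargetEvidence, revcomp

_IDX = {b: i for i, b in enumerate("ACGT")}
_COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G on encoded bases

CORE_START, CORE_END = 2, 13  # miRNA positions (1-based, inclusive)
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0

# Reduced nearest-neighbor stack table (kcal/mol), keyed by the miRNA-side
# 5'->3' dinucleotide of two consecutive Watson-Crick pairs; derived from
# the standard RNA WC stacking parameters via strand symmetry. Stacks that
# involve a G:U pair are scaled by 0.5 (see score_hybrid).
NN_STACK = {
    "AA": -0.93, "UU": -0.93, "AU": -1.10, "UA": -1.33,
    "CU": -2.08, "AG": -2.08, "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24, "GA": -2.35, "UC": -2.35,
    "CG": -2.36, "GG": -3.26, "CC": -3.26, "GC": -3.42,
}


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    try:
        return np.array([_IDX[b] for b in s], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"non-ACGU base {e} in sequence") from None


def _penalty_table() -> np.ndarray:
    """P[mir_base, transcript_base] before positional doubling."""
    P = np.full((4, 4), MISMATCH_PENALTY)
    for mb in range(4):
        P[mb, _COMP_IDX[mb]] = 0.0
    P[_IDX["G"], _IDX["T"]] = WOBBLE_PENALTY  # G:U
    P[_IDX["T"], _IDX["G"]] = WOBBLE_PENALTY  # U:G
    return P


_P = _penalty_table()


def _position_weights(m: int) -> np.ndarray:
    w = np.ones(m)
    w[CORE_START - 1:CORE_END] = 2.0
    return w


@dataclass(frozen=True)
class Site:
    transcript_id: str
    start: int  # 0-based
    end: int
    expectation: float

    @property
    def cleavage_pos(self) -> int:
        """1-based transcript coordinate opposite miRNA position 10."""
        m = self.end - self.start
        return self.start + m - 9


def score_site(mirna: str, site: str) -> float:
    """Expectation penalty for one explicit site (antiparallel alignment).

    Equal lengths score ungapped; a site longer by up to 2 nt is scored
    over all placements of transcript bulges (gap penalty per bulged base,
    doubled when the gap interrupts the miRNA core).
    """
    mir = _encode(mirna)
    tx = _encode(site)[::-1]  # align transcript 3'->5' against miRNA 5'->3'
    m, t = len(mir), len(tx)
    extra = t - m
    if extra < 0 or extra > 2:
        raise ValueError("site must be miRNA length to miRNA length + 2")
    w = _position_weights(m)
    if extra == 0:
        return float((_P[mir, tx] * w).sum())
    best = np.inf
    from itertools import combinations
    for bulges in combinations(range(1, m), extra):  # gaps between positions
        pen = 0.0
        j = 0
        for i in range(m):
            while j - i < sum(1 for b in bulges if b <= i):
                gap_w = 2.0 if CORE_START <= i + 1 <= CORE_END else 1.0
                pen += GAP_PENALTY * gap_w
                j += 1
            pen += _P[mir[i], tx[j]] * w[i]
            j += 1
        best = min(best, pen)
    return float(best)


def score_expectation(
    mirna: str,
    transcript: str,
    cutoff: float = 3.0,
    transcript_id: str = "tx",
) -> list[Site]:
    """Scan every transcript window of miRNA length; return sites with
    expectation <= ``cutoff`` (vectorised, ungapped)."""
    if len(mirna) < 15:
        raise ValueError("miRNA shorter than 15 nt")
    mir = _encode(mirna)
    tx = _encode(transcript)
    m = len(mir)
    if len(tx) < m:
        return []
    wins = np.lib.stride_tricks.sliding_window_view(tx, m)[:, ::-1]
    pen = (_P[mir[None, :], wins] * _position_weights(m)[None, :]).sum(axis=1)
    return [Site(transcript_id, int(s), int(s) + m, float(pen[s]))
            for s in np.flatnonzero(pen <= cutoff)]


def duplex_energy(mirna: str, site: str) -> float:
    """Stacking energy (kcal/mol, <= 0) of the ungapped antiparallel duplex."""
    mir = mirna.upper().replace("T", "U")
    txr = site.upper().replace("T", "U")[::-1]
    m = min(len(mir), len(txr))
    pairs = []
    wob = []
    for i in range(m):
        a, b = mir[i], txr[i]
        wc = (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        gu = (a, b) in {("G", "U"), ("U", "G")}
        pairs.append(wc or gu)
        wob.append(gu)
    e = 0.0
    for i in range(m - 1):
        if pairs[i] and pairs[i + 1]:
            stack = NN_STACK[mir[i] + mir[i + 1]]
            if wob[i] or wob[i + 1]:
                stack *= 0.5
            e += stack
    return e


def score_hybrid(mirna: str, site: str, cutoff: float = 0.75,
                 force_paired: tuple[int, int] | None = None
                 ) -> tuple[float, float, bool]:
    """Duplex energy and its ratio to the perfect-complement energy.

    Returns (energy, ratio, kept). ``force_paired=(8, 12)`` additionally
    requires those miRNA positions (1-based, inclusive) to be paired,
    mirroring a forced-helix constraint.
    """
    if not (len(mirna) <= len(site) <= len(mirna) + 5):
        raise ValueError("site length outside [miRNA, miRNA+5]")
    perfect = duplex_energy(mirna, revcomp(mirna))
    best = 0.0
    for off in range(len(site) - len(mirna) + 1):
        best = min(best, duplex_energy(mirna, site[off:off + len(mirna)]))
    ratio = best / perfect if perfect < 0 else 0.0
    kept = ratio >= cutoff
    if kept and force_paired is not None:
        mir = mirna.upper().replace("T", "U")
        txr = site.upper().replace("T", "U")[::-1]
        for p in range(force_paired[0], force_paired[1] + 1):
            a, b = mir[p - 1], txr[p - 1] if p - 1 < len(txr) else "N"
            if (a, b) not in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                              ("G", "U"), ("U", "G")}:
                kept = False
                break
    return best, ratio, kept


def classify_degradome(site: Site, density: Mapping[int, int] | None
                       ) -> tuple[int | None, int | None]:
    """Degradome category at the site's cleavage position.

    With r = reads at the cleavage position, M = transcript maximum and
    A = mean over positions with >= 1 read: category 0 = unique maximum
    (r = M, r > 1), 1 = tied maximum, 2 = A < r < M, 3 = 0 < r <= A,
    4 = r = 1; no reads -> (None, None).
    """
    if not density:
        return None, None
    pos = site.cleavage_pos
    r = density.get(pos, 0)
    if r == 0:
        return None, None
    counts = list(density.values())
    M = max(counts)
    A = sum(counts) / len(counts)
    if r == 1:
        cat = 4
    elif r == M:
        cat = 0 if counts.count(M) == 1 else 1
    elif r > A:
        cat = 2
    else:
        cat = 3
    return cat, pos


RETAINED_CATEGORIES = frozenset({0, 1, 2})


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    degradome: Mapping[str, Mapping[int, int]] | None = None,
    expectation_cutoff: float = 3.0,
    hybrid_cutoff: float = 0.75,
    candidate_cutoff: float | None = None,
    retained_categories: frozenset[int] = RETAINED_CATEGORIES,
) -> list[TargetEvidence]:
    """Run all three evidence routes over every miRNA x transcript pair.

    Candidate sites come from the expectation scan at ``candidate_cutoff``
    (default: twice the expectation cutoff, so hybrid- or degradome-only
    sites with marginal complementarity still surface); each candidate is
    then flagged per method. One record per pair keeps the best site.
    """
    if candidate_cutoff is None:
        candidate_cutoff = 2 * expectation_cutoff
    out: dict[tuple[str, str], TargetEvidence] = {}
    for mid in sorted(mirnas):
        mseq = mirnas[mid]
        for tid in sorted(transcripts):
            sites = score_expectation(mseq, transcripts[tid],
                                      cutoff=candidate_cutoff, transcript_id=tid)
            best_rec: TargetEvidence | None = None
            for site in sorted(sites, key=lambda s: (s.expectation, s.start)):
                methods = set()
                if site.expectation <= expectation_cutoff:
                    methods.add("expectation")
                site_seq = transcripts[tid][site.start:site.end]
                _e, ratio, kept = score_hybrid(mseq, site_seq, cutoff=hybrid_cutoff)
                if kept:
                    methods.add("hybrid")
                cat, cpos = (None, None)
                if degradome is not None:
                    cat, cpos = classify_degradome(site, degradome.get(tid))
                    if cat in retained_categories:
                        methods.add("degradome")
                if not methods:
                    continue
                rec = TargetEvidence(
                    mirna_id=mid, transcript_id=tid,
                    site_start=site.start, site_end=site.end,
                    expectation=site.expectation, energy_ratio=ratio,
                    degradome_category=cat, cleavage_pos=cpos, methods=methods)
                if best_rec is None or len(methods) > len(best_rec.methods):
                    best_rec = rec
            if best_rec is not None:
                out[(mid, tid)] = best_rec
    return list(out.values())


def consensus(records: Iterable[TargetEvidence]
              ) -> tuple[list[TargetEvidence], list[TargetEvidence]]:
    """(union, intersection): any method vs at least two methods."""
    union = [r for r in records if r.methods]
    intersection = [r for r in union if len(r.methods) >= 2]
    return union, intersection


def enrich_terms(target_set: Sequence[str], background: Sequence[str],
                 term_map: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term, BH-adjusted.

    ``term_map`` maps a term to the genes it annotates; the target set
    must be a subset of the background universe.
    """
    targets = set(target_set)
    universe = set(background)
    if not targets:
        raise ValueError("empty target set")
    if not term_map:
        raise ValueError("empty term map")
    if not targets <= universe:
        raise ValueError("target set not a subset of background")
    N, n = len(universe), len(targets)
    rows = []
    for term in sorted(term_map):
        annotated = set(term_map[term]) & universe
        K = len(annotated)
        k = len(annotated & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    df = pd.DataFrame(rows, columns=["term", "hits", "annotated", "p"])
    df["p_adj"] = np.minimum(1.0, np.maximum(
        df["p"], multipletests(df["p"], method="fdr_bh")[1]))
    return df.set_index("term")
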