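"""TF -> miRNA -> target regulatory network assembly.

Promoters are the 2000 nt upstream of each feature (strand-aware,
truncated at chromosome edges). PWM hits use log-odds scoring against the
background on both strands with a fraction-of-maximum threshold; a hit
must also score strictly above zero, so a zero-information matrix never
fires. Typed edges — TMI (TF->miRNA), MTI (miRNA->target, from the
targeting consensus) and TTI (TF->target, restricted to promoters of
genes that are miRNA targets) — feed cascade (TMI+MTI) and feed-forward
loop (cascade closed by a TTI) enumeration.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .types import (FflMotif, GenomicInterval, Pwm, RegulatoryInteraction,
                    revcomp)


# ----------------------------------------------------------------- promoters


def extract_promoters(
    features: Mapping[str, GenomicInterval],
    genome: Mapping[str, str],
    upstream: int = 2000,
) -> tuple[dict[str, str], dict[str, bool]]:
    """Upstream promoter sequence per feature; returns (seqs, truncated flags).

    Plus-strand features take ``[start-upstream, start)``; minus-strand
    features take ``[end, end+upstream)`` reverse-complemented. Zero-length
    results are skipped with a warning flag left implicit (absent key).
    """
    seqs: dict[str, str] = {}
    truncated: dict[str, bool] = {}
    for name, iv in features.items():
        glen = len(genome[iv.chrom])
        if iv.strand == "+":
            lo, hi = max(0, iv.start - upstream), iv.start
            seq = genome[iv.chrom][lo:hi]
            trunc = iv.start - upstream < 0
        else:
            lo, hi = iv.end, min(glen, iv.end + upstream)
            seq = revcomp(genome[iv.chrom][lo:hi])
            trunc = iv.end + upstream > glen
        if not seq:
            continue
        seqs[name] = seq
        truncated[name] = trunc
    return seqs, truncated


# ---------------------------------------------------------------- TFBS scan


def _log_odds(pwm: Pwm, pseudo: float = 1e-3) -> np.ndarray:
    return np.log2((pwm.matrix + pseudo) / (pwm.background[None, :] + pseudo))


def scan_tfbs(
    promoters: Mapping[str, str],
    pwms: Sequence[Pwm],
    score_threshold: float = 0.85,
) -> pd.DataFrame:
    """Scan promoters with PWMs; hit when log-odds >= threshold x maximum
    achievable score (and > 0). Overlapping hits of one PWM on one
    promoter are merged to the best-scoring one.

    Returns a table (tf, promoter, offset, strand, score); offsets are
    0-based on the forward promoter sequence.
    """
    idx = {b: i for i, b in enumerate("ACGT")}
    rows = []
    for pwm in pwms:
        lo = _log_odds(pwm)
        m = len(pwm)
        max_score = float(lo.max(axis=1).sum())
        if max_score <= 0:
            continue  # no information content: nothing can qualify
        thr = score_threshold * max_score
        for pid in sorted(promoters):
            seq = promoters[pid].upper()
            if len(seq) < m:
                continue
            enc = np.array([idx.get(b, 0) for b in seq], dtype=np.int64)
            wins = np.lib.stride_tricks.sliding_window_view(enc, m)
            fwd = lo[np.arange(m)[None, :], wins].sum(axis=1)
            rc = lo[::-1, :][:, ::-1]  # PWM applied to the reverse strand
            rev = rc[np.arange(m)[None, :], wins].sum(axis=1)
            hits = []
            for off in np.flatnonzero((fwd >= thr) & (fwd > 0)):
                hits.append((int(off), "+", float(fwd[off])))
            for off in np.flatnonzero((rev >= thr) & (rev > 0)):
                hits.append((int(off), "-", float(rev[off])))
            # merge overlapping hits of this PWM to the best one
            hits.sort(key=lambda h: (h[0], h[1]))
            merged: list[tuple[int, str, float]] = []
            for h in hits:
                if merged and h[0] < merged[-1][0] + m:
                    if h[2] > merged[-1][2]:
                        merged[-1] = h
                else:
                    merged.append(h)
            for off, strand, score in merged:
                rows.append((pwm.tf_id, pid, off, strand, score))
    return pd.DataFrame(rows, columns=["tf", "promoter", "offset",
                                       "strand", "score"])


# ------------------------------------------------------------- edge tables


def build_tables(
    tmi_hits: pd.DataFrame,
    tti_hits: pd.DataFrame,
    mti_pairs: Iterable[tuple[str, str]],
) -> tuple[list[RegulatoryInteraction], list[RegulatoryInteraction],
           list[RegulatoryInteraction]]:
    """Deduplicated typed edge tables (TMI, TTI, MTI).

    ``tmi_hits``/``tti_hits`` are scan tables whose promoter column names
    miRNAs / target genes respectively; ``mti_pairs`` comes from the
    targeting consensus (union or intersection, caller's choice).
    """

    def dedupe(hits: pd.DataFrame, kind: str) -> list[RegulatoryInteraction]:
        seen = set()
        out = []
        for row in hits.itertuples(index=False):
            key = (row.tf, row.promoter)
            if key in seen:
                continue
            seen.add(key)
            out.append(RegulatoryInteraction(kind, row.tf, row.promoter, "tfbs"))
        return out

    tmi = dedupe(tmi_hits, "TMI")
    tti = dedupe(tti_hits, "TTI")
    seen = set()
    mti = []
    for m, g in mti_pairs:
        if (m, g) not in seen:
            seen.add((m, g))
            mti.append(RegulatoryInteraction("MTI", m, g, "targeting"))
    return tmi, tti, mti


# -------------------------------------------------------------- enumeration


def enumerate_motifs(
    tmi: Sequence[RegulatoryInteraction],
    mti: Sequence[RegulatoryInteraction],
    tti: Sequence[RegulatoryInteraction],
) -> tuple[list[tuple[str, str, str]], list[FflMotif]]:
    """Cascades (TF->miRNA->target) and feed-forward loops.

    A cascade joins a TMI to an MTI on the shared miRNA; an FFL is a
    cascade whose (TF, target) edge exists in the TTI table. Hash joins
    keep this linear in the output size.
    """
    mti_by_mirna: dict[str, list[str]] = {}
    for e in mti:
        mti_by_mirna.setdefault(e.source, []).append(e.target)
    tti_set = {(e.source, e.target) for e in tti}
    cascades: list[tuple[str, str, str]] = []
    ffls: list[FflMotif] = []
    for e in tmi:
        for g in mti_by_mirna.get(e.target, ()):
            cascades.append((e.source, e.target, g))
            if (e.source, g) in tti_set:
                ffls.append(FflMotif(e.source, e.target, g))
    return cascades, ffls


def module_view(ffls: Sequence[FflMotif],
                cascades: Sequence[tuple[str, str, str]],
                hub: str) -> nx.DiGraph:
    """Induced sub-network of one miRNA hub: its cascades and closed FFLs."""
    known = {m for _tf, m, _g in cascades} | {f.mirna for f in ffls}
    if hub not in known:
        raise KeyError(f"unknown hub miRNA {hub!r}")
    g = nx.DiGraph()
    for tf, m, tgt in cascades:
        if m != hub:
            continue
        g.add_node(tf, kind="TF")
        g.add_node(m, kind="miRNA")
        g.add_node(tgt, kind="target")
        g.add_edge(tf, m, kind="TMI")
        g.add_edge(m, tgt, kind="MTI")
    for f in ffls:
        if f.mirna == hub:
            g.add_edge(f.tf, f.target, kind="TTI")
    return g


def build_graph(tmi: Sequence[RegulatoryInteraction],
                mti: Sequence[RegulatoryInteraction],
                tti: Sequence[RegulatoryInteraction]) -> nx.DiGraph:
    g = nx.DiGraph()
    kinds = {"TMI": ("TF", "miRNA"), "MTI": ("miRNA", "target"),
             "TTI": ("TF", "target")}
    for e in list(tmi) + list(mti) + list(tti):
        skind, tkind = kinds[e.kind]
        if e.source not in g:
            g.add_node(e.source, kind=skind)
        if e.target not in g:
            g.add_node(e.target, kind=tkind)
        g.add_edge(e.source, e.target, kind=e.kind)
    return g


# ------------------------------------------------------------------- export


def export_network(graph: nx.DiGraph, prefix: str) -> dict[str, str]:
    """Write SIF, GraphML and node/edge attribute TSVs; returns the paths."""
    paths = {
        "sif": f"{prefix}.sif",
        "graphml": f"{prefix}.graphml",
        "nodes": f"{prefix}.nodes.tsv",
        "edges": f"{prefix}.edges.tsv",
    }
    with open(paths["sif"], "w") as fh:
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{d.get('kind', 'edge')}\t{v}\n")
    nx.write_graphml(graph, paths["graphml"])
    pd.DataFrame(
        [(n, d.get("kind", "")) for n, d in sorted(graph.nodes(data=True))],
        columns=["node", "kind"]).to_csv(paths["nodes"], sep="\t", index=False)
    pd.DataFrame(
        [(u, v, d.get("kind", "")) for u, v, d in sorted(graph.edges(data=True))],
        columns=["source", "target", "kind"]).to_csv(
            paths["edges"], sep="\t", index=False)
    return paths
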