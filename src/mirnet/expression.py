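"""Abundance quantification and expression-pattern analysis.

miRNA abundance is RPM over reads that map inside a locus's precursor
with their 5' end within 2 nt of the mature 5' end (exact sequence
matches only, since mapping is exact). Transcript abundance is FPKM.
Pattern classes follow the <10 / >500 RPM convention on tissue means;
profile clustering is k-means (k = 16 by default) on per-entity z-scored
tissue means; pairwise-tissue differential expression uses a two-sided
Fisher exact test on pooled counts vs library totals with BH correction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, MirnaLocus, ReadStack

PATTERN_CLASSES = ("overall_high", "overall_low", "tissue_specific_high", "ordinary")


def quantify_mirna(
    stacks_per_library: Mapping[str, list[ReadStack]],
    loci: Sequence[MirnaLocus],
    library_totals: Mapping[str, int],
    samples: Mapping[str, tuple[str, str]],
    shift_tol: int = 2,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """RPM matrix (and raw counts) per locus x library.

    A stack counts toward a locus when one of its placements lies inside
    the precursor on the locus strand with its 5' end within ``shift_tol``
    nt of the mature 5' end.
    """
    for lib, total in library_totals.items():
        if total <= 0:
            raise ValueError(f"zero library total for {lib}")
    libs = list(stacks_per_library)
    by_key: dict[tuple[str, str], list[tuple[int, int, int, str]]] = {}
    for loc in loci:
        by_key.setdefault((loc.precursor.chrom, loc.precursor.strand), []).append(
            (loc.precursor.start, loc.precursor.end,
             loc.mature.five_prime(), loc.id))
    counts = pd.DataFrame(0, index=[l.id for l in loci], columns=libs, dtype=int)
    for lib, stacks in stacks_per_library.items():
        col = {lid: 0 for lid in counts.index}
        for st in stacks:
            n = st.per_library_counts.get(lib, 0)
            if n == 0:
                continue
            hit_loci = set()
            for p in st.placements:
                for ps, pe, mfp, lid in by_key.get((p.chrom, p.strand), ()):
                    if ps <= p.start and p.end <= pe \
                            and abs(p.five_prime() - mfp) <= shift_tol:
                        hit_loci.add(lid)
            for lid in hit_loci:
                col[lid] += n
        counts[lib] = pd.Series(col)
    rpm = counts.astype(float)
    for lib in libs:
        rpm[lib] = counts[lib] / library_totals[lib] * 1e6
    return ExpressionMatrix(rpm, samples, "RPM"), counts


def quantify_transcripts(
    counts: pd.DataFrame,
    lengths: Mapping[str, int],
    library_totals: Mapping[str, int],
    samples: Mapping[str, tuple[str, str]],
) -> ExpressionMatrix:
    """FPKM = count / (length/1e3) / (total/1e6)."""
    for tx in counts.index:
        if lengths[tx] <= 0:
            raise ValueError(f"zero length for transcript {tx}")
    fpkm = counts.astype(float).copy()
    lens = np.array([lengths[tx] for tx in counts.index], dtype=float)
    for lib in counts.columns:
        if library_totals[lib] <= 0:
            raise ValueError(f"zero library total for {lib}")
        fpkm[lib] = counts[lib] / (lens / 1e3) / (library_totals[lib] / 1e6)
    return ExpressionMatrix(fpkm, samples, "FPKM")


def classify_patterns(matrix: ExpressionMatrix, low: float = 10.0,
                      high: float = 500.0) -> pd.Series:
    """Per-entity class over tissue means: ``overall_high`` (> high in all
    tissues), ``overall_low`` (< low in all), ``tissue_specific_high``
    (> high somewhere but not everywhere), else ``ordinary``."""
    means = matrix.tissue_means()
    out = {}
    for ent, row in means.iterrows():
        if (row > high).all():
            out[ent] = "overall_high"
        elif (row < low).all():
            out[ent] = "overall_low"
        elif (row > high).any():
            out[ent] = "tissue_specific_high"
        else:
            out[ent] = "ordinary"
    return pd.Series(out, name="pattern")


def cluster_profiles(matrix: ExpressionMatrix, k: int = 16,
                     seed: int = 0, n_init: int = 50) -> pd.Series:
    """k-means over per-entity z-scored tissue-mean profiles (shapes, not
    magnitudes); deterministic for a fixed seed."""
    means = matrix.tissue_means()
    if k > len(means):
        raise ValueError(f"k={k} exceeds {len(means)} entities")
    X = means.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    return pd.Series(km.labels_, index=means.index, name="cluster")


def differential_expression(
    raw_counts: pd.DataFrame,
    samples: Mapping[str, tuple[str, str]],
    library_totals: Mapping[str, int],
    tissue_a: str,
    tissue_b: str,
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Pairwise-tissue DE table: log2FC on mean RPM, Fisher exact p on
    pooled counts, BH-adjusted p, and an up/down/ns call."""
    libs_a = [s for s in raw_counts.columns if samples[s][0] == tissue_a]
    libs_b = [s for s in raw_counts.columns if samples[s][0] == tissue_b]
    if not libs_a or not libs_b:
        raise ValueError("both tissues need at least one replicate")
    tot_a = sum(library_totals[l] for l in libs_a)
    tot_b = sum(library_totals[l] for l in libs_b)
    rpm_a = raw_counts[libs_a].div(
        pd.Series({l: library_totals[l] for l in libs_a}), axis=1).mean(axis=1) * 1e6
    rpm_b = raw_counts[libs_b].div(
        pd.Series({l: library_totals[l] for l in libs_b}), axis=1).mean(axis=1) * 1e6
    log2fc = np.log2((rpm_a + pseudocount) / (rpm_b + pseudocount))
    pvals = []
    for ent in raw_counts.index:
        ca = int(raw_counts.loc[ent, libs_a].sum())
        cb = int(raw_counts.loc[ent, libs_b].sum())
        table = [[ca, tot_a - ca], [cb, tot_b - cb]]
        pvals.append(stats.fisher_exact(table, alternative="two-sided")[1])
    padj = multipletests(pvals, method="fdr_bh")[1]
    call = np.where((np.abs(log2fc) >= fc_cut) & (padj < p_cut),
                    np.where(log2fc > 0, "up", "down"), "ns")
    return pd.DataFrame({"log2fc": log2fc, "p": pvals, "p_adj": padj,
                         "call": call}, index=raw_counts.index)


def replicate_consistency(matrix: ExpressionMatrix
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue replicate Pearson r and 2-component PCA coordinates of
    log-transformed samples."""
    rows = []
    by_tissue: dict[str, list[str]] = {}
    for sid in matrix.values.columns:
        by_tissue.setdefault(matrix.samples[sid][0], []).append(sid)
    for tissue, sids in by_tissue.items():
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                a = matrix.values[sids[i]]
                b = matrix.values[sids[j]]
                if a.std() == 0 or b.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                rows.append((tissue, sids[i], sids[j], r))
    pairs = pd.DataFrame(rows, columns=["tissue", "sample_a", "sample_b", "r"])
    X = np.log2(matrix.values.to_numpy(dtype=float).T + 1.0)
    ncomp = min(2, X.shape[0], X.shape[1])
    coords = PCA(n_components=ncomp, random_state=0).fit_transform(X)
    pca = pd.DataFrame(coords[:, :2] if ncomp == 2 else
                       np.column_stack([coords, np.zeros(len(coords))]),
                       index=matrix.values.columns, columns=["PC1", "PC2"])
    return pairs, pca
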