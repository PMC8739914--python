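"""miRNA-target expression correlation over tissue means.

Replicates are averaged within tissues first, so the Pearson coefficient
runs over n = number of tissues points and significance comes from the
Student t transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 degrees of
freedom (two-sided). With the paper-standard 4-tissue panel this leaves
df = 2, so p < 0.05 demands |r| > 0.95 — significance is deliberately
stringent. Zero-variance profiles leave r undefined; such records are
flagged degenerate and excluded from summaries rather than zero-filled.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .types import CorrelationRecord, ExpressionMatrix

BIN_LABELS = ("[-1,-0.5)", "[-0.5,0)", "0", "(0,0.5]", "(0.5,1]")


def pearson_with_t_pvalue(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided t-test p-value (closed form)."""
    n = len(x)
    r = float(pd.Series(x).corr(pd.Series(y)))
    if math.isnan(r):
        return float("nan"), float("nan")
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate(
    mirna_matrix: ExpressionMatrix,
    transcript_matrix: ExpressionMatrix,
    pairs: Iterable[tuple[str, str]],
) -> list[CorrelationRecord]:
    """Correlation records for (miRNA id, transcript id) pairs."""
    mm = mirna_matrix.tissue_means()
    tm = transcript_matrix.tissue_means()
    shared = [t for t in mm.columns if t in set(tm.columns)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared tissues; need >= 3")
    records = []
    for mid, tid in pairs:
        if mid not in mm.index:
            raise KeyError(f"unknown miRNA {mid}")
        if tid not in tm.index:
            raise KeyError(f"unknown transcript {tid}")
        x = mm.loc[mid, shared].to_numpy(dtype=float)
        y = tm.loc[tid, shared].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            records.append(CorrelationRecord(mid, tid, float("nan"),
                                             float("nan"), len(shared),
                                             degenerate=True))
            continue
        r, p = pearson_with_t_pvalue(x, y)
        rec = CorrelationRecord(mid, tid, r, p, len(shared))
        rec.bin = assign_bin(r)
        records.append(rec)
    return records


def assign_bin(r: float) -> str:
    """Five-section binning: [-1,-0.5), [-0.5,0), {0}, (0,0.5], (0.5,1]."""
    if r < -0.5:
        return BIN_LABELS[0]
    if r < 0:
        return BIN_LABELS[1]
    if r == 0:
        return BIN_LABELS[2]
    if r <= 0.5:
        return BIN_LABELS[3]
    return BIN_LABELS[4]


def bin_records(records: Sequence[CorrelationRecord]) -> dict[str, int]:
    counts = {lab: 0 for lab in BIN_LABELS}
    for rec in records:
        if rec.degenerate:
            continue
        counts[rec.bin or assign_bin(rec.r)] += 1
    return counts


def negative_fraction(records: Sequence[CorrelationRecord],
                      r_cut: float = -0.9, p_cut: float = 0.05
                      ) -> tuple[float, int, int]:
    """Proportion of records with r < r_cut and p < p_cut (the paper-style
    strict negative-regulation fraction); returns (fraction, hits, total)."""
    usable = [rec for rec in records if not rec.degenerate]
    if not usable:
        raise ValueError("no usable correlation records")
    hits = sum(1 for rec in usable if rec.r < r_cut and rec.p < p_cut)
    return hits / len(usable), hits, len(usable)


def records_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    """TSV/heatmap-ready export: one row per pair with significance stars."""
    rows = []
    for rec in records:
        star = "" if rec.degenerate or rec.p >= 0.05 else "*"
        rows.append((rec.mirna_id, rec.transcript_id, rec.r, rec.p, rec.n,
                     rec.bin or "", star, rec.degenerate))
    return pd.DataFrame(rows, columns=["mirna", "transcript", "r", "p", "n",
                                       "bin", "sig", "degenerate"])
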