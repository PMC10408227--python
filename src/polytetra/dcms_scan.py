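"""Composite selection scan: DCMS over windowed statistics.

The scan combines several window statistics (here Delta-CLR, F_ST,
Delta-Tajima's D, and Fay-Wu's H) into a single decorrelated composite of
multiple signals (DCMS).  Each statistic is first made Gaussian by a
two-step normalization — percentile rank, then inverse-normal transform —
and converted to a one-sided p-value oriented so that sweep-like signal maps
to small p.  The composite for a window is

    DCMS = sum_i log10((1 - p_i) / p_i) / sum_j |r_ij|

where r_ij is the Pearson correlation between the p-value columns of
statistics i and j across windows; the denominator down-weights statistics
that duplicate information already carried by correlated partners.  Window
p-values for the composite are obtained by re-normalizing the DCMS scores
with the same two-step procedure and taking the upper tail; windows with
p < alpha are called as putatively selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GenotypeMatrix, IntervalSet, ValidationError

#: orientation of each scan statistic: which tail indicates selection
DEFAULT_DIRECTIONS = {
    "delta_clr": "upper",
    "fst": "upper",
    "delta_d": "upper",
    "fay_wu_h": "lower",
}


def make_windows(
    gm: GenotypeMatrix,
    window_bp: int = 25_000,
    min_snps: int = 10,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Non-overlapping windows tiled from coordinate 0 on each chromosome.

    The final partial window of a chromosome is emitted; windows with fewer
    than ``min_snps`` SNPs are dropped.  Chromosome lengths default to the
    last SNP position when not supplied.
    """
    rows = []
    for chrom in pd.unique(gm.chrom):
        pos0 = gm.pos[gm.chrom == chrom] - 1
        if pos0.size == 0:
            continue
        if chrom_lengths is not None and str(chrom) in chrom_lengths:
            length = int(chrom_lengths[str(chrom)])
        else:
            length = int(pos0.max()) + 1
        start = 0
        while start < length:
            end = min(start + window_bp, length)
            n = int(np.sum((pos0 >= start) & (pos0 < end)))
            if n >= min_snps:
                rows.append(
                    {"chrom": chrom, "start": start, "end": end, "n_snps": n}
                )
            start += window_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])


def two_step_normalize(values: np.ndarray) -> np.ndarray:
    """Percentile-rank then inverse-normal transform to Z scores.

    Ties get average ranks; rank r of n maps to the uniform score r/(n+1)
    before the standard-normal quantile.  Missing (NaN) values stay missing.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    n = int(ok.sum())
    if n < 3:
        raise ValidationError("two_step_normalize needs >= 3 non-missing values")
    ranks = stats.rankdata(values[ok], method="average")
    out[ok] = stats.norm.ppf(ranks / (n + 1))
    return out


def stat_p(z: np.ndarray, direction: str) -> np.ndarray:
    """One-sided normal p-values from Z scores.

    ``upper``: p = 1 - Phi(z) (large z -> small p); ``lower``: p = Phi(z).
    """
    z = np.asarray(z, dtype=float)
    if direction == "upper":
        return stats.norm.sf(z)
    if direction == "lower":
        return stats.norm.cdf(z)
    raise ValidationError(f"unknown direction {direction!r}")


def dcms_combine(p_matrix: np.ndarray):
    """DCMS scores from a windows x statistics matrix of one-sided p-values.

    Returns (dcms vector, correlation matrix, per-statistic weights), with
    weight_i = sum_j |r_ij| (>= 1, since r_ii = 1).  Rows with any missing
    p-value get a missing score; correlations use complete rows only.
    """
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3 or p.shape[1] < 1:
        raise ValidationError("need >= 3 windows and >= 1 statistic")
    complete = ~np.isnan(p).any(axis=1)
    if complete.sum() < 3:
        raise ValidationError("need >= 3 complete windows for correlations")
    k = p.shape[1]
    if k == 1:
        corr = np.ones((1, 1))
    else:
        sub = p[complete]
        if np.any(sub.std(axis=0) == 0):
            raise ValidationError("constant p-value column: correlation undefined")
        corr = np.corrcoef(sub, rowvar=False)
    weights = np.abs(corr).sum(axis=1)
    with np.errstate(divide="ignore"):
        terms = np.log10((1.0 - p) / p)
    dcms = (terms / weights[np.newaxis, :]).sum(axis=1)
    return dcms, corr, weights


def call_selected_windows(
    windows: pd.DataFrame,
    dcms: np.ndarray,
    genes: IntervalSet | None = None,
    alpha: float = 0.05,
):
    """Window p-values from re-normalized DCMS scores, and overlapping genes.

    DCMS scores are passed through the same two-step normalization and an
    upper-tail p assigned; windows with p < alpha are flagged.  Genes with
    any base-pair overlap with a flagged window are returned de-duplicated.
    """
    dcms = np.asarray(dcms, dtype=float)
    if len(dcms) != len(windows):
        raise ValidationError("dcms vector length != number of windows")
    z = two_step_normalize(dcms)
    p = stat_p(z, "upper")
    out = windows.reset_index(drop=True).copy()
    out["dcms"] = dcms
    out["p_dcms"] = p
    out["selected"] = p < alpha
    gene_ids: list[str] = []
    if genes is not None and len(genes) and out["selected"].any():
        trees = genes.trees()
        seen = set()
        for w in out[out["selected"]].itertuples(index=False):
            tree = trees.get(str(w.chrom))
            if tree is None:
                continue
            for hit in tree.overlap(w.start, w.end):
                label = genes.df.iloc[hit.data]["label"]
                if label not in seen:
                    seen.add(label)
                    gene_ids.append(label)
    return out, gene_ids


def dcms_scan(
    stat_table: pd.DataFrame,
    directions: dict | None = None,
    genes: IntervalSet | None = None,
    alpha: float = 0.05,
):
    """Full scan: normalize each statistic column, combine, and call windows.

    ``stat_table`` carries chrom/start/end plus the statistic columns named
    in ``directions`` (default: the four-statistic sweep orientation).
    Returns the annotated window table (z_*, p_* columns, dcms, p_dcms,
    selected), the correlation matrix, the weights, and the gene list.
    """
    directions = DEFAULT_DIRECTIONS if directions is None else directions
    cols = [c for c in directions if c in stat_table.columns]
    if not cols:
        raise ValidationError("no statistic columns found in table")
    p_cols = []
    out = stat_table.reset_index(drop=True).copy()
    for c in cols:
        z = two_step_normalize(out[c].to_numpy())
        p = stat_p(z, directions[c])
        out[f"z_{c}"] = z
        out[f"p_{c}"] = p
        p_cols.append(p)
    p_matrix = np.column_stack(p_cols)
    dcms, corr, weights = dcms_combine(p_matrix)
    called, gene_ids = call_selected_windows(
        out[["chrom", "start", "end"]], dcms, genes, alpha
    )
    out["dcms"] = called["dcms"]
    out["p_dcms"] = called["p_dcms"]
    out["selected"] = called["selected"]
    return out, corr, weights, gene_ids
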