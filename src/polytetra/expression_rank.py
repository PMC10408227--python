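"""TPM normalization, allele-dosage expression, and rank-based DEG calling.

RNA-seq counts are normalized to transcripts per million (TPM) and usually
log2-transformed.  Two analyses follow.  First, gene expression (mean log2
TPM over a gene's alleles) is compared across allele-count groups with
pairwise Wilcoxon rank-sum tests, asking whether retaining more allelic
copies raises expression.  Second, differential expression between diploid
and autotetraploid samples is called by a rank-based nonparametric
procedure: within each sample, genes are sorted from high to low expression
and assigned a percentile rank (1 = most expressed, 100 = least); because
percentile ranks are invariant to any per-sample monotone distortion, the
procedure is robust to library-size and batch effects.  Per-gene group
differences in rank are tested with the Wilcoxon rank-sum test and
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import ValidationError


@dataclass
class ExpressionMatrix:
    """Gene-by-sample counts with gene lengths and sample annotations."""

    counts: pd.DataFrame  # genes x samples, nonnegative
    gene_length_bp: pd.Series  # per gene, > 0
    group: pd.Series  # per sample, e.g. diploid/tetraploid
    batch: pd.Series  # per sample

    def __post_init__(self) -> None:
        if (self.gene_length_bp <= 0).any():
            raise ValidationError("gene lengths must be positive")
        if not self.gene_length_bp.index.equals(self.counts.index):
            raise ValidationError("length index must match count rows")
        for ann in (self.group, self.batch):
            if not set(self.counts.columns) <= set(ann.index):
                raise ValidationError("every sample needs group and batch labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")


def tpm(em: ExpressionMatrix, log2: bool = True) -> pd.DataFrame:
    """Transcripts per million; optionally log2(TPM + 1).

    TPM divides each count by gene length in kb and rescales each sample so
    the column sums to 1e6 before the log transform.
    """
    rate = em.counts.div(em.gene_length_bp / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        raise ValidationError("sample with all-zero counts")
    t = rate.div(colsum, axis=1) * 1e6
    return np.log2(t + 1.0) if log2 else t


def allele_dosage_expression(
    allele_tpm: pd.DataFrame,
    allele_map: pd.Series,
    allele_counts: pd.Series,
    expressed_min_tpm: float | None = None,
):
    """Gene expression by allele-count group, with adjacent-group tests.

    ``allele_tpm`` is log2 TPM per allele (rows) per sample; ``allele_map``
    maps allele id -> gene id; ``allele_counts`` maps gene id -> retained
    allele number.  Gene expression is the mean log2 TPM over its alleles,
    averaged across samples.  When ``expressed_min_tpm`` is given, only
    genes whose every allele exceeds log2(min+1) are kept.  Returns the
    per-gene table and a frame of two-sided Wilcoxon rank-sum p-values
    between adjacent allele-count groups (NaN when a group has < 2 genes).
    """
    mapped = allele_map[allele_map.index.isin(allele_tpm.index)]
    per_allele = allele_tpm.loc[mapped.index].mean(axis=1)
    df = pd.DataFrame({"gene": mapped, "expr": per_allele})
    if expressed_min_tpm is not None:
        thresh = np.log2(expressed_min_tpm + 1.0)
        ok = df.groupby("gene")["expr"].transform("min") > thresh
        df = df[ok]
    gene_expr = df.groupby("gene")["expr"].mean()
    out = pd.DataFrame(
        {"expr": gene_expr, "n_alleles": allele_counts.reindex(gene_expr.index)}
    ).dropna()
    out["n_alleles"] = out["n_alleles"].astype(int)
    groups = sorted(out["n_alleles"].unique())
    rows = []
    for lo, hi in zip(groups[:-1], groups[1:]):
        x = out.loc[out["n_alleles"] == lo, "expr"].to_numpy()
        y = out.loc[out["n_alleles"] == hi, "expr"].to_numpy()
        p = (
            float("nan")
            if min(len(x), len(y)) < 2
            else float(stats.ranksums(x, y).pvalue)
        )
        rows.append({"group_low": lo, "group_high": hi, "p_value": p})
    return out, pd.DataFrame(rows)


def percentile_rank_profiles(expr: pd.DataFrame) -> pd.DataFrame:
    """Percentile ranks (1..100) per gene within each sample.

    Genes are ordered from high to low expression; a gene at (average,
    tie-shared) position ``r`` of ``n`` gets percentile ceil(100 r / n), so
    the most expressed gene lands in bucket 1.  Invariant to any strictly
    increasing per-sample transform of expression.
    """
    n = len(expr)
    if n == 0:
        raise ValidationError("empty expression matrix")
    out = {}
    for col in expr.columns:
        # rank 1 = highest expression, ties share the average position
        desc_rank = stats.rankdata(-expr[col].to_numpy(), method="average")
        out[col] = np.ceil(100.0 * desc_rank / n)
    return pd.DataFrame(out, index=expr.index)


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p, exact for small groups.

    For groups of at most 10 the exact null distribution is used: scipy's
    closed-form exact method when the pooled values are tie-free, otherwise
    full permutation enumeration (which conditions on the observed tie
    pattern).  Larger groups fall back to the normal approximation with
    continuity correction.
    """
    if max(len(x), len(y)) <= 10:
        if len(np.unique(np.concatenate([x, y]))) == len(x) + len(y):
            method = "exact"
        else:
            if np.ptp(np.concatenate([x, y])) == 0:
                return 1.0
            method = stats.PermutationMethod(n_resamples=200_000)
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def rank_deg(
    rank_matrix: pd.DataFrame, group: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank-based DEG calls between two sample groups.

    Per gene, a two-sided Wilcoxon rank-sum test compares percentile ranks
    between the two groups; p-values are Benjamini-Hochberg adjusted and
    genes with q < alpha are flagged.
    """
    labels = group.reindex(rank_matrix.columns)
    uniq = labels.dropna().unique()
    if len(uniq) != 2:
        raise ValidationError("need exactly two sample groups")
    ga = rank_matrix.loc[:, labels == uniq[0]].to_numpy()
    gb = rank_matrix.loc[:, labels == uniq[1]].to_numpy()
    if ga.shape[1] < 2 or gb.shape[1] < 2:
        raise ValidationError("need >= 2 samples per group")
    pvals = np.array(
        [_wilcoxon_rank_sum(ga[i], gb[i]) for i in range(rank_matrix.shape[0])]
    )
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "p_value": pvals,
            "q_value": qvals,
            "is_deg": qvals < alpha,
        },
        index=rank_matrix.index,
    )
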