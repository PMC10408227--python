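"""Allele-loss and genome-structure association analysis.

In an autotetraploid each gene locus carries up to four allelic copies, one
per homologous chromosome; loci retaining fewer than four are said to show
allele loss, while loci with more than four reflect copy gain.  This module
summarizes allele-count tables, groups structural variants (SVs) that are
the same event seen in several monoploid genomes, classifies genes by
proximity to SVs and overlap with transposable elements (TEs), flags genes
with protein-protein interaction (PPI) evidence via reciprocal best hits,
and tests each contrast for enrichment of allele loss with Fisher's exact
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_core import IntervalSet, ValidationError

logger = logging.getLogger(__name__)

SV_TYPES = ("inversion", "translocation", "duplication")
ALLELE_CLASSES = ("1", "2", "3", "4", ">4")


@dataclass
class ContingencyResult:
    table: tuple  # (a, b, c, d)
    odds_ratio: float
    p_value: float


def allele_summary(allele_table: pd.Series | dict) -> pd.DataFrame:
    """Counts, percentages, and mean of per-gene allele numbers.

    Genes are classed by allele count {1, 2, 3, 4, >4}; percentages are
    reported to two decimals of the total gene count, and the mean is total
    alleles over total genes.
    """
    s = pd.Series(allele_table, dtype="int64")
    if s.empty:
        raise ValidationError("empty allele table")
    if (s < 0).any():
        raise ValidationError("allele counts must be nonnegative")
    total_genes = len(s)
    total_alleles = int(s.sum())
    rows = []
    for cls in ALLELE_CLASSES:
        n = int((s > 4).sum()) if cls == ">4" else int((s == int(cls)).sum())
        rows.append(
            {
                "allele_class": cls,
                "n_genes": n,
                "percent": round(100.0 * n / total_genes, 2),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total_genes"] = total_genes
    out.attrs["total_alleles"] = total_alleles
    out.attrs["mean_alleles_per_gene"] = round(total_alleles / total_genes, 2)
    return out


def _reciprocal_overlap_ok(s1, e1, s2, e2) -> bool:
    """Overlap must reach 50% of the shorter interval."""
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return False
    shorter = min(e1 - s1, e2 - s2)
    return ov >= 0.5 * shorter


def group_identical_svs(svs: pd.DataFrame, allelic_map: dict) -> pd.DataFrame:
    """Group SV records that are the same event across monoploid genomes.

    ``svs`` columns: chrom, start, end (diploid reference coordinates),
    sv_type, monoploid.  Two SVs join one group when (1) they overlap by at
    least 50% of the shorter interval on the reference, (2) their source
    chromosomes belong to the same homologous group per ``allelic_map``
    (chromosome name -> group id), and (3) they are the same SV type.
    Connected components become groups; each group's presence class is the
    set of member monoploids (one of the 15 nonempty subsets of {A,B,C,D}).

    Returns the input frame with added ``group_id`` and ``presence_class``
    columns.
    """
    svs = svs.reset_index(drop=True)
    for c in svs["chrom"].unique():
        if c not in allelic_map:
            raise ValidationError(f"chromosome {c!r} missing from allelic map")
    n = len(svs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    by_key: dict[tuple, list[int]] = {}
    for i, row in svs.iterrows():
        key = (allelic_map[row["chrom"]], row["sv_type"])
        by_key.setdefault(key, []).append(i)
    for members in by_key.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if _reciprocal_overlap_ok(
                    svs.at[i, "start"],
                    svs.at[i, "end"],
                    svs.at[j, "start"],
                    svs.at[j, "end"],
                ):
                    union(i, j)
    roots = [find(i) for i in range(n)]
    ids = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    out = svs.copy()
    out["group_id"] = [ids[r] for r in roots]
    presence = out.groupby("group_id")["monoploid"].agg(
        lambda m: "".join(sorted(set(m)))
    )
    out["presence_class"] = out["group_id"].map(presence)
    return out


def classify_gene_sv(
    genes: IntervalSet, svs: IntervalSet, margin_bp: int = 2000
) -> pd.Series:
    """Classify each gene as within_sv, near_sv (<= margin), or far.

    A gene is ``within_sv`` on any base-pair overlap with an SV; otherwise
    ``near_sv`` when the gap to the nearest SV is at most ``margin_bp``;
    otherwise ``far``.
    """
    overlap_trees = svs.trees()
    # widening by margin+1 makes a gap of exactly margin_bp register as an
    # overlap under the half-open convention (gap margin_bp+1 does not)
    near_trees = svs.trees(margin_bp=margin_bp + 1)
    out = []
    for g in genes.df.itertuples(index=False):
        t0 = overlap_trees.get(str(g.chrom))
        if t0 is not None and t0.overlap(g.start, g.end):
            out.append("within_sv")
            continue
        t1 = near_trees.get(str(g.chrom))
        if t1 is not None and t1.overlap(g.start, g.end):
            out.append("near_sv")
        else:
            out.append("far")
    return pd.Series(out, index=genes.df["label"].to_numpy(), name="sv_class")


def flag_te_overlap(genes: IntervalSet, tes: IntervalSet) -> pd.Series:
    """True iff a gene span overlaps any TE interval by >= 1 bp."""
    trees = tes.trees()
    out = []
    for g in genes.df.itertuples(index=False):
        t = trees.get(str(g.chrom))
        out.append(bool(t is not None and t.overlap(g.start, g.end)))
    return pd.Series(out, index=genes.df["label"].to_numpy(), name="te_overlap")


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> list[tuple]:
    """Reciprocal best hits between two protein sets.

    Each table has columns query_id, subject_id, score (higher is better).
    A pair (a, b) is returned iff b is a's best hit and a is b's best hit.
    Score ties are broken by lexicographically smallest subject id (logged).
    """

    def best(hits: pd.DataFrame) -> dict:
        out: dict[str, tuple] = {}
        for row in hits.itertuples(index=False):
            cur = out.get(row.query_id)
            cand = (-float(row.score), str(row.subject_id))
            if cur is None or cand < cur:
                if cur is not None and cand[0] == cur[0]:
                    logger.info(
                        "reciprocal_best_hits: score tie for %s broken "
                        "lexicographically (%s over %s)",
                        row.query_id,
                        min(cand[1], cur[1]),
                        max(cand[1], cur[1]),
                    )
                out[row.query_id] = cand
            elif cand[0] == cur[0]:
                logger.info(
                    "reciprocal_best_hits: score tie for %s broken "
                    "lexicographically (%s over %s)",
                    row.query_id,
                    cur[1],
                    cand[1],
                )
        return {q: s for q, (_, s) in out.items()}

    ab = best(hits_ab)
    ba = best(hits_ba)
    return sorted((a, b) for a, b in ab.items() if ba.get(b) == a)


def fisher_enrichment(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    p is the sum of probabilities of all tables (fixed margins) no more
    likely than the observed one; the odds ratio is the sample ad/bc
    (inf when bc = 0, nan for the 0/0 case).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValidationError("counts must be nonnegative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValidationError("zero margin: contrast undefined")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(table=(a, b, c, d), odds_ratio=odds, p_value=float(p))


def breakpoint_density(n_breakpoints: int, genome_size_bp: int) -> float:
    """Assembly breakpoints per megabase of anchored sequence."""
    if genome_size_bp <= 0:
        raise ValidationError("genome size must be positive")
    if n_breakpoints < 0:
        raise ValidationError("breakpoint count must be nonnegative")
    return n_breakpoints / (genome_size_bp / 1e6)


def loss_association_report(genes: pd.DataFrame) -> pd.DataFrame:
    """Allele-loss enrichment contrasts for SV proximity, TE overlap, PPI.

    ``genes`` columns: gene_id, n_alleles, sv_class, te_overlap, ppi.  Loss
    means n_alleles < 4.  For each contrast the report gives the 2x2 table,
    the within-stratum proportions (to two decimals), the odds ratio, and
    the Fisher p-value.  The SV contrast is reported both merged (within or
    near) and for the within-only category.
    """
    loss = genes["n_alleles"] < 4
    if loss.all() or (~loss).all():
        raise ValidationError("need both loss and no-loss genes for contrasts")
    contrasts = {
        "sv_within_or_near": genes["sv_class"].isin(["within_sv", "near_sv"]),
        "sv_within": genes["sv_class"] == "within_sv",
        "te_overlap": genes["te_overlap"].astype(bool),
        "ppi": genes["ppi"].astype(bool),
    }
    rows = []
    for name, flag in contrasts.items():
        a = int((loss & flag).sum())
        b = int((loss & ~flag).sum())
        c = int((~loss & flag).sum())
        d = int((~loss & ~flag).sum())
        res = fisher_enrichment(a, b, c, d)
        rows.append(
            {
                "contrast": name,
                "loss_flagged": a,
                "loss_unflagged": b,
                "noloss_flagged": c,
                "noloss_unflagged": d,
                "loss_pct": round(100.0 * a / (a + b), 2),
                "noloss_pct": round(100.0 * c / (c + d), 2),
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
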