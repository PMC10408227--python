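"""Self-contained validation experiments over synthetic data.

Each function runs one calibration or parameter-recovery experiment end to
end — generating its own synthetic inputs, running the relevant pipeline
stage, and measuring the result — and returns plain numbers.  They back both
the acceptance tests and the reproduction script, so the problem sizes here
are the package's reference study conditions (documented in the methods
note).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import dcms_scan, expression_rank, genome_structure, popgen_stats
from .inheritance_sfs import (
    CoalescentConfig,
    fit_inheritance,
    ks_two_sample,
    simulate_locus,
    simulate_sfs,
)
from .io_core import GenotypeMatrix
from .synthetic_data import (
    SynthConfig,
    synth_expression,
    synth_sweep_windows,
    synth_two_pop_genotypes,
)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# coalescent SFS calibration


def tetrasomic_sfs_experiment(
    seed: int, n_individuals: int = 2, theta: float = 1.0, n_loci: int = 10_000
) -> dict:
    """Unfolded tetrasomic SFS against the neutral expectation theta/i.

    Simulates ``n_loci`` independent loci for ``n_individuals`` tetraploids
    (one pool of 4n exchangeable chromosomes) and compares each unfolded
    class total with ``n_loci * theta / i``, in units of the Monte-Carlo
    standard error estimated from the across-locus variance.
    """
    rng = np.random.default_rng(seed)
    n_chrom = 4 * n_individuals
    sums = np.zeros(n_chrom - 1)
    sumsq = np.zeros(n_chrom - 1)
    for _ in range(n_loci):
        dos = simulate_locus("tetrasomic", 0.0, theta, n_individuals, rng)
        der = dos.sum(axis=1)
        xi = np.bincount(der, minlength=n_chrom)[1:n_chrom]
        sums += xi
        sumsq += xi.astype(float) ** 2
    mean = sums / n_loci
    var = sumsq / n_loci - mean**2
    se = np.sqrt(var * n_loci)
    expected = n_loci * theta / np.arange(1, n_chrom)
    z = (sums - expected) / se
    return {
        "observed": sums,
        "expected": expected,
        "max_abs_z": float(np.max(np.abs(z))),
        "n_loci": n_loci,
    }


def inheritance_recovery_experiment(
    seed: int,
    n_trials: int = 10,
    true_td: float = 0.6,
    true_proportion: float = 0.3,
    n_individuals: int = 12,
    theta: float = 2.0,
    n_loci: int = 24_000,
) -> dict:
    """Recover a planted disomic genome fraction from simulated SFS data.

    Each trial simulates an observed frequency sample under the truth
    (``true_proportion`` of loci disomic at ``true_td``) and fits the
    proportion grid at the matched td.  The td is fixed because weakly
    disomic models (small td) of any proportion are statistically close to
    mixtures with older td and smaller proportion — the proportion is only
    identifiable at a given td.  Success = the fitted upper bound
    (max non-rejected proportion) within one grid step (0.1) of the truth.
    """
    seeds = _spawn_seeds(seed, 2 * n_trials)
    recovered = []
    for trial in range(n_trials):
        truth = CoalescentConfig(
            n_individuals=n_individuals,
            theta=theta,
            n_loci=n_loci,
            td=true_td,
            disomic_proportion=true_proportion,
            seed=int(seeds[2 * trial]),
        )
        _, obs = simulate_sfs(truth)
        fit = fit_inheritance(
            obs,
            CoalescentConfig(
                n_individuals=n_individuals,
                theta=theta,
                n_loci=n_loci,
                td_grid=(true_td,),
                seed=int(seeds[2 * trial + 1]),
            ),
        )
        recovered.append(fit.max_nonrejected_proportion)
    successes = sum(
        1 for r in recovered if abs(r - true_proportion) <= 0.1 + 1e-9
    )
    return {"recovered": recovered, "successes": successes, "n_trials": n_trials}


# ---------------------------------------------------------------------------
# DCMS calibration


def dcms_duplication_invariance(seed: int, n_windows: int = 200) -> float:
    """Max |DCMS difference| when a statistic column is duplicated.

    The correlation-sum weighting halves each copy's contribution while the
    term appears twice, leaving the composite unchanged.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.001, 0.999, size=(n_windows, 1))
    single, _, _ = dcms_scan.dcms_combine(p)
    doubled, _, _ = dcms_scan.dcms_combine(np.hstack([p, p]))
    return float(np.max(np.abs(single - doubled)))


def null_dcms_selection_rate(seed: int, n_windows: int = 1000) -> dict:
    """Fraction of windows called selected on null (signal-free) statistics.

    Four independent standard-normal statistic columns stand in for a scan
    with no selective signal; the selection rate at alpha = 0.05 should sit
    at the nominal level.
    """
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_windows) * 25_000,
            "end": (np.arange(n_windows) + 1) * 25_000,
            "delta_clr": rng.normal(size=n_windows),
            "fst": rng.normal(size=n_windows),
            "delta_d": rng.normal(size=n_windows),
            "fay_wu_h": rng.normal(size=n_windows),
        }
    )
    out, _, _, _ = dcms_scan.dcms_scan(table)
    return {"rate": float(out["selected"].mean()), "n_windows": n_windows}


def sweep_rank_experiment(seed: int) -> dict:
    """DCMS ranking of windows carrying a planted sweep signature.

    Simulates two-population genotypes (8 diploids vs 8 tetraploids), plants
    intensity-0.9 sweeps in the tetraploid population in designated 25 kb
    windows, computes windowed F_ST, delta Tajima's D and Fay-Wu's H from
    two-allele subsampled tetraploid data, scans with DCMS, and reports the
    mean percentile rank (1 = best) of the truth windows.
    """
    seeds = _spawn_seeds(seed, 3)
    cfg = SynthConfig(
        seed=int(seeds[0]),
        n_diploid=8,
        n_tetraploid=8,
        n_loci=900,
        theta=2.0,
        split_time=0.2,
        chrom_length=2_000_000,
        n_chroms=2,
    )
    gm = synth_two_pop_genotypes(cfg)
    sweep_windows = [
        ("chr1", 200_000, 225_000, 0.9),
        ("chr1", 800_000, 825_000, 0.9),
        ("chr1", 1_400_000, 1_425_000, 0.9),
        ("chr2", 400_000, 425_000, 0.9),
        ("chr2", 1_000_000, 1_025_000, 0.9),
        ("chr2", 1_600_000, 1_625_000, 0.9),
    ]
    tet = [s for s in gm.samples if s.startswith("tet")]
    dip = [s for s in gm.samples if s.startswith("dip")]
    gm, truth = synth_sweep_windows(
        gm, sweep_windows, intensity=0.9, seed=int(seeds[1]), samples=tet
    )
    windows = dcms_scan.make_windows(gm, window_bp=25_000, min_snps=10)
    tet_table = popgen_stats.window_scan_table(gm, windows, tet, other_pop=dip)
    dip_table = popgen_stats.window_scan_table(gm, windows, dip)
    stat = windows.copy()
    stat["fst"] = tet_table["fst"]
    stat["delta_d"] = dip_table["tajima_d"] - tet_table["tajima_d"]
    stat["fay_wu_h"] = tet_table["fay_wu_h"]
    out, _, _, _ = dcms_scan.dcms_scan(stat)
    merged = out.merge(truth, on=["chrom", "start", "end"], how="left")
    is_sweep = merged["swept"].eq(True).to_numpy()
    # percentile rank of DCMS (1 = highest score)
    pct = stats.rankdata(-out["dcms"].to_numpy()) / len(out)
    mean_pct = float(np.mean(1.0 - pct[is_sweep]))
    return {
        "mean_rank_percentile": mean_pct,
        "n_windows": int(len(out)),
        "n_sweep_windows": int(is_sweep.sum()),
    }


# ---------------------------------------------------------------------------
# exact-oracle agreements


def fisher_oracle_max_diff(seed: int, n_tables: int = 200, max_margin: int = 30) -> float:
    """Two-sided Fisher p-values against exhaustive table enumeration."""

    def brute_p(a, b, c, d):
        r1, r2 = a + b, c + d
        c1 = a + c
        n = r1 + r2
        def prob(x):
            return (
                math.comb(r1, x)
                * math.comb(r2, c1 - x)
                / math.comb(n, c1)
            )
        p_obs = prob(a)
        lo = max(0, c1 - r2)
        hi = min(r1, c1)
        return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        while True:
            a, b, c, d = rng.integers(0, max_margin // 2 + 1, size=4)
            if min(a + b, c + d, a + c, b + d) > 0:
                break
        res = genome_structure.fisher_enrichment(int(a), int(b), int(c), int(d))
        worst = max(worst, abs(res.p_value - brute_p(int(a), int(b), int(c), int(d))))
    return worst


def bh_oracle_max_diff(seed: int, n_vectors: int = 50, max_len: int = 1000) -> float:
    """BH-adjusted p-values against a brute-force step-up implementation."""

    def brute_bh(p):
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        return q

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        p = rng.uniform(size=m)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        worst = max(worst, float(np.max(np.abs(q - brute_bh(p)))))
    return worst


def ks_oracle_max_diff(seed: int, n_pairs: int = 200, max_n: int = 50) -> float:
    """KS D statistics against a brute-force double-loop ECDF oracle."""

    def brute_d(x, y, side):
        pts = np.concatenate([x, y])
        best = 0.0
        for t in pts:
            fx = np.mean(x <= t)
            fy = np.mean(y <= t)
            if side == "greater":
                best = max(best, fx - fy)
            elif side == "less":
                best = max(best, fy - fx)
            else:
                best = max(best, abs(fx - fy))
        return best

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        nx = int(rng.integers(1, max_n + 1))
        ny = int(rng.integers(1, max_n + 1))
        # discrete support encourages ties within and between samples
        x = rng.integers(0, 10, size=nx) / 10.0
        y = rng.integers(0, 10, size=ny) / 10.0
        for side in ("greater", "less", "two-sided"):
            res = ks_two_sample(x, y, side)
            worst = max(worst, abs(res.d_stat - brute_d(x, y, side)))
    return worst


# ---------------------------------------------------------------------------
# F_ST calibration


def fst_fixed_difference(n_per_pop: int = 8, n_sites: int = 20) -> float:
    """Windowed W&C F_ST when the two populations are fixed for different
    alleles (expected value 1)."""
    dosage = np.hstack(
        [
            np.zeros((n_sites, n_per_pop), dtype=np.int16),
            np.full((n_sites, n_per_pop), 2, dtype=np.int16),
        ]
    )
    names = [f"a{i}" for i in range(n_per_pop)] + [f"b{i}" for i in range(n_per_pop)]
    gm = GenotypeMatrix(
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1) * 100,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosage=dosage,
        ploidy=np.full(2 * n_per_pop, 2, dtype=np.int8),
        samples=names,
    )
    return popgen_stats.wc_fst(gm, names[:n_per_pop], names[n_per_pop:])


def fst_permutation_mean(seed: int, n_windows_min: int = 30) -> dict:
    """Mean windowed F_ST across random splits of one panmictic population."""
    seeds = _spawn_seeds(seed, 2)
    cfg = SynthConfig(
        seed=int(seeds[0]),
        n_diploid=16,
        n_tetraploid=1,  # unused below; generator requires >= 1
        n_loci=600,
        theta=2.0,
        split_time=0.0,
        chrom_length=1_500_000,
    )
    gm = synth_two_pop_genotypes(cfg)
    dip = [s for s in gm.samples if s.startswith("dip")]
    rng = np.random.default_rng(int(seeds[1]))
    perm = rng.permutation(len(dip))
    popA = [dip[i] for i in perm[: len(dip) // 2]]
    popB = [dip[i] for i in perm[len(dip) // 2 :]]
    windows = dcms_scan.make_windows(gm, window_bp=25_000, min_snps=5)
    vals = []
    pos0 = gm.pos - 1
    for w in windows.itertuples(index=False):
        m = (gm.chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        vals.append(popgen_stats.wc_fst(gm.take_sites(m), popA, popB))
    vals = np.array(vals, dtype=float)
    vals = vals[~np.isnan(vals)]
    return {"mean_fst": float(vals.mean()), "n_windows": int(vals.size)}


# ---------------------------------------------------------------------------
# expression calibration


def null_deg_type1_rate(seed: int, n_genes: int = 2000, n_replicates: int = 6) -> dict:
    """Fraction of genes with raw Wilcoxon p < 0.05 on null expression data.

    The null generator has no group fold-change but a 2x library-size batch
    shift, exercising the rank procedure's batch robustness.
    """
    cfg = SynthConfig(
        seed=seed,
        n_expr_genes=n_genes,
        n_replicates=n_replicates,
        batch_shift=2.0,
        deg_fraction=0.0,
    )
    em, _ = synth_expression(cfg)
    logtpm = expression_rank.tpm(em)
    ranks = expression_rank.percentile_rank_profiles(logtpm)
    res = expression_rank.rank_deg(ranks, em.group)
    return {
        "type1_rate": float((res["p_value"] < 0.05).mean()),
        "n_genes": n_genes,
    }


def rank_profile_invariance(seed: int, n_genes: int = 500) -> float:
    """Max rank difference after a per-sample strictly monotone transform."""
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.lognormal(2.0, 1.0, size=(n_genes, 6)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(6)],
    )
    base = expression_rank.percentile_rank_profiles(expr)
    transformed = expression_rank.percentile_rank_profiles(expr**3 * 7.5 + 2.0)
    return float((base - transformed).abs().to_numpy().max())
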