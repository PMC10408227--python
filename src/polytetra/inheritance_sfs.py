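"""Coalescent simulation of tetraploid site-frequency spectra and model fitting.

An autotetraploid may transmit its four homologous chromosomes in two extreme
modes.  Under *tetrasomic* inheritance all four homologs pair at random, so a
sample of chromosomes behaves as a single coalescent pool.  Under *disomic*
inheritance the homologs segregate as two fixed pairs (subgenomes) that stop
exchanging lineages; coalescences between subgenomes can then only happen
deeper in time than ``td``, the epoch (in units of 4N generations) at which
the disomic regime began.  Long isolation between subgenomes piles up
fixed inter-subgenome differences, visible in genotype data as sites where
every individual carries exactly two derived alleles — an excess of mass at
the 50% frequency class of the folded SFS.

This module simulates independent neutral loci under either mode (or a
mixture: a fraction of loci disomic), builds folded SFS and per-site
minor-allele-frequency samples, compares them with an observed SFS by
one-sided two-sample Kolmogorov–Smirnov tests, and bounds the fraction of
the genome compatible with disomic inheritance.

Time is scaled so that a deme of relative size 1 corresponds to the full
pool of 4N chromosomes: within a deme of relative size ``s``, each pair of
lineages coalesces at rate ``1/s`` per unit time.  Mutations are placed as
Poisson(theta/2 x branch length) under the infinite-sites model, which gives
the standard neutral expectation E[xi_i] = theta / i for the unfolded SFS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .io_core import ValidationError

DEFAULT_TD_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_PROPORTION_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class CoalescentConfig:
    """Grid and per-locus parameters for inheritance-model simulation."""

    n_individuals: int = 12
    theta: float = 1.0
    n_loci: int = 1000
    td: float = 0.6
    disomic_proportion: float = 0.0
    td_grid: tuple = DEFAULT_TD_GRID
    proportion_grid: tuple = DEFAULT_PROPORTION_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValidationError("counts must be positive")
        if self.td < 0:
            raise ValidationError("td must be nonnegative")
        if not 0.0 <= self.disomic_proportion <= 1.0:
            raise ValidationError("disomic_proportion must lie in [0, 1]")


@dataclass
class SFS:
    """Site-frequency spectrum over a fixed chromosome sample size."""

    counts: np.ndarray
    n_chromosomes: int
    folded: bool

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = (
            self.n_chromosomes // 2 if self.folded else self.n_chromosomes - 1
        )
        if len(self.counts) != expected:
            raise ValidationError(
                f"SFS length {len(self.counts)} != {expected} for "
                f"n={self.n_chromosomes}, folded={self.folded}"
            )
        if np.any(self.counts < 0):
            raise ValidationError("SFS counts must be nonnegative")


@dataclass
class KsCompareResult:
    d_stat: float
    p_value: float
    side: str


@dataclass
class InheritanceFit:
    """KS grid over (td, disomic proportion) models plus the tetrasomic model."""

    results: dict  # (td, proportion) -> KsCompareResult; tetrasomic key (0.0, 0.0)
    best_model: tuple
    max_nonrejected_proportion: float


# ---------------------------------------------------------------------------
# structured coalescent core

_EYE_CACHE: dict[int, np.ndarray] = {}


def _identity_rows(n: int) -> np.ndarray:
    if n not in _EYE_CACHE:
        _EYE_CACHE[n] = np.eye(n, dtype=np.int16)
    return _EYE_CACHE[n]


def simulate_structured_locus(
    samples_per_deme: list,
    deme_sizes: list,
    merge_time: float,
    theta: float,
    rng: np.random.Generator,
    n_individuals: int | None = None,
):
    """Simulate one neutral locus under demes that merge into one pool.

    Parameters
    ----------
    samples_per_deme : list of lists; element ``d`` maps each sampled lineage
        of deme ``d`` to its individual index.
    deme_sizes : relative deme sizes before the merge (pair coalescence rate
        is ``1/size``); after ``merge_time`` all lineages join one deme of
        relative size 1.
    merge_time : epoch (in 4N-generation units) at which demes merge;
        0 collapses to a single-pool Kingman coalescent.
    theta : scaled mutation rate; mutations ~ Poisson(theta/2 x tree length).

    Returns
    -------
    (n_sites, n_individuals) int array of per-individual derived-allele
    dosages, one row per segregating site (0 rows if no mutation).
    """
    if n_individuals is None:
        n_individuals = 1 + max(
            (i for deme in samples_per_deme for i in deme), default=0
        )
    # active lineage state: per-individual descendant count vectors
    # (leaf vectors are shared read-only rows of an identity matrix)
    eye = _identity_rows(n_individuals)
    demes = [[eye[ind] for ind in deme] for deme in samples_per_deme]
    segments: list[tuple[np.ndarray, float]] = []  # (descendants, branch length)
    birth: list[list[float]] = [[0.0] * len(d) for d in demes]

    log = math.log

    def coalesce_pair(lin, bt, t, rng):
        k = len(lin)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        segments.append((lin[i], t - bt[i]))
        segments.append((lin[j], t - bt[j]))
        merged = lin[i] + lin[j]
        lin[j] = lin[-1]
        bt[j] = bt[-1]
        lin[i] = merged
        bt[i] = t
        lin.pop()
        bt.pop()

    t = 0.0
    # epoch 1: separate demes until merge_time
    if merge_time > 0:
        while True:
            rates = [
                len(d) * (len(d) - 1) / 2.0 / s if len(d) > 1 else 0.0
                for d, s in zip(demes, deme_sizes)
            ]
            total = sum(rates)
            if total == 0.0:
                t = merge_time
                break
            wait = -log(1.0 - rng.random()) / total
            if t + wait >= merge_time:
                t = merge_time
                break
            t += wait
            u = rng.random() * total
            d = 0
            acc = rates[0]
            while u >= acc:
                d += 1
                acc += rates[d]
            coalesce_pair(demes[d], birth[d], t, rng)
    # epoch 2: single ancestral pool of relative size 1
    lin = [v for d in demes for v in d]
    bt = [x for b in birth for x in b]
    while len(lin) > 1:
        rate = len(lin) * (len(lin) - 1) / 2.0
        t += -log(1.0 - rng.random()) / rate
        coalesce_pair(lin, bt, t, rng)

    if theta <= 0 or not segments:
        return np.empty((0, n_individuals), dtype=np.int16)
    lengths = np.array([s[1] for s in segments])
    n_mut = rng.poisson(0.5 * theta * lengths)
    rows = []
    total_sampled = sum(len(d) for d in samples_per_deme)
    for (desc, _), m in zip(segments, n_mut):
        nd = int(desc.sum())
        if nd == 0 or nd == total_sampled:
            continue  # non-segregating in the sample
        for _ in range(int(m)):
            rows.append(desc)
    if not rows:
        return np.empty((0, n_individuals), dtype=np.int16)
    return np.vstack(rows)


def simulate_locus(
    mode: str,
    td: float,
    theta: float,
    n_individuals: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-individual derived dosages for one locus of a tetraploid sample.

    ``tetrasomic``: all 4 x n_individuals lineages in one deme of size 1.
    ``disomic``: each individual contributes 2 lineages to each of two demes
    of relative size 0.5 (the subgenomes); the demes merge at ``td``.
    """
    inds = list(range(n_individuals))
    if mode == "tetrasomic":
        samples = [[i for i in inds for _ in range(4)]]
        return simulate_structured_locus(
            samples, [1.0], 0.0, theta, rng, n_individuals
        )
    if mode == "disomic":
        half = [i for i in inds for _ in range(2)]
        return simulate_structured_locus(
            [half, list(half)], [0.5, 0.5], td, theta, rng, n_individuals
        )
    raise ValidationError(f"unknown inheritance mode {mode!r}")


# ---------------------------------------------------------------------------
# SFS construction


def _fold_class(i: int, n: int) -> int:
    return min(i, n - i)


def simulate_sfs(cfg: CoalescentConfig, rng=None):
    """Aggregate folded SFS and a per-locus minor-allele-frequency sample.

    A fraction ``cfg.disomic_proportion`` of the ``cfg.n_loci`` loci is
    simulated under the disomic model at ``cfg.td``; the rest tetrasomic.
    The SFS pools every segregating site.  The returned frequency sample
    holds ONE randomly chosen segregating site per locus: sites within a
    locus share a genealogy and are strongly correlated, so the one-per-
    locus sample is what the (iid-assuming) KS comparison may use.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_chrom = 4 * cfg.n_individuals
    counts = np.zeros(n_chrom // 2, dtype=np.int64)
    freqs = []
    n_disomic = int(round(cfg.disomic_proportion * cfg.n_loci))
    for locus in range(cfg.n_loci):
        mode = "disomic" if locus < n_disomic else "tetrasomic"
        dos = simulate_locus(mode, cfg.td, cfg.theta, cfg.n_individuals, rng)
        if dos.shape[0] == 0:
            continue
        der = dos.sum(axis=1)
        minor = np.minimum(der, n_chrom - der)
        seg = minor[minor >= 1]
        if seg.size == 0:
            continue
        counts += np.bincount(seg, minlength=n_chrom // 2 + 1)[1:]
        freqs.append(seg[int(rng.integers(seg.size))] / n_chrom)
    freq_sample = np.asarray(freqs, dtype=float)
    return SFS(counts, n_chrom, folded=True), freq_sample


def observed_sfs(gm, samples: list):
    """Folded minor-allele SFS of tetraploid samples from a genotype matrix.

    Sites with any missing dosage among the named samples are skipped.
    """
    idx = gm.sample_indices(samples)
    if not np.all(gm.ploidy[idx] == 4):
        raise ValidationError("all named samples must be tetraploid")
    d = gm.dosage[:, idx]
    complete = np.all(d != -1, axis=1)
    d = d[complete]
    n_chrom = 4 * len(samples)
    alt = d.sum(axis=1)
    minor = np.minimum(alt, n_chrom - alt)
    seg = minor >= 1
    if d.shape[0] == 0:
        raise ValidationError("no complete sites among the named samples")
    counts = np.bincount(minor[seg], minlength=n_chrom // 2 + 1)[1:]
    return SFS(counts, n_chrom, folded=True), minor[seg] / n_chrom


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov comparison


def ks_two_sample(x, y, side: str = "two-sided") -> KsCompareResult:
    """Two-sample KS test with explicit one-sided variants.

    ``greater``: D+ = sup(ECDF_x - ECDF_y), small p when y is stochastically
    larger than x.  ``less``: D- = sup(ECDF_y - ECDF_x).  One-sided p uses
    the asymptotic bound exp(-2 m n D^2 / (m+n)); two-sided p the Kolmogorov
    distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("KS test needs nonempty samples")
    grid = np.concatenate([x, y])
    grid.sort()
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    d_plus = float(np.max(fx - fy))
    d_minus = float(np.max(fy - fx))
    m, n = x.size, y.size
    en = m * n / (m + n)
    if side == "greater":
        d = max(d_plus, 0.0)
        p = math.exp(-2.0 * en * d * d)
    elif side == "less":
        d = max(d_minus, 0.0)
        p = math.exp(-2.0 * en * d * d)
    elif side == "two-sided":
        d = max(d_plus, d_minus)
        p = float(special.kolmogorov(math.sqrt(en) * d))
    else:
        raise ValidationError(f"unknown side {side!r}")
    return KsCompareResult(d_stat=d, p_value=min(1.0, p), side=side)


def fit_inheritance(
    observed_freqs,
    cfg: CoalescentConfig,
    alpha: float = 0.05,
    side: str = "greater",
    n_chromosomes: int | None = None,
) -> InheritanceFit:
    """Grid KS comparison of an observed frequency sample against models.

    For every (td, proportion) on the grids — plus the pure tetrasomic model,
    keyed (0.0, 0.0) — a frequency sample of ``cfg.n_loci`` loci is simulated
    and compared with the observed sample.  The default one-sided orientation
    asks whether the simulated model carries more intermediate-frequency mass
    than the data; a model is rejected when p < alpha.  The reported
    ``max_nonrejected_proportion`` is the largest grid proportion whose
    best-over-td p-value is >= alpha (0 if all rejected), i.e. the upper
    bound on the disomic genome fraction compatible with the data.
    """
    observed_freqs = np.asarray(observed_freqs, dtype=float)
    if (
        n_chromosomes is not None
        and n_chromosomes != 4 * cfg.n_individuals
    ):
        raise ValidationError(
            f"observed sample size ({n_chromosomes} chromosomes) does not "
            f"match the simulation grid ({4 * cfg.n_individuals})"
        )
    rng = np.random.default_rng(cfg.seed)
    results: dict[tuple, KsCompareResult] = {}

    def locus_pool(mode: str, td: float) -> np.ndarray:
        pool_cfg = CoalescentConfig(
            n_individuals=cfg.n_individuals,
            theta=cfg.theta,
            n_loci=cfg.n_loci,
            td=td,
            disomic_proportion=1.0 if mode == "disomic" else 0.0,
            seed=cfg.seed,
        )
        _, f = simulate_sfs(pool_cfg, rng)
        return f

    # the tetrasomic pool is shared by every mixture model; each td gets one
    # disomic pool, and a proportion-p model reuses the first p*n_loci
    # disomic loci plus (1-p)*n_loci tetrasomic loci — the same mixture law
    # as a dedicated simulation, at a fraction of the cost
    tet_pool = locus_pool("tetrasomic", 0.0)
    results[(0.0, 0.0)] = ks_two_sample(observed_freqs, tet_pool, side)
    per_locus_tet = len(tet_pool) / cfg.n_loci  # segregating fraction
    for td in cfg.td_grid:
        dis_pool = locus_pool("disomic", td)
        per_locus_dis = len(dis_pool) / cfg.n_loci
        for prop in cfg.proportion_grid:
            n_dis = int(round(prop * cfg.n_loci) * per_locus_dis)
            n_tet = int(round((1.0 - prop) * cfg.n_loci) * per_locus_tet)
            sim = np.concatenate([dis_pool[:n_dis], tet_pool[:n_tet]])
            results[(td, prop)] = ks_two_sample(observed_freqs, sim, side)
    best_model = min(results, key=lambda k: results[k].d_stat)
    max_prop = 0.0
    for prop in cfg.proportion_grid:
        best_p = max(
            results[(td, prop)].p_value for td in cfg.td_grid
        )
        if best_p >= alpha:
            max_prop = max(max_prop, prop)
    return InheritanceFit(
        results=results,
        best_model=best_model,
        max_nonrejected_proportion=max_prop,
    )
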