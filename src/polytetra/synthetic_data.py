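"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shapes of the study inputs — two-population
genotype matrices with a diploid and a tetraploid deme, sweep-distorted
windows, gene/SV/TE/PPI annotation tables with planted association odds
ratios, and RNA-seq count matrices with batch and allele-dosage effects —
without attempting base-level realism (no linkage within chromosomes, no
sequencing error).  All generators are deterministic given the seed.

Genotypes come from the same structured-coalescent engine used for
inheritance-model fitting: sites are independent loci from a two-deme
coalescent that splits at ``split_time`` (no migration), diploids sampled
from deme 1 and tetraploids from deme 2, with positions scattered uniformly
along synthetic chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inheritance_sfs import simulate_structured_locus
from .io_core import GenotypeMatrix, IntervalSet, ValidationError


@dataclass
class SynthConfig:
    """Knobs for all synthetic generators (counts, effects, planted truth)."""

    seed: int = 0
    n_diploid: int = 12
    n_tetraploid: int = 12
    n_loci: int = 2000
    theta: float = 1.0
    split_time: float = 0.1
    chrom_length: int = 1_000_000
    n_chroms: int = 1
    sweep_windows: list = field(default_factory=list)  # (chrom, start, end, intensity)
    # annotation generator
    n_genes: int = 5000
    or_sv: float = 1.0
    or_te: float = 1.0
    or_ppi: float = 1.0
    baseline_loss: float = 0.3
    sv_flag_rate: float = 0.2
    te_flag_rate: float = 0.5
    ppi_flag_rate: float = 0.7
    # expression generator
    n_expr_genes: int = 2000
    n_replicates: int = 6
    batch_shift: float = 1.0
    dosage_effect: float = 1.0
    deg_fraction: float = 0.0
    fold_change: float = 1.0
    nb_dispersion: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_diploid", "n_tetraploid", "n_loci", "n_genes",
                     "n_expr_genes", "n_replicates", "chrom_length", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("or_sv", "or_te", "or_ppi", "dosage_effect", "fold_change"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for _, _, _, intensity in self.sweep_windows:
            if not 0.0 <= intensity <= 1.0:
                raise ValidationError("sweep intensity must lie in [0, 1]")


# ---------------------------------------------------------------------------
# genotypes


def synth_two_pop_genotypes(cfg: SynthConfig) -> GenotypeMatrix:
    """Two-population genotypes: diploids (deme 1) vs tetraploids (deme 2).

    ``cfg.n_loci`` independent loci are simulated from a two-deme coalescent
    (equal deme sizes, merge at ``split_time``, no migration); every
    segregating site becomes one matrix site at a uniform position on a
    synthetic chromosome.  The reference allele is ancestral at every site
    (``ancestral_is_ref`` all True), and true derived frequencies per deme
    are stored in ``truth`` attributes on the returned matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ind = cfg.n_diploid + cfg.n_tetraploid
    dip = list(range(cfg.n_diploid))
    tet = list(range(cfg.n_diploid, n_ind))
    samples_deme1 = [i for i in dip for _ in range(2)]
    samples_deme2 = [i for i in tet for _ in range(4)]
    rows = []
    for _ in range(cfg.n_loci):
        dos = simulate_structured_locus(
            [samples_deme1, samples_deme2],
            [1.0, 1.0],
            cfg.split_time,
            cfg.theta,
            rng,
            n_individuals=n_ind,
        )
        if dos.shape[0]:
            rows.append(dos)
    if not rows:
        dosage = np.empty((0, n_ind), dtype=np.int16)
    else:
        dosage = np.vstack(rows)
    n_sites = dosage.shape[0]
    chroms = np.sort(rng.integers(0, cfg.n_chroms, size=n_sites))
    pos = np.empty(n_sites, dtype=np.int64)
    chrom_names = np.empty(n_sites, dtype=object)
    for c in range(cfg.n_chroms):
        m = chroms == c
        k = int(m.sum())
        p = np.sort(rng.choice(cfg.chrom_length, size=k, replace=False)) + 1
        pos[m] = p
        chrom_names[m] = f"chr{c + 1}"
    order = np.lexsort((pos, chroms))
    dosage = dosage[order]
    bases = np.array(list("ACGT"), dtype=object)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ploidy = np.array([2] * cfg.n_diploid + [4] * cfg.n_tetraploid, dtype=np.int8)
    names = [f"dip{i:03d}" for i in range(cfg.n_diploid)] + [
        f"tet{i:03d}" for i in range(cfg.n_tetraploid)
    ]
    gm = GenotypeMatrix(
        chrom=chrom_names[order] if n_sites else chrom_names,
        pos=pos[order] if n_sites else pos,
        ref=bases[ref_idx],
        alt=bases[alt_idx],
        dosage=dosage,
        ploidy=ploidy,
        samples=names,
        ancestral_is_ref=np.ones(n_sites, dtype=bool),
    )
    d_dip = dosage[:, : cfg.n_diploid]
    d_tet = dosage[:, cfg.n_diploid :]
    gm.truth = {
        "freq_diploid": d_dip.sum(axis=1) / (2 * cfg.n_diploid),
        "freq_tetraploid": d_tet.sum(axis=1) / (4 * cfg.n_tetraploid),
    }
    return gm


def synth_sweep_windows(
    gm: GenotypeMatrix,
    windows: list,
    intensity: float,
    seed: int = 0,
    samples: list | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Distort the SFS inside designated windows to mimic selective sweeps.

    Within each window (chrom, start, end), a fraction ``intensity`` of
    intermediate-frequency sites (pooled minor allele frequency >= 0.1) is
    removed, and a fraction ``intensity`` of the remaining polymorphic sites
    is pushed to high derived frequency (all but one chromosome derived),
    yielding negative Tajima's D and Fay-Wu's H signatures.  When
    ``samples`` is given, the sweep is confined to those samples: selected
    intermediate sites are set to dosage 0 there instead of being removed
    (leaving other samples untouched, as for a sweep in one population).
    Returns the distorted matrix and the truth window table.
    """
    if not 0.0 <= intensity <= 1.0:
        raise ValidationError("intensity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cols = (
        np.arange(gm.n_samples)
        if samples is None
        else gm.sample_indices(samples)
    )
    keep = np.ones(gm.n_sites, dtype=bool)
    dosage = gm.dosage.copy()
    pos0 = gm.pos - 1
    alt, n = gm.allele_counts()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(alt / np.maximum(n, 1), 1 - alt / np.maximum(n, 1))
    for chrom, start, end, *_ in windows:
        in_win = (gm.chrom == chrom) & (pos0 >= start) & (pos0 < end)
        inter = in_win & (maf >= 0.1)
        drop = np.flatnonzero(inter)
        drop = drop[rng.random(drop.size) < intensity]
        if samples is None:
            keep[drop] = False
        else:
            for i in drop:
                dosage[np.ix_([i], cols)] = 0
        remaining = np.flatnonzero(in_win & keep & (alt > 0))
        remaining = np.setdiff1d(remaining, drop)
        boost = remaining[rng.random(remaining.size) < intensity]
        for i in boost:
            # all chromosomes derived except one, placed in a random sample
            dosage[i, cols] = gm.ploidy[cols]
            j = cols[rng.integers(0, cols.size)]
            dosage[i, j] -= 1
    out = GenotypeMatrix(
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        dosage=dosage,
        ploidy=gm.ploidy,
        samples=list(gm.samples),
        ancestral_is_ref=gm.ancestral_is_ref,
    ).take_sites(keep)
    truth = pd.DataFrame(
        [(c, s, e) for c, s, e, *_ in windows],
        columns=["chrom", "start", "end"],
    )
    truth["swept"] = True
    return out, truth


# ---------------------------------------------------------------------------
# annotations


def synth_gene_annotations(cfg: SynthConfig):
    """Gene table with planted allele-loss associations, plus interval tracks.

    Per gene, SV-proximity, TE-overlap, and PPI flags are drawn as
    independent Bernoullis; allele-loss status is then drawn with odds
    ``baseline_loss_odds * or_sv^[sv] * or_te^[te] * or_ppi^[not ppi]`` so
    each configured odds ratio is the conditional loss odds ratio of its
    flag.  Loss genes draw allele count uniformly from {1, 2, 3}; others
    keep 4.  Gene, SV, and TE intervals are laid out on one synthetic
    chromosome so that interval classification recovers the planted flags.

    Returns (gene table, SV IntervalSet, TE IntervalSet, PPI gene-id set,
    gene IntervalSet).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    sv_flag = rng.random(n) < cfg.sv_flag_rate
    te_flag = rng.random(n) < cfg.te_flag_rate
    ppi_flag = rng.random(n) < cfg.ppi_flag_rate
    base_odds = cfg.baseline_loss / (1.0 - cfg.baseline_loss)
    odds = (
        base_odds
        * np.where(sv_flag, cfg.or_sv, 1.0)
        * np.where(te_flag, cfg.or_te, 1.0)
        * np.where(~ppi_flag, cfg.or_ppi, 1.0)
    )
    p_loss = odds / (1.0 + odds)
    loss = rng.random(n) < p_loss
    n_alleles = np.where(loss, rng.integers(1, 4, size=n), 4)

    gene_len, gap = 3000, 7000
    starts = np.arange(n, dtype=np.int64) * (gene_len + gap) + gap
    genes = pd.DataFrame(
        {
            "chrom": "chrS1",
            "start": starts,
            "end": starts + gene_len,
            "label": [f"gene{i:05d}" for i in range(n)],
            "source": "synthetic",
        }
    )
    sv_rows, te_rows = [], []
    sv_types = ("inversion", "translocation", "duplication")
    for i in np.flatnonzero(sv_flag):
        # half inside the gene, half just upstream within the 2 kb margin
        if rng.random() < 0.5:
            s = starts[i] + rng.integers(0, gene_len // 2)
            e = s + rng.integers(200, 1000)
        else:
            e = starts[i] - rng.integers(1, 2000)
            s = max(0, e - rng.integers(200, 1000))
        if e > s:
            sv_rows.append(
                ("chrS1", int(s), int(e), sv_types[int(rng.integers(0, 3))])
            )
    for i in np.flatnonzero(te_flag):
        s = starts[i] + rng.integers(0, gene_len - 300)
        te_rows.append(("chrS1", int(s), int(s + 300), "TE"))
    svs = IntervalSet(
        pd.DataFrame(sv_rows, columns=["chrom", "start", "end", "label"])
    )
    tes = IntervalSet(
        pd.DataFrame(te_rows, columns=["chrom", "start", "end", "label"])
    )
    gene_table = pd.DataFrame(
        {
            "gene_id": genes["label"],
            "n_alleles": n_alleles,
            "sv_flag": sv_flag,
            "te_overlap": te_flag,
            "ppi": ppi_flag,
        }
    )
    gene_table["sv_class"] = np.where(sv_flag, "within_sv", "far")
    ppi_ids = set(genes["label"][ppi_flag])
    gene_table.attrs["true_or"] = {
        "sv": cfg.or_sv,
        "te": cfg.or_te,
        "ppi": cfg.or_ppi,
    }
    return gene_table, svs, tes, ppi_ids, IntervalSet(genes)


# ---------------------------------------------------------------------------
# expression


def synth_expression(cfg: SynthConfig, allele_counts: pd.Series | None = None):
    """Negative-binomial count matrix with planted group and batch structure.

    Samples: ``n_replicates`` diploid and ``n_replicates`` tetraploid
    libraries split over two batches; batch 2 library sizes are multiplied
    by ``batch_shift``.  A fraction ``deg_fraction`` of genes carries a
    ``fold_change`` between groups; when ``allele_counts`` is given, gene
    mean expression is additionally scaled by
    ``dosage_effect ** (n_alleles - 4)``.  Returns an ExpressionMatrix-ready
    bundle: (counts, lengths, group, batch, truth table).
    """
    from .expression_rank import ExpressionMatrix

    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_expr_genes
    genes = [f"g{i:05d}" for i in range(g)]
    base_mu = np.exp(rng.normal(4.0, 1.5, size=g))
    lengths = pd.Series(rng.integers(500, 5000, size=g), index=genes)
    is_deg = rng.random(g) < cfg.deg_fraction
    up = rng.random(g) < 0.5
    fc = np.where(is_deg, np.where(up, cfg.fold_change, 1.0 / cfg.fold_change), 1.0)
    dosage_scale = np.ones(g)
    if allele_counts is not None:
        ac = allele_counts.reindex(genes).fillna(4).to_numpy()
        dosage_scale = cfg.dosage_effect ** (ac - 4.0)
    n_rep = cfg.n_replicates
    cols, groups, batches = [], {}, {}
    counts = np.zeros((g, 2 * n_rep), dtype=np.int64)
    for j in range(2 * n_rep):
        grp = "diploid" if j < n_rep else "tetraploid"
        rep = j if j < n_rep else j - n_rep
        batch = "b1" if rep < (n_rep + 1) // 2 else "b2"
        lib = 1.0 if batch == "b1" else cfg.batch_shift
        mu = base_mu * dosage_scale * lib
        if grp == "tetraploid":
            mu = mu * fc
        # NB with gene-wise dispersion alpha: var = mu + alpha mu^2
        alpha = cfg.nb_dispersion
        shape = 1.0 / alpha
        lam = rng.gamma(shape, mu * alpha)
        counts[:, j] = rng.poisson(lam)
        name = f"{grp[:3]}_{batch}_{rep:02d}"
        cols.append(name)
        groups[name] = grp
        batches[name] = batch
    cdf = pd.DataFrame(counts, index=genes, columns=cols)
    em = ExpressionMatrix(
        counts=cdf,
        gene_length_bp=lengths,
        group=pd.Series(groups),
        batch=pd.Series(batches),
    )
    truth = pd.DataFrame(
        {"gene": genes, "is_deg": is_deg, "fold_change": fc}
    ).set_index("gene")
    return em, truth
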