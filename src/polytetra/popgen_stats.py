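"""Windowed diversity and differentiation statistics for mixed-ploidy data.

Implements per-site nucleotide diversity (pi) and between-population
divergence (D_XY) over sliding or tiled windows, Tajima's D, Fay and Wu's H
(unnormalized, requiring outgroup polarization), the Weir–Cockerham F_ST
estimator with VCFtools-style weighted windowing, the delta statistics used
to contrast diploid and autotetraploid scans, and the molecular-clock
conversion from synonymous divergence (Ks) to absolute time.

Tetraploid samples contribute four chromosomes directly to allele counts;
the selection-scan path instead feeds two-allele subsampled matrices (see
``io_core.subsample_two_alleles``).  Statistics that are undefined on a
window (no SNPs, too few chromosomes, monomorphic) are reported as NaN,
never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GenotypeMatrix, ValidationError

WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps"]


@dataclass(frozen=True)
class WindowSpec:
    chrom: str
    start: int
    end: int
    n_snps: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("window end must exceed start")
        if self.n_snps < 0:
            raise ValidationError("n_snps must be nonnegative")


# ---------------------------------------------------------------------------
# per-window scalar statistics


def site_pi_terms(alt: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site expected pairwise difference 2 j (n - j) / (n (n - 1))."""
    n = np.asarray(n, dtype=float)
    alt = np.asarray(alt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * alt * (n - alt) / (n * (n - 1.0))
    out[n < 2] = np.nan
    return out


def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, e1, e2


def tajimas_d(alt: np.ndarray, n_chrom: int) -> float:
    """Tajima's D from alt-allele counts of the segregating sites in a window.

    ``n_chrom`` is the (fixed) number of sampled chromosomes.  Returns NaN
    when there are no segregating sites or fewer than 3 chromosomes.
    """
    alt = np.asarray(alt)
    seg = (alt > 0) & (alt < n_chrom)
    s = int(seg.sum())
    if s == 0 or n_chrom < 3:
        return float("nan")
    pi_total = float(np.sum(site_pi_terms(alt[seg], np.full(s, n_chrom))))
    a1, e1, e2 = _tajima_constants(n_chrom)
    var = e1 * s + e2 * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_total - s / a1) / np.sqrt(var)


def fay_wu_h(derived: np.ndarray, n_chrom: int) -> float:
    """Unnormalized Fay and Wu's H = theta_pi - theta_H over polarized sites.

    ``derived`` holds derived-allele counts (requires outgroup polarization);
    theta_H = sum over sites of 2 i^2 / (n (n - 1)) with i the derived count.
    Negative values indicate an excess of high-frequency derived alleles.
    """
    derived = np.asarray(derived, dtype=float)
    seg = (derived > 0) & (derived < n_chrom)
    if not np.any(seg) or n_chrom < 2:
        return float("nan")
    i = derived[seg]
    denom = n_chrom * (n_chrom - 1.0)
    theta_pi = float(np.sum(2.0 * i * (n_chrom - i) / denom))
    theta_h = float(np.sum(2.0 * i * i / denom))
    return theta_pi - theta_h


def wc_fst_components(dosage_a, ploidy_a, dosage_b, ploidy_b):
    """Per-site Weir–Cockerham variance components (a, b, c) for two pops.

    When every sample is diploid this is the standard two-level estimator
    with the observed-heterozygosity term (the VCFtools formulation).  With
    tetraploid samples, chromosomes are treated as haploid units (no
    within-individual component).  Missing dosages are excluded per site.
    Returns arrays (a, abc) of the among-population component and the total.
    """
    dosage_a = np.asarray(dosage_a)
    dosage_b = np.asarray(dosage_b)
    all_diploid = np.all(ploidy_a == 2) and np.all(ploidy_b == 2)
    n_sites = dosage_a.shape[0]
    a_out = np.full(n_sites, np.nan)
    abc_out = np.full(n_sites, np.nan)
    r = 2.0
    for i in range(n_sites):
        da = dosage_a[i][dosage_a[i] != -1]
        db = dosage_b[i][dosage_b[i] != -1]
        pa_chr = ploidy_a[dosage_a[i] != -1]
        pb_chr = ploidy_b[dosage_b[i] != -1]
        if all_diploid:
            n1, n2 = float(len(da)), float(len(db))  # individuals
            if n1 < 1 or n2 < 1 or n1 + n2 < 3:
                continue
            p1, p2 = da.sum() / (2 * n1), db.sum() / (2 * n2)
            h1 = np.mean(da == 1) if n1 else 0.0
            h2 = np.mean(db == 1) if n2 else 0.0
        else:
            # haploid view: each chromosome an independent unit
            n1, n2 = float(pa_chr.sum()), float(pb_chr.sum())
            if n1 < 1 or n2 < 1 or n1 + n2 < 3:
                continue
            p1, p2 = da.sum() / n1, db.sum() / n2
            h1 = h2 = 0.0
        n_bar = (n1 + n2) / r
        if n_bar <= 1:
            continue
        n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        if all_diploid:
            a = (n_bar / n_c) * (
                s2
                - (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
                / (n_bar - 1.0)
            )
            b = (n_bar / (n_bar - 1.0)) * (
                p_bar * (1 - p_bar)
                - s2 * (r - 1.0) / r
                - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
            )
            c = h_bar / 2.0
        else:
            a = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r) / (n_bar - 1.0)
            )
            b = (n_bar / (n_bar - 1.0)) * (
                p_bar * (1 - p_bar) - s2 * (r - 1.0) / r
            )
            c = 0.0
        a_out[i] = a
        abc_out[i] = a + b + c
    return a_out, abc_out


def wc_fst(gm: GenotypeMatrix, popA: list, popB: list, site_mask=None) -> float:
    """Windowed Weir–Cockerham theta: ratio of summed variance components.

    Negative estimates are reported as computed (not clipped).  Returns NaN
    for windows with no informative (polymorphic, called) sites.
    """
    ia, ib = gm.sample_indices(popA), gm.sample_indices(popB)
    dos = gm.dosage if site_mask is None else gm.dosage[site_mask]
    a, abc = wc_fst_components(
        dos[:, ia], gm.ploidy[ia], dos[:, ib], gm.ploidy[ib]
    )
    ok = ~np.isnan(abc) & (abc != 0)
    if not np.any(ok):
        return float("nan")
    denom = np.sum(abc[ok])
    if denom == 0:
        return float("nan")
    return float(np.sum(a[ok]) / denom)


# ---------------------------------------------------------------------------
# windowing


def sliding_windows(chrom_len: int, window_bp: int, step_bp: int):
    """Start/end pairs of sliding windows covering [0, chrom_len)."""
    starts = list(range(0, max(chrom_len - window_bp, 0) + 1, step_bp))
    if not starts:
        starts = [0]
    wins = [(s, min(s + window_bp, chrom_len)) for s in starts]
    last_end = wins[-1][1]
    if last_end < chrom_len:
        wins.append((starts[-1] + step_bp, chrom_len))
    return wins


def pi_windows(
    gm: GenotypeMatrix,
    samples: list,
    window_bp: int = 50_000,
    step_bp: int = 20_000,
    subsample_k: int | None = None,
    n_reps: int = 20,
    seed: int = 0,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Per-site pi in sliding windows, optionally averaging over individual
    subsamples.

    When ``subsample_k`` is given, ``k`` individuals are drawn ``n_reps``
    times and the reported pi is the mean across draws (the polyploid
    subsampling scheme).  The per-site denominator is the window length;
    windows shorter than ``window_bp`` at chromosome ends are emitted with
    their actual length.
    """
    if window_bp < step_bp:
        raise ValidationError("window_bp must be >= step_bp")
    rng = np.random.default_rng(seed)
    if subsample_k is None or subsample_k >= len(samples):
        draws = [list(samples)]
    else:
        draws = [
            list(np.asarray(samples)[rng.choice(len(samples), subsample_k, replace=False)])
            for _ in range(n_reps)
        ]
    rows = []
    for chrom in pd.unique(gm.chrom):
        on = gm.chrom == chrom
        pos0 = gm.pos[on] - 1  # to 0-based
        length = (
            chrom_lengths[str(chrom)]
            if chrom_lengths is not None
            else int(pos0.max()) + 1
        )
        per_draw_terms = []
        for ids in draws:
            idx = gm.sample_indices(ids)
            alt, n = gm.allele_counts(idx)
            per_draw_terms.append(site_pi_terms(alt[on], n[on]))
        for start, end in sliding_windows(length, window_bp, step_bp):
            in_win = (pos0 >= start) & (pos0 < end)
            vals = []
            for terms in per_draw_terms:
                t = terms[in_win]
                t = t[~np.isnan(t)]
                vals.append(t.sum() / (end - start))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": int(in_win.sum()),
                    "pi": float(np.mean(vals)),
                }
            )
    return pd.DataFrame(rows)


def dxy_windows(
    gm: GenotypeMatrix,
    popA: list,
    popB: list,
    region: tuple,
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Per-site D_XY over a syntenic region, tiled in ``window_bp`` steps.

    Regions of at least ``window_bp`` are tiled in non-overlapping windows
    (final remainder emitted whole); shorter regions are emitted as a single
    window.  Monomorphic or uncalled stretches count as identical sequence
    (D_XY contribution 0 over the stated length).
    """
    chrom, rstart, rend = region
    if rend <= rstart:
        raise ValidationError("empty region")
    ia, ib = gm.sample_indices(popA), gm.sample_indices(popB)
    on = (gm.chrom == chrom) & (gm.pos - 1 >= rstart) & (gm.pos - 1 < rend)
    alt_a, n_a = gm.allele_counts(ia)
    alt_b, n_b = gm.allele_counts(ib)
    pos0 = gm.pos - 1
    if rend - rstart < window_bp:
        bounds = [(rstart, rend)]
    else:
        bounds = []
        s = rstart
        while s + window_bp <= rend:
            bounds.append((s, s + window_bp))
            s += window_bp
        if s < rend:
            bounds.append((s, rend))
    rows = []
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(n_a > 0, alt_a / np.maximum(n_a, 1), np.nan)
        pb = np.where(n_b > 0, alt_b / np.maximum(n_b, 1), np.nan)
    site_dxy = pa * (1 - pb) + pb * (1 - pa)
    for start, end in bounds:
        m = on & (pos0 >= start) & (pos0 < end)
        vals = site_dxy[m]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_snps": int(m.sum()),
                "dxy": float(vals.sum() / (end - start)),
            }
        )
    return pd.DataFrame(rows)


def delta_stats(dip_table: pd.DataFrame, tet_table: pd.DataFrame) -> pd.DataFrame:
    """Delta statistics contrasting diploid and tetraploid window scans.

    delta_d = Tajima's D (diploid) - Tajima's D (tetraploid);
    delta_clr = CLR (tetraploid) - CLR (diploid).  Window sets must match;
    a missing input leaves the corresponding delta missing.
    """
    key = ["chrom", "start", "end"]
    if not dip_table[key].reset_index(drop=True).equals(
        tet_table[key].reset_index(drop=True)
    ):
        raise ValidationError("window sets differ between tables")
    out = dip_table[key].copy()
    if "tajima_d" in dip_table and "tajima_d" in tet_table:
        out["delta_d"] = (
            dip_table["tajima_d"].to_numpy() - tet_table["tajima_d"].to_numpy()
        )
    if "clr" in dip_table and "clr" in tet_table:
        out["delta_clr"] = (
            tet_table["clr"].to_numpy() - dip_table["clr"].to_numpy()
        )
    return out


def window_scan_table(
    gm: GenotypeMatrix,
    windows: pd.DataFrame,
    samples: list,
    other_pop: list | None = None,
) -> pd.DataFrame:
    """Per-window Tajima's D, Fay–Wu's H (when polarized) and, if a second
    population is given, Weir–Cockerham F_ST.

    ``windows`` must carry chrom/start/end columns (0-based half-open).
    Sites with missing calls among the chosen samples are dropped per window
    so the chromosome sample size stays fixed, as the estimators require.
    """
    idx = gm.sample_indices(samples)
    n_chrom = int(gm.ploidy[idx].sum())
    d = gm.dosage[:, idx]
    complete = np.all(d != -1, axis=1)
    alt = np.where(d == -1, 0, d).sum(axis=1)
    der, _, polarized = gm.derived_counts(idx)
    pos0 = gm.pos - 1
    rows = []
    for w in windows.itertuples(index=False):
        m = (gm.chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end) & complete
        row = {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "n_snps": int(m.sum()),
            "tajima_d": tajimas_d(alt[m], n_chrom),
            "fay_wu_h": (
                fay_wu_h(der[m & polarized], n_chrom)
                if gm.ancestral_is_ref is not None
                else float("nan")
            ),
        }
        if other_pop is not None:
            row["fst"] = wc_fst(gm, samples, other_pop, site_mask=m)
        rows.append(row)
    return pd.DataFrame(rows)


def ks_to_time(ks: float, mu: float) -> float:
    """Divergence time in years from synonymous divergence: T = Ks / (2 mu)."""
    if mu <= 0:
        raise ValidationError("mutation rate must be positive")
    if ks < 0:
        raise ValidationError("Ks must be nonnegative")
    return ks / (2.0 * mu)
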