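"""Genotype and interval containers, standard-format I/O, and SNP filtering.

The central container is :class:`GenotypeMatrix`: biallelic sites by samples,
with per-sample ploidy (2 for diploids, 4 for autotetraploids) and genotypes
stored as alternate-allele dosage.  Coordinates are 1-based for site positions
(VCF convention) and 0-based half-open for intervals; GFF3's 1-based closed
intervals are converted at the boundary.

Filtering follows the neutral/independent SNP recipe used for population
structure and scan inputs: drop sites inside coding sequence plus a flanking
margin, thin to a minimum inter-SNP distance, then drop rare alleles by minor
allele frequency.  Tetraploid genotypes can be reduced to pseudo-diploid
dosages by random subsampling of two of the four chromosomes per site, with
replicate-consistency checks via rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import pysam
import yaml
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call (distinct from dosage 0)
MISSING = -1


class ValidationError(ValueError):
    """Raised when an input violates a container or operation contract."""


@dataclass
class GenotypeMatrix:
    """Biallelic variant sites by samples, genotypes as alt-allele dosage.

    Attributes
    ----------
    chrom, pos : per-site chromosome name and 1-based position.
    ref, alt : per-site reference and alternate alleles.
    dosage : (n_sites, n_samples) integer array; ``MISSING`` encodes no call.
    ploidy : per-sample ploidy, each 2 or 4.
    samples : sample identifiers, order matching the dosage columns.
    ancestral_is_ref : optional per-site flag (True where the reference
        allele is ancestral, e.g. from an outgroup ``AA`` tag).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    ploidy: np.ndarray
    samples: list[str]
    ancestral_is_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        if self.dosage.shape != (self.n_sites, self.n_samples):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({self.n_sites}, {self.n_samples})"
            )
        if not np.all(np.isin(self.ploidy, (2, 4))):
            raise ValidationError("per-sample ploidy must be 2 or 4")
        called = self.dosage != MISSING
        if np.any(self.dosage[called] < 0) or np.any(
            (self.dosage > self.ploidy[np.newaxis, :]) & called
        ):
            raise ValidationError("dosage out of range 0..ploidy")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(f"positions not strictly increasing on {c}")
        if self.ancestral_is_ref is not None:
            self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=bool)
            if self.ancestral_is_ref.shape != (self.n_sites,):
                raise ValidationError("ancestral_is_ref length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from e

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[idx],
            ploidy=self.ploidy,
            samples=list(self.samples),
            ancestral_is_ref=(
                None if self.ancestral_is_ref is None else self.ancestral_is_ref[idx]
            ),
        )

    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """Alt-allele count and called-chromosome count per site.

        Missing genotypes are excluded from both numerator and denominator.
        """
        d = self.dosage if sample_idx is None else self.dosage[:, sample_idx]
        p = self.ploidy if sample_idx is None else self.ploidy[sample_idx]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=1)
        n = (called * p[np.newaxis, :]).sum(axis=1)
        return alt, n

    def derived_counts(self, sample_idx: np.ndarray | None = None):
        """Derived-allele count per site using ``ancestral_is_ref`` polarity.

        Returns (derived count, called chromosomes, polarized mask).
        Sites without polarization are flagged False in the mask.
        """
        alt, n = self.allele_counts(sample_idx)
        if self.ancestral_is_ref is None:
            return alt, n, np.zeros(self.n_sites, dtype=bool)
        der = np.where(self.ancestral_is_ref, alt, n - alt)
        return der, n, np.ones(self.n_sites, dtype=bool)


@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open, possibly overlapping."""

    df: pd.DataFrame  # columns: chrom, start, end, label, source

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise ValidationError(f"interval frame needs columns {required}")
        for col, default in (("label", ""), ("source", "")):
            if col not in self.df.columns:
                self.df[col] = default
        if len(self.df):
            if (self.df["start"] < 0).any():
                raise ValidationError("negative interval coordinates")
            if (self.df["start"] >= self.df["end"]).any():
                raise ValidationError("interval start >= end")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def trees(self, margin_bp: int = 0) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees, each interval widened by margin."""
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[str(chrom)] = IntervalTree.from_tuples(
                (max(0, s - margin_bp), e + margin_bp, i)
                for i, (s, e) in enumerate(zip(sub["start"], sub["end"]))
            )
        return out


@dataclass
class FilterConfig:
    """Neutral/independent SNP filter parameters (all in bp or fractions)."""

    cds_margin_bp: int = 20_000
    thin_bp: int = 20_000
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        if self.cds_margin_bp < 0 or self.thin_bp < 0:
            raise ValidationError("margins must be nonnegative")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValidationError("maf_min must lie in [0, 0.5]")

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Non-biallelic records are skipped (count logged).  GT fields define the
    dosage; an ``AA`` INFO tag, when present, sets per-site ancestral polarity.
    Mixed ploidy within one sample across sites is rejected.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chrom, pos, ref, alt, anc = [], [], [], [], []
    dosages = []
    ploidy = np.zeros(len(samples), dtype=np.int64)
    has_aa = False
    n_skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        row = np.empty(len(samples), dtype=np.int16)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                row[j] = MISSING
                # ploidy still inferred from the GT arity when present
                if gt is not None and ploidy[j] == 0:
                    ploidy[j] = len(gt)
                continue
            if any(a is None for a in gt):
                row[j] = MISSING
            else:
                row[j] = sum(1 for a in gt if a == 1)
            if ploidy[j] == 0:
                ploidy[j] = len(gt)
            elif ploidy[j] != len(gt):
                raise ValidationError(
                    f"sample {s!r} changes ploidy ({ploidy[j]} -> {len(gt)}) "
                    f"at {rec.chrom}:{rec.pos}"
                )
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alt.append(rec.alts[0])
        dosages.append(row)
        aa = rec.info.get("AA")
        if aa is not None:
            has_aa = True
            anc.append(str(aa) == rec.ref)
        else:
            anc.append(False)
    vf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    ploidy[ploidy == 0] = 2
    return GenotypeMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=(
            np.vstack(dosages)
            if dosages
            else np.empty((0, len(samples)), dtype=np.int16)
        ),
        ploidy=ploidy,
        samples=samples,
        ancestral_is_ref=np.array(anc, dtype=bool) if has_aa else None,
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            if gm.ancestral_is_ref is None:
                info = "."
            else:
                info = f"AA={gm.ref[i] if gm.ancestral_is_ref[i] else gm.alt[i]}"
            cells = []
            for j in range(gm.n_samples):
                d, p = gm.dosage[i, j], gm.ploidy[j]
                if d == MISSING:
                    cells.append("/".join(["."] * p))
                else:
                    cells.append("/".join(["0"] * (p - d) + ["1"] * d))
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\t.\t"
                f"{info}\tGT\t" + "\t".join(cells) + "\n"
            )


def read_intervals(path, format: str) -> IntervalSet:
    """Read BED (0-based half-open), GFF3 (1-based closed), or TSV intervals.

    GFF3 coordinates are shifted to the internal 0-based half-open convention
    (start-1, end).  TSV expects a header with chrom/start/end[/label] columns
    already 0-based half-open.
    """
    if format == "bed":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                rows.append(
                    {
                        "chrom": parts[0],
                        "start": int(parts[1]),
                        "end": int(parts[2]),
                        "label": parts[3] if len(parts) > 3 else "",
                        "source": "bed",
                    }
                )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "source"])
    elif format == "gff3":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                rows.append(
                    {
                        "chrom": parts[0],
                        "start": int(parts[3]) - 1,
                        "end": int(parts[4]),
                        "label": attrs.get("ID", parts[2]),
                        "source": parts[2],
                    }
                )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "source"])
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
        if "label" not in df.columns:
            df["label"] = ""
        df["source"] = "tsv"
    else:
        raise ValidationError(f"unknown interval format {format!r}")
    return IntervalSet(df)


def write_intervals(iv: IntervalSet, path, format: str = "bed") -> None:
    if format == "bed":
        iv.df[["chrom", "start", "end", "label"]].to_csv(
            path, sep="\t", header=False, index=False
        )
    elif format == "tsv":
        iv.df.to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unsupported output format {format!r}")


def site_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per site over all non-missing chromosomes."""
    alt, n = gm.allele_counts()
    with np.errstate(invalid="ignore"):
        f = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return np.minimum(f, 1.0 - f)


def filter_neutral_independent(
    gm: GenotypeMatrix, cds: IntervalSet, cfg: FilterConfig
) -> GenotypeMatrix:
    """CDS±margin exclusion, then distance thinning, then MAF filter.

    The three steps are applied in this fixed order.  Thinning is greedy from
    the smallest coordinate per chromosome: a site is kept only if it lies at
    least ``thin_bp`` beyond the last kept site.
    """
    if gm.n_sites == 0:
        return gm
    # 1. CDS + margin exclusion (site pos is 1-based; interval space 0-based)
    keep = np.ones(gm.n_sites, dtype=bool)
    trees = cds.trees(margin_bp=cfg.cds_margin_bp)
    for i in range(gm.n_sites):
        tree = trees.get(str(gm.chrom[i]))
        if tree is not None and tree.overlaps_point(gm.pos[i] - 1):
            keep[i] = False
    gm = gm.take_sites(keep)
    # 2. greedy thinning per chromosome
    keep = np.ones(gm.n_sites, dtype=bool)
    last_kept: dict[str, int] = {}
    for i in range(gm.n_sites):
        c = str(gm.chrom[i])
        if c in last_kept and gm.pos[i] - last_kept[c] < cfg.thin_bp:
            keep[i] = False
        else:
            last_kept[c] = int(gm.pos[i])
    gm = gm.take_sites(keep)
    # 3. MAF
    if gm.n_sites:
        maf = site_maf(gm)
        gm = gm.take_sites(~(maf < cfg.maf_min) & ~np.isnan(maf))
    return gm


def subsample_two_alleles(
    gm: GenotypeMatrix, n_replicates: int = 5, seed: int = 0
) -> list[GenotypeMatrix]:
    """Reduce tetraploid genotypes to pseudo-diploid dosages by subsampling.

    For each replicate, each tetraploid genotype with alt dosage ``d`` draws 2
    of its 4 chromosomes without replacement, giving a diploid dosage that is
    hypergeometric(4, d, 2).  Diploid samples pass through unchanged; missing
    stays missing.  Replicate ``r`` uses an independent RNG stream derived
    from ``(seed, r)``.
    """
    tet = np.flatnonzero(gm.ploidy == 4)
    if tet.size == 0:
        raise ValidationError("no tetraploid samples to subsample")
    out = []
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        dosage = gm.dosage.copy()
        for j in tet:
            col = dosage[:, j]
            called = col != MISSING
            d = col[called].astype(np.int64)
            drawn = rng.hypergeometric(d, 4 - d, 2)
            newcol = np.full(col.shape, MISSING, dtype=np.int16)
            newcol[called] = drawn.astype(np.int16)
            dosage[:, j] = newcol
        ploidy = gm.ploidy.copy()
        ploidy[tet] = 2
        out.append(replace(gm, dosage=dosage, ploidy=ploidy))
    return out


def replicate_consistency(stat_tables: list, statistic: str) -> np.ndarray:
    """Pairwise two-sided Wilcoxon rank-sum p-values across replicate tables.

    ``stat_tables`` are window-statistic DataFrames over identical windows;
    ``statistic`` names the column compared.  Returns a symmetric matrix with
    unit diagonal.
    """
    if len(stat_tables) < 2:
        raise ValidationError("need at least two replicate tables")
    frames = [t if isinstance(t, pd.DataFrame) else t.df for t in stat_tables]
    key_cols = ["chrom", "start", "end"]
    base = frames[0][key_cols].reset_index(drop=True)
    for f in frames[1:]:
        if not base.equals(f[key_cols].reset_index(drop=True)):
            raise ValidationError("replicate tables cover different windows")
    k = len(frames)
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = frames[i][statistic].dropna().to_numpy()
            y = frames[j][statistic].dropna().to_numpy()
            p = stats.ranksums(x, y).pvalue
            pmat[i, j] = pmat[j, i] = p
    return pmat
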