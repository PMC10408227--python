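#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes a two-population genotype VCF (12 diploids vs 12 tetraploids with a
shallow split), gene/SV/TE interval tracks with planted allele-loss
associations, and an RNA-seq count matrix with batch structure, all under
results/synthetic/.
"""

import argparse
from pathlib import Path

import pandas as pd

from polytetra.io_core import write_intervals, write_vcf
from polytetra.synthetic_data import (
    SynthConfig,
    synth_expression,
    synth_gene_annotations,
    synth_two_pop_genotypes,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geno_cfg = SynthConfig(
        seed=args.seed, n_diploid=12, n_tetraploid=12, n_loci=800,
        theta=2.0, split_time=0.2, chrom_length=2_000_000, n_chroms=2,
    )
    gm = synth_two_pop_genotypes(geno_cfg)
    write_vcf(gm, args.out / "genotypes.vcf")
    print(f"genotypes: {gm.n_sites} biallelic sites, "
          f"{(gm.ploidy == 2).sum()} diploids + {(gm.ploidy == 4).sum()} tetraploids")

    ann_cfg = SynthConfig(
        seed=args.seed + 1, n_genes=5000, or_sv=2.0, or_te=1.2, or_ppi=2.5,
    )
    genes, svs, tes, ppi, gene_iv = synth_gene_annotations(ann_cfg)
    genes.to_csv(args.out / "gene_annotations.tsv", sep="\t", index=False)
    write_intervals(svs, args.out / "svs.bed")
    write_intervals(tes, args.out / "tes.bed")
    write_intervals(gene_iv, args.out / "genes.bed")
    pd.Series(sorted(ppi), name="gene_id").to_csv(
        args.out / "ppi_genes.tsv", sep="\t", index=False
    )
    loss = (genes["n_alleles"] < 4).mean()
    print(f"annotations: {len(genes)} genes, {loss:.1%} with allele loss, "
          f"planted odds ratios sv=2.0 te=1.2 ppi=2.5")

    expr_cfg = SynthConfig(
        seed=args.seed + 2, n_expr_genes=2000, n_replicates=6,
        batch_shift=2.0, deg_fraction=0.1, fold_change=4.0,
    )
    em, truth = synth_expression(expr_cfg)
    em.counts.to_csv(args.out / "expression_counts.tsv", sep="\t")
    pd.DataFrame(
        {"length_bp": em.gene_length_bp}
    ).to_csv(args.out / "gene_lengths.tsv", sep="\t")
    pd.DataFrame(
        {"group": em.group, "batch": em.batch}
    ).to_csv(args.out / "sample_sheet.tsv", sep="\t")
    truth.to_csv(args.out / "expression_truth.tsv", sep="\t")
    print(f"expression: {em.counts.shape[0]} genes x {em.counts.shape[1]} samples, "
          f"{truth['is_deg'].sum()} planted DEGs (4-fold), 2x batch shift")


if __name__ == "__main__":
    main()
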