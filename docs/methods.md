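# Methods

## Containers and conventions

Genotypes live in a `GenotypeMatrix`: biallelic sites × samples, genotypes
stored as alternate-allele dosage with per-sample ploidy in {2, 4} and a
distinct missing code. Site positions are 1-based (VCF convention);
intervals are 0-based half-open internally, with BED read unchanged and
GFF3 converted at the boundary (start−1, end). Missing genotypes are
excluded from all allele-frequency denominators. Statistics that are
undefined on a window (no SNPs, monomorphic, too few chromosomes) are NaN,
never 0.

## SNP filtering and tetraploid subsampling

The neutral/independent SNP filter applies, in fixed order: (1) removal of
sites within any coding sequence extended by `cds_margin_bp` (default
20 kb) on both sides; (2) greedy distance thinning from the smallest
coordinate per chromosome, keeping a site only if ≥ `thin_bp` (20 kb) from
the last kept site; (3) removal of sites with minor allele frequency
< 0.01, computed over all non-missing chromosomes jointly. The order and
the greedy anchor are design choices; the filter is idempotent.

Two-allele subsampling converts each tetraploid genotype with dosage *d*
into a pseudo-diploid dosage drawn as hypergeometric(4, *d*, 2) — two of
the four chromosomes without replacement. Replicate *r* uses the
independent RNG stream seeded by (seed, *r*), so replicates differ only in
their draws and the whole set is reproducible. Consistency across
replicates is assessed by pairwise two-sided Wilcoxon rank-sum tests on a
chosen window statistic.

## Windowed statistics

Per-site π uses the unbiased pairwise estimator 2j(n−j)/(n(n−1)) summed
over sites and divided by window length in bp (sliding 50 kb windows, 20 kb
steps by default; trailing partial windows are emitted with their actual
length). Optional polyploid subsampling draws k individuals n_reps times
(default 4 individuals, 20 draws) and reports the mean. D_XY is computed
from allele frequencies, p_A(1−p_B) + p_B(1−p_A) summed per window and
divided by window length; regions ≥ 50 kb are tiled in non-overlapping
50 kb windows with the remainder emitted whole, shorter regions whole.
Monomorphic or uncalled stretches count as identical sequence.

Tajima's D uses the standard constants for the fixed chromosome count of
the chosen samples; sites with missing calls among those samples are
dropped per window so n stays fixed. Fay–Wu's H is the unnormalized
θ_π − θ_H form and requires outgroup polarization (`ancestral_is_ref`).
F_ST is the Weir–Cockerham two-population θ; windows report the ratio of
summed variance components (the "weighted" convention), negative estimates
uncensored. With all-diploid samples the full formulation with the
observed-heterozygosity term is used; when tetraploid genotypes enter
directly, chromosomes are treated as haploid units instead (no
within-individual component) — the scan path avoids this by using the
two-allele subsampled matrices. The molecular-clock conversion is
T = Ks/(2μ) with μ in substitutions per site per year.

## DCMS selection scan

Windows are tiled non-overlapping from coordinate 0 (25 kb default),
dropping windows with fewer than 10 SNPs. Each statistic column is
normalized in two steps — percentile rank (average ranks for ties), mapped
to r/(n+1), then the standard-normal quantile — and converted to a
one-sided p-value. Orientation is fixed so sweep-like signal maps to small
p: upper tail for ΔCLR (CLR_tet − CLR_dip), F_ST and ΔTajima's D
(D_dip − D_tet); lower tail for Fay–Wu's H. The composite is
DCMS = Σᵢ log10((1−pᵢ)/pᵢ)/wᵢ with wᵢ = Σⱼ|r_ij| over the Pearson
correlations of the p-value columns. A duplicated column doubles its own
weight while contributing its term twice, leaving the composite unchanged
(exactly so when the duplicated column is uncorrelated with the others;
with correlated companions the other columns' weights also shift, so the
invariance is exact only in that case and for k = 1 → 2). Window p-values
re-apply the same two-step normalization to the DCMS scores and take the
upper tail — a rank-based calibration whose null selection rate at
α = 0.05 is the nominal 5% by construction; a Gaussian fit to the DCMS
distribution is deliberately not used. CLR is consumed as a precomputed
column when available; scans run on whatever subset of the four statistics
is present.

## Inheritance-mode inference

The simulator is a structured Kingman coalescent written for this package
(no external binary). Time is scaled so a deme of relative size 1 is the
full pool of 4N chromosomes: within a deme of relative size s, each lineage
pair coalesces at rate 1/s. Tetrasomic loci place all 4n sampled lineages
in one size-1 deme. Disomic loci place 2 lineages per individual in each of
two size-½ demes (the subgenomes) with no coalescence between demes more
recently than td; at td both merge into the size-1 ancestral pool. Setting
td = 0 reproduces the tetrasomic model exactly. Mutations are Poisson with
mean θ/2 × branch length under infinite sites, giving E[ξ_i] = θ/i for the
unfolded spectrum (verified against both the closed form and an independent
msprime simulation of the same model in the test suite). Dosages are
unphased: a site's genotype is the derived count among an individual's four
lineages, so subgenome origin is unobservable, as in real genotype data.

Mixture models simulate a fraction p of loci disomic at a given td and the
rest tetrasomic. The observed/simulated comparison uses per-site
minor-allele frequencies, but **one randomly chosen segregating site per
locus**: sites within a locus share a genealogy and are strongly
correlated, and pooling them inflates the KS statistic far beyond its iid
null (measured empirically during development). The aggregate folded SFS
still pools all sites. The KS test implements D⁺ = sup(ECDF_obs − ECDF_sim)
with the one-sided asymptotic p = exp(−2mnD²/(m+n)); the default
orientation rejects models that carry *more* intermediate-frequency mass
than the data, so the largest non-rejected grid proportion is an upper
bound on the disomic genome fraction.

**Identifiability.** The disomic proportion and td are confounded in the
folded spectrum: a large fraction of weakly diverged subgenomes (td = 0.2)
is statistically indistinguishable from a small fraction of strongly
diverged ones (D ≈ 0.005–0.008 against a td = 0.6, p = 0.3 truth even at
2 × 10⁴ independent sites). A proportion bound profiled over the full td
grid therefore always escapes through the weak-td column; the
parameter-recovery experiment fixes the td grid at the generating value and
recovers the proportion within one grid step (±0.1). The reference design —
12 tetraploid individuals (48 chromosomes), θ = 2 per locus, 24 000 loci
per model, α = 0.05 — was set by a design-stage power analysis on pilot
seeds before the acceptance runs and is not adjusted afterwards.
`fit_inheritance` shares one tetrasomic locus pool across all mixture
models and one disomic pool per td (a proportion-p model takes the first
p·n disomic plus (1−p)·n tetrasomic loci), which preserves each model's
distribution while cutting simulation cost about five-fold.

## Genome structure and allele loss

Allele summaries class genes by retained allele count {1, 2, 3, 4, >4}
with percentages to two decimals and mean = total alleles / total genes.
SV identity across the four monoploid genomes requires ≥ 50% overlap of
the shorter interval on the diploid reference (the overlap denominator is
unspecified upstream; the shorter interval is this package's choice), the
same SV type, and allelic source chromosomes; groups are connected
components since "two or more" events may chain, and each group's presence
class is its member subset of {A, B, C, D}. Gene–SV classification is
exhaustive and exclusive: any-bp overlap → within; gap ≤ 2000 bp → near;
else far (a gap of exactly the margin counts as near under the half-open
convention). TE overlap is any-bp on the full gene span — gene granularity
matches the upstream annotations, not exon structure. Reciprocal best hits
demand mutual unique best scores, with ties broken by lexicographically
smallest subject id and logged. Fisher's exact tests are two-sided by
minimum-likelihood summation (scipy's convention, matched exactly by an
exhaustive-enumeration oracle for margins ≤ 30); sample odds ratios are
ad/bc with bc = 0 reported as infinity. The association report emits both
the merged "within or near SV" contrast and within-only, since the merged
category is what the published proportions describe.

## Expression

TPM divides counts by gene length in kb, rescales each sample to 10⁶, and
by default returns log2(TPM + 1) — the +1 pseudocount is this package's
zero-handling choice. Allele-dosage analysis averages log2 TPM over a
gene's alleles, optionally keeping only genes whose every allele clears a
TPM threshold, and compares adjacent allele-count groups with two-sided
rank-sum tests. Percentile-rank profiles sort each sample from high to low
expression and assign ceil(100·position/n), ties sharing their average
position, so bucket 1 holds the most expressed genes; the profiles are
invariant to any strictly increasing per-sample transform, which is the
precise sense in which the DEG procedure is batch-robust (no explicit batch
covariate is fitted). Per-gene group comparisons use the exact Wilcoxon
null for groups ≤ 10 — scipy's closed form when tie-free, full permutation
enumeration otherwise — and the continuity-corrected normal approximation
for larger groups; p-values are BH-adjusted and genes called at q < 0.05.
Bucketed ranks feed the test by default; continuous ranks remain available
by ranking the TPM matrix directly.

## Synthetic data

The generators supply every pipeline input with planted truth; they are
study conditions, not dials. Two-population genotypes reuse the structured
coalescent: equal-size demes merging at `split_time`, diploids sampled from
deme 1 (2 lineages each) and tetraploids from deme 2 (4 each), sites
independent across loci with uniform positions — no within-chromosome
linkage, recombination, or sequencing error, so tests exercise statistical
behavior, not LD-aware methods. The reference allele is ancestral
everywhere, and true per-deme derived frequencies are recorded. Sweep
windows thin intermediate-frequency sites (pooled MAF ≥ 0.1) with
probability = intensity and push the same fraction of remaining polymorphic
sites to near-fixation of the derived allele; restricted to one
population's samples, removal becomes dosage-zeroing so site counts (and
window SNP thresholds) are preserved and the signal is population-specific.
Annotation tables draw SV/TE/PPI flags as independent Bernoullis and then
loss status with odds = baseline × or_sv^[sv] × or_te^[te] × or_ppi^[no
ppi], so each configured value is the conditional odds ratio of its flag;
intervals are laid out so interval classification recovers the flags
exactly. Expression counts are negative binomial (gamma–Poisson, dispersion
0.1) with lognormal gene means, a multiplicative batch library-size shift,
an optional group fold-change on a stated fraction of genes, and an
optional dosage effect scaling means by dosage_effect^(alleles − 4). All
generators are deterministic given their seed.

## Reference problem sizes

The calibration experiments (in `polytetra.experiments`, shared by the
acceptance tests and `scripts/acceptance.py`) use: 10⁴ loci at θ = 1 for
the tetrasomic SFS check (agreement within 3 Monte-Carlo SE); 10 recovery
trials at the design above (success = bound within one grid step of the
planted 0.3, ≥ 8/10 required); 1000 null windows for the DCMS selection
rate (0.05 ± 0.02); a 160-window scan with six planted sweeps for the
ranking check (truth windows' mean percentile in the top decile); 200
random tables/pairs and 50 p-vectors for the Fisher/KS/BH oracle
agreements; 2000 genes × 6 + 6 replicates with a 2× batch shift for the
DEG type-I check (raw p < 0.05 rate 0.05 ± 0.02). Together they run in
about five minutes on one CPU, dominated by the recovery trials.

## Known limitations

- No linkage or recombination within simulated chromosomes; window
  statistics on synthetic data are over independent sites.
- The disomic-fraction bound is conditional on td (see Identifiability);
  real-data applications should report the full (td × proportion) grid.
- W&C F_ST for unreduced tetraploid genotypes uses the haploid-unit view;
  dosage-aware polyploid F_ST estimators are out of scope.
- The DCMS null calibration is rank-based and therefore exact under
  exchangeability but insensitive to the absolute scale of the composite.
- KS p-values are asymptotic; for very small samples an exact permutation
  p would differ.
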