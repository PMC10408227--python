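import numpy as np
import pytest
from scipy import stats as sps

from polytetra.inheritance_sfs import (
    CoalescentConfig,
    ValidationError,
    fit_inheritance,
    ks_two_sample,
    observed_sfs,
    simulate_locus,
    simulate_sfs,
)
from tests.conftest import make_gm


def unfolded_counts(mode, td, theta, n_ind, n_loci, seed):
    rng = np.random.default_rng(seed)
    n_chrom = 4 * n_ind
    counts = np.zeros(n_chrom - 1)
    for _ in range(n_loci):
        dos = simulate_locus(mode, td, theta, n_ind, rng)
        if dos.shape[0]:
            counts += np.bincount(dos.sum(axis=1), minlength=n_chrom)[1:n_chrom]
    return counts


class TestSimulateLocus:
    def test_tetrasomic_neutral_sfs_shape(self):
        # E[xi_i] = theta / i per locus for the single-pool coalescent
        n_loci, theta = 6000, 1.0
        counts = unfolded_counts("tetrasomic", 0.0, theta, 2, n_loci, 10)
        expected = n_loci * theta / np.arange(1, 8)
        # Poisson-ish MC noise: allow 4 sigma with sigma ~ sqrt(3*expected)
        assert np.all(np.abs(counts - expected) < 4 * np.sqrt(3 * expected))

    def test_matches_msprime_oracle(self):
        # independent implementation of the same single-pool model
        msprime = pytest.importorskip("msprime")
        n_loci, theta, n_ind = 4000, 1.0, 2
        counts = unfolded_counts("tetrasomic", 0.0, theta, n_ind, n_loci, 11)
        n_chrom = 4 * n_ind
        ms_counts = np.zeros(n_chrom - 1)
        reps = msprime.sim_ancestry(
            samples=n_chrom, ploidy=1, population_size=1.0,
            num_replicates=n_loci, random_seed=12,
        )
        rng = np.random.default_rng(13)
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=theta / 2, random_seed=int(rng.integers(1, 2**31)),
                discrete_genome=False,
            )
            for var in mts.variants():
                k = int(np.sum(np.array(var.genotypes) > 0))
                if 0 < k < n_chrom:
                    ms_counts[k - 1] += 1
        # the two spectra estimate the same expectation
        for obs, orc in zip(counts, ms_counts):
            se = np.sqrt(3 * max(obs, orc, 1.0))
            assert abs(obs - orc) < 5 * se

    def test_disomic_large_td_mass_at_half(self):
        rng = np.random.default_rng(14)
        half = tot = 0
        for _ in range(400):
            dos = simulate_locus("disomic", 50.0, 1.0, 4, rng)
            if dos.shape[0]:
                der = dos.sum(axis=1)
                tot += der.size
                half += int(np.sum(der == 8))  # 8 of 16 chromosomes
        assert half / tot > 0.5

    def test_disomic_td_zero_equals_tetrasomic_in_distribution(self):
        a = unfolded_counts("disomic", 0.0, 1.0, 3, 2000, 15)
        b = unfolded_counts("tetrasomic", 0.0, 1.0, 3, 2000, 16)
        # same expected spectrum; chi-square-style agreement
        for x, y in zip(a, b):
            assert abs(x - y) < 5 * np.sqrt(3 * max(x, y, 1.0))

    def test_zero_theta_no_sites(self):
        rng = np.random.default_rng(17)
        assert simulate_locus("tetrasomic", 0.0, 0.0, 2, rng).shape[0] == 0


class TestSimulateSfs:
    def test_deterministic_given_seed(self):
        cfg = CoalescentConfig(n_individuals=3, theta=1.0, n_loci=200, seed=18)
        s1, f1 = simulate_sfs(cfg)
        s2, f2 = simulate_sfs(cfg)
        np.testing.assert_array_equal(s1.counts, s2.counts)
        np.testing.assert_array_equal(f1, f2)

    def test_proportion_zero_is_pure_tetrasomic(self):
        base = dict(n_individuals=3, theta=1.0, n_loci=200, seed=19)
        s1, _ = simulate_sfs(CoalescentConfig(**base, disomic_proportion=0.0))
        s2, _ = simulate_sfs(CoalescentConfig(**base, disomic_proportion=0.0, td=5.0))
        np.testing.assert_array_equal(s1.counts, s2.counts)

    def test_half_class_mass_monotone_in_proportion(self):
        masses = []
        for prop in (0.0, 0.5, 1.0):
            cfg = CoalescentConfig(
                n_individuals=4, theta=1.0, n_loci=600, td=5.0,
                disomic_proportion=prop, seed=20,
            )
            sfs, _ = simulate_sfs(cfg)
            masses.append(sfs.counts[-1] / sfs.counts.sum())
        assert masses[0] < masses[1] < masses[2]


class TestObservedSfs:
    def test_monomorphic_sites_empty_spectrum(self):
        gm = make_gm([[0, 0], [4, 4]], ploidy=[4, 4])
        sfs, freqs = observed_sfs(gm, gm.samples)
        assert sfs.counts.sum() == 0 and freqs.size == 0

    def test_single_site_class(self):
        gm = make_gm([[1, 0]], ploidy=[4, 4])
        sfs, freqs = observed_sfs(gm, gm.samples)
        assert sfs.counts[0] == 1 and sfs.n_chromosomes == 8
        assert freqs[0] == pytest.approx(1 / 8)

    def test_folding(self):
        gm = make_gm([[4, 2]], ploidy=[4, 4])  # alt count 6 of 8 -> class 2
        sfs, _ = observed_sfs(gm, gm.samples)
        assert sfs.counts[1] == 1

    def test_missing_sites_skipped_and_all_missing_errors(self):
        from polytetra.io_core import MISSING

        gm = make_gm([[MISSING, 1], [1, 1]], ploidy=[4, 4])
        sfs, _ = observed_sfs(gm, gm.samples)
        assert sfs.counts.sum() == 1
        gm2 = make_gm([[MISSING, 1]], ploidy=[4, 4])
        with pytest.raises(ValidationError):
            observed_sfs(gm2, gm2.samples)

    def test_diploid_samples_rejected(self):
        gm = make_gm([[1, 1]], ploidy=[2, 4])
        with pytest.raises(ValidationError):
            observed_sfs(gm, gm.samples)


class TestKsTwoSample:
    def test_identical_samples(self):
        x = np.array([0.1, 0.2, 0.2, 0.7])
        r = ks_two_sample(x, x.copy(), "two-sided")
        assert r.d_stat == 0.0 and r.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        r = ks_two_sample([0.1, 0.2], [0.8, 0.9], "two-sided")
        assert r.d_stat == 1.0

    def test_one_sided_directionality(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(size=300)
        y = x + 0.3  # y stochastically larger
        assert ks_two_sample(x, y, "greater").p_value < 0.01
        assert ks_two_sample(x, y, "less").p_value == pytest.approx(1.0)

    def test_two_sided_matches_scipy(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=80)
        y = rng.normal(0.4, 1.0, size=60)
        mine = ks_two_sample(x, y, "two-sided")
        ref = sps.ks_2samp(x, y, method="asymp")
        assert mine.d_stat == pytest.approx(ref.statistic, abs=1e-12)
        # scipy adds a finite-sample correction to the Kolmogorov argument;
        # the plain asymptotic p agrees to ~15% at these sizes
        assert mine.p_value == pytest.approx(ref.pvalue, rel=0.2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [0.1], "two-sided")


class TestFitInheritance:
    def test_alpha_one_rejects_everything(self):
        cfg = CoalescentConfig(
            n_individuals=3, theta=1.0, n_loci=150, seed=23,
            td_grid=(0.5,), proportion_grid=(0.2, 0.8),
        )
        _, obs = simulate_sfs(
            CoalescentConfig(n_individuals=3, theta=1.0, n_loci=150, seed=24)
        )
        fit = fit_inheritance(obs, cfg, alpha=1.0)
        assert fit.max_nonrejected_proportion == 0.0

    def test_tetrasomic_self_consistency(self):
        # observed drawn from pure tetrasomy: the tetrasomic model is not
        # rejected and the best model is statistically indistinguishable
        # from it
        truth = CoalescentConfig(n_individuals=6, theta=1.0, n_loci=2500, seed=25)
        _, obs = simulate_sfs(truth)
        fit = fit_inheritance(
            obs,
            CoalescentConfig(
                n_individuals=6, theta=1.0, n_loci=2500, seed=26,
                td_grid=(0.5, 1.0), proportion_grid=(0.3, 0.6, 0.9),
            ),
        )
        tet = fit.results[(0.0, 0.0)]
        assert tet.p_value > 0.05
        best = fit.results[fit.best_model]
        assert best.d_stat <= tet.d_stat
        assert tet.d_stat - best.d_stat < 0.02

    def test_chromosome_count_mismatch_rejected(self):
        cfg = CoalescentConfig(n_individuals=6, theta=1.0, n_loci=50, seed=27)
        with pytest.raises(ValidationError):
            fit_inheritance([0.1, 0.2], cfg, n_chromosomes=48)
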