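import numpy as np
import pandas as pd
import pytest

from polytetra import popgen_stats as ps
from polytetra.io_core import MISSING, ValidationError
from polytetra.synthetic_data import SynthConfig, synth_two_pop_genotypes
from tests.conftest import make_gm


def brute_pi_per_site(alleles):
    """O(n^2) mean pairwise difference over explicit chromosome alleles."""
    n = len(alleles)
    diff = sum(
        alleles[i] != alleles[j] for i in range(n) for j in range(i + 1, n)
    )
    return diff / (n * (n - 1) / 2)


class TestPi:
    def test_monomorphic_window_zero(self):
        gm = make_gm([[0, 0]] * 5, ploidy=[2, 2])
        t = ps.pi_windows(gm, gm.samples, window_bp=1000, step_bp=1000)
        assert (t["pi"] == 0).all()

    def test_single_snp_hand_value(self):
        # 1 SNP, 4 chromosomes, alt count 2, 10 kb window:
        # pi = (2*2*2/12) / 10000 = 6.67e-5
        gm = make_gm([[1, 1]], ploidy=[2, 2], pos=[5000])
        t = ps.pi_windows(
            gm, gm.samples, window_bp=10_000, step_bp=10_000,
            chrom_lengths={"chr1": 10_000},
        )
        assert t.loc[0, "pi"] == pytest.approx((2 * 2 * 2 / 12) / 10_000)

    def test_subsample_all_equals_none(self):
        rng = np.random.default_rng(0)
        gm = make_gm(
            rng.integers(0, 3, size=(30, 6)).astype(np.int16),
            ploidy=[2] * 6,
            pos=np.sort(rng.choice(50_000, 30, replace=False)) + 1,
        )
        a = ps.pi_windows(gm, gm.samples, window_bp=10_000, step_bp=10_000)
        b = ps.pi_windows(
            gm, gm.samples, window_bp=10_000, step_bp=10_000,
            subsample_k=6, n_reps=5, seed=1,
        )
        np.testing.assert_allclose(a["pi"], b["pi"])

    def test_matches_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(20, 5)).astype(np.int16)
        gm = make_gm(dosage, ploidy=[2] * 5, pos=np.arange(1, 21))
        t = ps.pi_windows(
            gm, gm.samples, window_bp=100, step_bp=100,
            chrom_lengths={"chr1": 100},
        )
        expected = 0.0
        for row in dosage:
            alleles = []
            for d in row:
                alleles += [1] * d + [0] * (2 - d)
            expected += brute_pi_per_site(alleles)
        assert t.loc[0, "pi"] == pytest.approx(expected / 100)

    def test_ref_alt_relabel_invariance(self):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, size=(25, 4)).astype(np.int16)
        gm = make_gm(dosage, ploidy=[2] * 4, pos=np.arange(1, 26))
        flipped = make_gm(2 - dosage, ploidy=[2] * 4, pos=np.arange(1, 26))
        a = ps.pi_windows(gm, gm.samples, window_bp=100, step_bp=100)
        b = ps.pi_windows(flipped, gm.samples, window_bp=100, step_bp=100)
        np.testing.assert_allclose(a["pi"], b["pi"])


class TestDxy:
    def test_identical_fixed_sequences_zero(self):
        gm = make_gm([[0, 0], [2, 2]], ploidy=[2, 2], pos=[100, 200])
        t = ps.dxy_windows(gm, ["s0"], ["s1"], ("chr1", 0, 10_000))
        assert t["dxy"].iloc[0] == 0.0

    def test_fixed_difference_per_length(self):
        gm = make_gm([[0, 2]], ploidy=[2, 2], pos=[100])
        t = ps.dxy_windows(gm, ["s0"], ["s1"], ("chr1", 0, 10_000))
        assert t["dxy"].iloc[0] == pytest.approx(1e-4)

    def test_tiling_rule_long_region(self):
        gm = make_gm([[0, 2]], ploidy=[2, 2], pos=[100])
        t = ps.dxy_windows(gm, ["s0"], ["s1"], ("chr1", 0, 120_000))
        assert list(zip(t["start"], t["end"])) == [
            (0, 50_000),
            (50_000, 100_000),
            (100_000, 120_000),
        ]

    def test_short_region_emitted_whole(self):
        gm = make_gm([[0, 2]], ploidy=[2, 2], pos=[100])
        t = ps.dxy_windows(gm, ["s0"], ["s1"], ("chr1", 0, 30_000))
        assert len(t) == 1 and t["end"].iloc[0] == 30_000


class TestTajimasD:
    def test_no_segregating_sites_missing(self):
        assert np.isnan(ps.tajimas_d(np.array([0, 4]), 4))

    def test_hand_value_singletons(self):
        # n=4, S=3 singletons: pi=1.5, thetaW=3/a1, hand-evaluated D
        d = ps.tajimas_d(np.array([1, 1, 1]), 4)
        assert d == pytest.approx(-0.754, abs=0.01)

    def test_balanced_sfs_gives_zero(self):
        # xi ~ theta/i: xi_1=6, xi_2=3, xi_3=2 makes pi == thetaW exactly
        alt = np.array([1] * 6 + [2] * 3 + [3] * 2)
        assert ps.tajimas_d(alt, 4) == pytest.approx(0.0, abs=1e-12)

    def test_neutral_panmictic_mean_near_zero(self):
        cfg = SynthConfig(
            seed=11, n_diploid=10, n_tetraploid=1, n_loci=1800,
            theta=2.0, split_time=0.0, chrom_length=2_000_000, n_chroms=3,
        )
        gm = synth_two_pop_genotypes(cfg)
        dip = [s for s in gm.samples if s.startswith("dip")]
        idx = gm.sample_indices(dip)
        alt = gm.dosage[:, idx].sum(axis=1)
        pos0 = gm.pos - 1
        vals = []
        for chrom in ("chr1", "chr2", "chr3"):
            for start in range(0, 2_000_000, 25_000):
                m = (gm.chrom == chrom) & (pos0 >= start) & (pos0 < start + 25_000)
                if m.sum() >= 4:
                    vals.append(ps.tajimas_d(alt[m], 20))
        vals = np.array(vals)
        assert len(vals) >= 200
        assert abs(np.nanmean(vals)) < 0.3


class TestFayWuH:
    def test_singletons_positive(self):
        assert ps.fay_wu_h(np.array([1, 1, 1]), 8) > 0

    def test_high_frequency_derived_negative(self):
        assert ps.fay_wu_h(np.array([7, 7, 7]), 8) < -1

    def test_single_site_direct_summation(self):
        # n=4, derived count 2: theta_pi = 2*2*2/12, theta_H = 2*4/12
        expected = (2 * 2 * 2 / 12) - (2 * 2 * 2 / 12)
        assert ps.fay_wu_h(np.array([2]), 4) == pytest.approx(expected)
        # and an asymmetric case, i=3 of n=4
        expected = (2 * 3 * 1 / 12) - (2 * 9 / 12)
        assert ps.fay_wu_h(np.array([3]), 4) == pytest.approx(expected)


class TestWcFst:
    def test_fixed_difference_is_one(self):
        gm = make_gm(
            np.hstack([np.zeros((10, 4)), np.full((10, 4), 2)]).astype(np.int16),
            ploidy=[2] * 8,
            pos=np.arange(1, 11),
        )
        assert ps.wc_fst(gm, gm.samples[:4], gm.samples[4:]) == pytest.approx(1.0)

    def test_random_split_of_one_population_near_zero(self):
        # permutation oracle: labels carry no information, theta ~ 0
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0.05, 0.95, size=400)
        dosage = rng.binomial(2, freqs[:, None], size=(400, 16)).astype(np.int16)
        gm = make_gm(dosage, ploidy=[2] * 16, pos=np.arange(1, 401))
        perm = rng.permutation(16)
        popA = [gm.samples[i] for i in perm[:8]]
        popB = [gm.samples[i] for i in perm[8:]]
        assert abs(ps.wc_fst(gm, popA, popB)) < 0.05

    def test_monomorphic_window_missing(self):
        gm = make_gm([[0, 0]], ploidy=[2, 2])
        assert np.isnan(ps.wc_fst(gm, ["s0"], ["s1"]))


class TestDeltaStats:
    @staticmethod
    def table(**cols):
        n = len(next(iter(cols.values())))
        base = {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
        }
        return pd.DataFrame(base | cols)

    def test_equal_inputs_zero(self):
        t = self.table(tajima_d=[1.0, -0.5], clr=[2.0, 3.0])
        out = ps.delta_stats(t, t.copy())
        assert (out["delta_d"] == 0).all() and (out["delta_clr"] == 0).all()

    def test_arithmetic(self):
        dip = self.table(tajima_d=[1.0], clr=[1.0])
        tet = self.table(tajima_d=[-0.5], clr=[4.0])
        out = ps.delta_stats(dip, tet)
        assert out.loc[0, "delta_d"] == pytest.approx(1.5)
        assert out.loc[0, "delta_clr"] == pytest.approx(3.0)

    def test_missing_clr_column(self):
        dip = self.table(tajima_d=[1.0])
        tet = self.table(tajima_d=[0.0])
        out = ps.delta_stats(dip, tet)
        assert "delta_clr" not in out.columns and "delta_d" in out.columns

    def test_window_mismatch_rejected(self):
        dip = self.table(tajima_d=[1.0])
        tet = self.table(tajima_d=[1.0, 2.0])
        with pytest.raises(Exception):
            ps.delta_stats(dip, tet)


class TestKsToTime:
    def test_wgd_peak_age(self):
        # Ks peak 0.005 at 2.06e-9 per site per year: ~1.2 Myr
        t = ps.ks_to_time(0.005, 2.06e-9)
        assert t == pytest.approx(1.2136e6, rel=1e-3)
        assert round(t / 1e6, 1) == 1.2

    def test_zero_ks(self):
        assert ps.ks_to_time(0.0, 1e-9) == 0.0

    def test_direct_arithmetic(self):
        assert ps.ks_to_time(0.325, 2.06e-9) == pytest.approx(7.888e7, rel=1e-3)

    def test_invalid_mu(self):
        with pytest.raises(ValidationError):
            ps.ks_to_time(0.1, 0.0)
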