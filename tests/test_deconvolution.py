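"""Intensity-histogram deconvolution: bases, chi-squared, mixture recovery."""

import numpy as np
import pytest

from smolsensor import deconvolution as dec
from smolsensor import simulate as sim


@pytest.fixture(scope="module")
def rho1():
    x = sim.gen_monomer_intensities(100000, seed=1)
    return dec.build_histogram(x, n_bins=50).normalized()


class TestBuildHistogram:
    def test_single_bin_tally(self):
        h = dec.build_histogram([5.0, 5.0, 5.0], n_bins=1)
        assert h.counts.tolist() == [3.0]

    def test_counts_conserved(self):
        x = sim.gen_monomer_intensities(10000, seed=2)
        h = dec.build_histogram(x, n_bins=50)
        assert h.counts.sum() == 10000
        assert h.bin_edges[0] == 0.0 and h.bin_edges[-1] == x.max()

    def test_percentile_policy_clips_into_top_bin(self):
        x = sim.gen_monomer_intensities(10000, seed=3)
        h = dec.build_histogram(x, n_bins=50, range_policy=0.999)
        assert h.counts.sum() == 10000

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dec.build_histogram([])
        with pytest.raises(ValueError):
            dec.build_histogram([1.0, -2.0])

    def test_matches_empirical_cdf_at_edges(self):
        x = sim.gen_monomer_intensities(5000, seed=4)
        h = dec.build_histogram(x, n_bins=40)
        cdf_hist = np.concatenate([[0.0], np.cumsum(h.pmf)])
        cdf_emp = np.searchsorted(np.sort(x), h.bin_edges, side="right") / x.size
        assert np.max(np.abs(cdf_hist - cdf_emp)) <= 1.0 / x.size + 1e-12


class TestDeriveBasis:
    def test_identity_for_M1(self, rho1):
        b = dec.derive_basis(rho1, M=1, mode="scale")
        assert b.M == 1
        np.testing.assert_allclose(b.rho[0], rho1.pmf, atol=1e-12)

    def test_invalid_order_rejected(self, rho1):
        with pytest.raises(ValueError):
            dec.derive_basis(rho1, M=0)

    @pytest.mark.parametrize("mode", ["scale", "convolve"])
    def test_rows_normalized_on_common_grid(self, rho1, mode):
        b = dec.derive_basis(rho1, M=3, mode=mode)
        np.testing.assert_allclose(b.rho.sum(axis=1), 1.0, atol=1e-9)
        assert b.bin_edges[-1] >= 3 * rho1.bin_edges[-1] - 1e-9

    def test_scale_mode_mean_doubles(self, rho1):
        b = dec.derive_basis(rho1, M=2, mode="scale")
        half_bin = np.diff(b.bin_edges)[0] / 2
        assert abs(b.component(2).mean() - 2 * rho1.mean()) <= half_bin

    def test_convolve_mode_variance_doubles(self, rho1):
        b = dec.derive_basis(rho1, M=2, mode="convolve")
        # discretization adds w^2/12 per convolution order
        w = np.diff(b.bin_edges)[0]
        assert b.component(2).var() == pytest.approx(2 * rho1.var(), abs=w**2, rel=0.02)

    def test_modes_agree_at_M1_diverge_at_M2(self, rho1):
        bs = dec.derive_basis(rho1, M=2, mode="scale")
        bc = dec.derive_basis(rho1, M=2, mode="convolve")
        np.testing.assert_allclose(bs.rho[0], bc.rho[0], atol=1e-9)
        # axis scaling quadruples the variance; convolution only doubles it
        assert bs.component(2).var() > 1.5 * bc.component(2).var()


class TestSimulateModelHistogram:
    def test_zero_draws(self, rho1):
        b = dec.derive_basis(rho1, M=3)
        h = dec.simulate_model_histogram(b, [1.0, 0.0, 0.0], 0, seed=0)
        assert h.counts.sum() == 0 and h.n_total == 0

    def test_determinism(self, rho1):
        b = dec.derive_basis(rho1, M=2)
        h1 = dec.simulate_model_histogram(b, [0.7, 0.3], 1000, seed=9)
        h2 = dec.simulate_model_histogram(b, [0.7, 0.3], 1000, seed=9)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_chi2_near_one_under_null(self, rho1):
        b = dec.derive_basis(rho1, M=1)
        vals = [
            dec.reduced_chi2(
                dec.simulate_model_histogram(b, [1.0], 20000, seed=s).counts,
                20000 * b.rho[0],
                n_free_params=0,
            )
            for s in range(10)
        ]
        assert 0.7 <= float(np.median(vals)) <= 1.3


class TestReducedChi2:
    def test_identical_histograms_give_zero(self):
        e = np.array([10.0, 20.0, 30.0])
        assert dec.reduced_chi2(e, e, n_free_params=0) == 0.0

    def test_hand_computed_three_bin_case(self):
        obs = np.array([10.0, 20.0, 30.0])
        exp = np.array([12.0, 18.0, 30.0])
        # ((10-12)^2/12 + (20-18)^2/18 + 0) / (3 - 0 - 1)
        expected = (4 / 12 + 4 / 18) / 2
        assert dec.reduced_chi2(obs, exp, n_free_params=0) == pytest.approx(expected)
        # doubling expected counts changes the statistic per the formula
        exp2 = 2 * exp
        expected2 = ((10 - 24) ** 2 / 24 + (20 - 36) ** 2 / 36 + (30 - 60) ** 2 / 60) / 2
        assert dec.reduced_chi2(obs, exp2, n_free_params=0) == pytest.approx(expected2)

    def test_poisson_resample_near_one(self):
        rng = np.random.default_rng(5)
        exp = np.full(45, 300.0)
        obs = rng.poisson(exp).astype(float)
        assert 0.7 <= dec.reduced_chi2(obs, exp, n_free_params=0) <= 1.3

    def test_low_expected_bins_are_pooled(self):
        obs = np.array([3.0, 2.0, 50.0])
        exp = np.array([2.0, 4.0, 49.0])
        # first two bins pool to one (expected 6 >= 5): 2 bins, dof = 1
        val = dec.reduced_chi2(obs, exp, n_free_params=0)
        assert val == pytest.approx(((5 - 6) ** 2 / 6 + (50 - 49) ** 2 / 49) / 1)

    def test_insufficient_dof_raises(self):
        with pytest.raises(ValueError):
            dec.reduced_chi2(np.array([10.0]), np.array([10.0]), n_free_params=2)


class TestMixtureFit:
    def test_pure_monomer_self_consistency(self, rho1):
        basis = dec.derive_basis(rho1, M=3)
        x = sim.gen_monomer_intensities(5000, seed=21)
        expt = dec.build_histogram(x, n_bins=50)
        res = dec.fit_mixture(expt, basis, seed=0)
        assert res.monomer_fraction >= 0.95
        assert 0.5 <= res.chi2_red <= 1.5

    def test_simplex_constraint_exact(self, rho1):
        basis = dec.derive_basis(rho1, M=3)
        x = sim.gen_multimer_mixture(2000, [0.6, 0.3, 0.1], seed=8)["intensity"]
        res = dec.fit_mixture(dec.build_histogram(x), basis, seed=1)
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.fractions >= 0)
        assert res.dof > 0

    def test_underpowered_or_empty_rejected(self, rho1):
        basis = dec.derive_basis(rho1, M=2)
        small = dec.build_histogram(sim.gen_monomer_intensities(50, seed=1))
        with pytest.raises(ValueError):
            dec.MultimerMixtureModel(small, basis)

    def test_rebinning_invariance(self):
        """Halving the bin width moves the recovered fraction by < 0.02."""
        mix = sim.gen_multimer_mixture(5000, [0.981, 0.019, 0.0], seed=13)["intensity"]
        calib = sim.gen_monomer_intensities(50000, seed=14)
        res50 = dec.MultimerMixtureModel.from_samples(mix, calib, M=3, n_bins=50).fit(seed=0)
        res100 = dec.MultimerMixtureModel.from_samples(mix, calib, M=3, n_bins=100).fit(seed=0)
        assert abs(res50.monomer_fraction - res100.monomer_fraction) < 0.02

    def test_recovery_across_monomer_fraction_grid(self):
        """Mean absolute error of the monomer fraction < 0.03 over the grid."""
        errs = []
        for f1 in (1.0, 0.981, 0.9, 0.7, 0.5):
            fr = [f1, 0.7 * (1 - f1), 0.3 * (1 - f1)]
            for s in range(4):
                mix = sim.gen_multimer_mixture(5000, fr, seed=1000 + 17 * s + int(f1 * 100))
                calib = sim.gen_monomer_intensities(50000, seed=2000 + s)
                res = dec.MultimerMixtureModel.from_samples(
                    mix["intensity"].to_numpy(), calib, M=3).fit(seed=s)
                errs.append(abs(res.monomer_fraction - f1))
        assert np.mean(errs) < 0.03

    def test_summary_mentions_fractions(self, rho1):
        basis = dec.derive_basis(rho1, M=2)
        x = sim.gen_monomer_intensities(1000, seed=3)
        res = dec.fit_mixture(dec.build_histogram(x), basis, seed=0)
        s = res.summary()
        assert "reduced chi2" in s and "1-mer fraction" in s
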