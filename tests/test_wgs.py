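"""WGS z-score caller simulation: calibration, reference, sensitivity."""

import numpy as np
import pytest
from scipy import stats

import nipsim as ns
from nipsim.cohort import BinnedReadCounts
from nipsim.wgs import _sample_statistic


def _nb_counts(rng, lam, phi, n):
    rate = rng.gamma(lam / (phi - 1), phi - 1, size=n)
    return rng.poisson(rate)


class TestDepthCalibration:
    def test_poisson_counts_give_scale_one(self, genome, rng):
        counts = [BinnedReadCounts("S0", "chr13", rng.poisson(170, 50_000))]
        cal = ns.calibrate_effective_depth(counts, genome)
        assert cal.scale == pytest.approx(1.0, abs=0.03)
        assert cal.effective_reads == pytest.approx(cal.raw_reads, rel=0.03)

    def test_overdispersed_counts_recover_phi(self, genome, rng):
        counts = [BinnedReadCounts("S0", "chr13", _nb_counts(rng, 170, 2.5, 50_000))]
        cal = ns.calibrate_effective_depth(counts, genome)
        assert cal.scale == pytest.approx(2.5, abs=0.1)

    def test_effective_reads_definition(self, genome):
        """Counts generated at raw 1.8e7 reads with dispersion 1.8 calibrate
        to effective ~1.0e7 reads."""
        counts = ns.generate_bin_counts(genome, 1.8e7, 0.0, "euploid", dispersion=1.8, seed=6)
        cal = ns.calibrate_effective_depth(counts, genome, raw_reads=1.8e7)
        assert cal.effective_reads == pytest.approx(1.0e7, rel=0.07)

    def test_rescaled_counts_fit_poisson(self, genome, rng):
        counts = [BinnedReadCounts("S0", "chr18", _nb_counts(rng, 170, 1.8, 50_000))]
        cal = ns.calibrate_effective_depth(counts, genome)
        assert cal.gof < 0.1  # total variation distance to the fitted Poisson

    def test_too_few_bins_rejected(self, genome, rng):
        counts = [BinnedReadCounts("S0", "chr21", rng.poisson(170, 500))]
        with pytest.raises(ValueError, match="1000"):
            ns.calibrate_effective_depth(counts, genome)


class TestStatisticSampler:
    @pytest.mark.parametrize("n_bins", [933, 934])  # odd and even bin counts
    def test_median_sampler_matches_direct_simulation(self, n_bins, rng):
        """The order-statistic quantile transform reproduces the distribution
        of the median of iid Poisson bins."""
        lam = 173.9
        direct = np.median(rng.poisson(lam, size=(4000, n_bins)), axis=1)
        sampled = _sample_statistic(rng, lam, n_bins, 4000, "median")
        ks = stats.ks_2samp(direct, sampled)
        assert ks.pvalue > 0.01
        assert sampled.mean() == pytest.approx(direct.mean(), abs=0.05)

    def test_mean_sampler_moments(self, rng):
        lam, B = 173.9, 934
        draws = _sample_statistic(rng, lam, B, 20_000, "mean")
        assert draws.mean() == pytest.approx(lam, abs=0.02)
        assert draws.std() == pytest.approx(np.sqrt(lam / B), rel=0.05)


class TestZReference:
    def test_mean_statistic_clt_moments(self, genome, zref_mean):
        """CLT oracle: mu_ref ~ lambda, sigma_ref ~ sqrt(lambda / B_c)."""
        lam = genome.mean_depth(1e7)
        for chrom in genome.chromosomes:
            assert zref_mean.mu_ref[chrom] == pytest.approx(lam, rel=1e-3)
            expected_sd = np.sqrt(lam / genome.n_bins(chrom))
            assert zref_mean.sigma_ref[chrom] == pytest.approx(expected_sd, rel=0.05)

    def test_more_bins_tighter_statistic(self, zref_mean, zref_median):
        for ref in (zref_mean, zref_median):
            assert ref.sigma_ref["chr13"] < ref.sigma_ref["chr21"]

    def test_deterministic_for_fixed_seed(self, genome):
        a = ns.build_z_reference(genome, 1e7, n_reference=500, seed=3)
        b = ns.build_z_reference(genome, 1e7, n_reference=500, seed=3)
        assert a == b

    def test_low_depth_warns(self, genome):
        with pytest.warns(UserWarning, match="shallow"):
            ns.build_z_reference(genome, 50_000, n_reference=100, statistic="mean", seed=1)


class TestSampleZ:
    def test_null_z_standard_normal(self, genome, zref_median):
        """Euploid z against its own reference: mean 0, SD 1 within
        sampling tolerance (median statistic)."""
        lam = genome.mean_depth(1e7)
        draws = _sample_statistic(np.random.default_rng(11), lam, genome.n_bins("chr21"), 20_000, "median")
        z = (draws - zref_median.mu_ref["chr21"]) / zref_median.sigma_ref["chr21"]
        assert abs(z.mean()) < 0.05
        assert 0.9 < z.std() < 1.1

    def test_noncentrality_formula(self, genome, zref_mean):
        """Mean-statistic oracle: E[z] = (ff/2) sqrt(lambda B_c)."""
        lam = genome.mean_depth(1e7)
        B = genome.n_bins("chr21")
        ff = 0.01
        z = np.array([
            ns.simulate_sample_z(genome, zref_mean, 1e7, ff, "T21", seed=1000 + i)
            for i in range(800)
        ])
        expected = (ff / 2) * np.sqrt(lam * B)
        assert z.mean() == pytest.approx(expected, abs=4 / np.sqrt(800) + 0.05)

    def test_z_stochastically_increasing_in_ff(self, genome, zref_median):
        means = []
        for ff in (0.0, 0.01, 0.02, 0.03):
            z = [ns.simulate_sample_z(genome, zref_median, 1e7, ff, "T18", seed=i) for i in range(200)]
            means.append(np.mean(z))
        assert all(np.diff(means) > 0)

    def test_unknown_trisomy_rejected(self, genome, zref_median):
        with pytest.raises(ValueError, match="trisomy"):
            ns.simulate_sample_z(genome, zref_median, 1e7, 0.05, "T20")


class TestSensitivity:
    def test_saturates_at_high_ff(self, genome, zref_median):
        as_, _ = ns.sensitivity_at_ff(genome, zref_median, 1e7, "T21", 0.40, n_reps=2000, seed=1)
        assert as_ == 1.0

    def test_null_ff_is_false_positive_rate(self, genome, zref_mean):
        as_, _ = ns.sensitivity_at_ff(genome, zref_mean, 1e7, "T21", 0.0, n_reps=50_000, seed=2)
        assert as_ < 0.004

    def test_matches_normal_oracle_on_grid(self, genome, zref_mean):
        """Mean-statistic AS equals Phi((ff/2) sqrt(lambda B) - 3) within 3
        binomial standard errors over a 10-point FF grid."""
        lam = genome.mean_depth(1e7)
        B = genome.n_bins("chr21")
        n_reps = 4000
        for ff in np.linspace(0.008, 0.022, 10):
            as_, se = ns.sensitivity_at_ff(genome, zref_mean, 1e7, "T21", float(ff), n_reps=n_reps, seed=31)
            oracle = stats.norm.cdf((ff / 2) * np.sqrt(lam * B) - 3)
            assert abs(as_ - oracle) < 3 * max(se, np.sqrt(oracle * (1 - oracle) / n_reps))

    def test_curve_monotone_in_reads(self, genome, zref_median):
        """Doubling effective reads never decreases AS (within MC error).
        The deeper run needs its own reference at the deeper depth."""
        ref2 = ns.build_z_reference(genome, 2e7, n_reference=10_000, statistic="median", seed=7)
        grid = np.array([0.01, 0.015, 0.02, 0.03])
        c1 = ns.build_sensitivity_curve(genome, zref_median, 1e7, "T18", grid, n_reps=2000, seed=5)
        c2 = ns.build_sensitivity_curve(genome, ref2, 2e7, "T18", grid, n_reps=2000, seed=5)
        assert np.all(c2.sensitivity >= c1.sensitivity - 3 * (c1.mc_se + c2.mc_se))

    def test_chromosome_size_ordering(self, genome, zref_mean):
        """Bigger chromosome, more reads, higher AS at fixed FF: with the
        continuous mean statistic AS_chr13 >= AS_chr18 >= AS_chr21."""
        grid = np.array([0.008, 0.012, 0.016, 0.02])
        curves = {
            t: ns.build_sensitivity_curve(genome, zref_mean, 1e7, t, grid, n_reps=4000, seed=9)
            for t in ("T13", "T18", "T21")
        }
        tol = 3 * (curves["T13"].mc_se + curves["T21"].mc_se)
        assert np.all(curves["T13"].sensitivity >= curves["T18"].sensitivity - tol)
        assert np.all(curves["T18"].sensitivity >= curves["T21"].sensitivity - tol)

    def test_degenerate_grid(self, genome, zref_median):
        curve = ns.build_sensitivity_curve(genome, zref_median, 1e7, "T13", np.array([0.02]), n_reps=500, seed=3)
        assert len(curve.sensitivity) == 1

    def test_curve_deterministic_and_serializable(self, genome, zref_median, tmp_path):
        grid = np.array([0.01, 0.02])
        a = ns.build_sensitivity_curve(genome, zref_median, 1e7, "T21", grid, n_reps=500, seed=8)
        b = ns.build_sensitivity_curve(genome, zref_median, 1e7, "T21", grid, n_reps=500, seed=8)
        np.testing.assert_array_equal(a.sensitivity, b.sensitivity)
        path = tmp_path / "curve.json"
        a.to_json(path)
        back = ns.SensitivityCurve.from_json(path)
        np.testing.assert_allclose(back.sensitivity, a.sensitivity)


class TestFalsePositiveRate:
    def test_higher_cutoff_lowers_rate(self, genome):
        ref3 = ns.build_z_reference(genome, 1e7, n_reference=20_000, statistic="mean", z_cutoff=3, seed=4)
        ref4 = ns.build_z_reference(genome, 1e7, n_reference=20_000, statistic="mean", z_cutoff=4, seed=4)
        r3 = ns.false_positive_rate(genome, ref3, 1e7, "chr21", n_reps=100_000, seed=5)
        r4 = ns.false_positive_rate(genome, ref4, 1e7, "chr21", n_reps=100_000, seed=5)
        assert r4 < r3

    def test_reproducible(self, genome, zref_mean):
        a = ns.false_positive_rate(genome, zref_mean, 1e7, "chr18", n_reps=50_000, seed=6)
        b = ns.false_positive_rate(genome, zref_mean, 1e7, "chr18", n_reps=50_000, seed=6)
        assert a == b

    def test_unknown_chromosome(self, genome, zref_mean):
        with pytest.raises(KeyError):
            ns.false_positive_rate(genome, zref_mean, 1e7, "chr99", n_reps=1000, seed=1)
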