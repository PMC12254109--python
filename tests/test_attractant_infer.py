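"""Stage-2 likelihood, priors and posterior sampling of theta."""

import math

import numpy as np
import pytest
from scipy import stats

from woundwalk.attractant import AttractantParams, predicted_bias
from woundwalk.attractant_infer import (
    SD_FLOOR,
    AttractantLikelihood,
    TruncatedNormal,
    Uniform,
    marginal_mode,
    prior_presets,
    sample_theta,
    theta_log_likelihood,
)
from woundwalk.brw_infer import BinPosterior
from woundwalk.synthetic import control_scenario, generate_binned_bias, knockdown_scenario
from woundwalk.tracks import BinGrid, WoundGeometry

GRID = BinGrid(spatial_edges=(70.0, 110.0, 150.0, 190.0, 230.0),
               temporal_edges=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0))


def _flat_bins(grid, b0=0.05, sd=0.01, rng=None):
    rng = rng or np.random.default_rng(0)
    out = []
    for i in range(grid.n_temporal):
        for j in range(grid.n_spatial):
            out.append(BinPosterior(
                i_time=i, j_space=j, k_azimuth=None,
                observed_bias_mean=b0 + rng.normal(0, sd),
                observed_bias_sd=sd,
                observed_persistence_mean=0.3, observed_persistence_sd=0.1,
                n_steps=50))
    return out


class TestThetaLogLikelihood:
    def test_matches_brute_force_gaussian_sum(self, wound, params):
        bins = _flat_bins(GRID)[:3]
        like = AttractantLikelihood(bins, wound, GRID, exclude_first_spatial=False)
        theta = params.as_vector()
        expected = 0.0
        for b in bins:
            r = GRID.spatial_centers()[b.j_space]
            t = GRID.temporal_centers()[b.i_time]
            pred = predicted_bias(np.array(wound.center) + [r, 0.0], t, wound, params)
            expected += stats.norm.logpdf(b.observed_bias_mean, pred,
                                          max(b.observed_bias_sd, SD_FLOOR))
        assert like.log_likelihood(theta) == pytest.approx(expected, rel=1e-9)

    def test_exclusion_zone_skips_inner_bin(self, wound):
        grid = BinGrid()  # first spatial bin 0-70 um
        bins = _flat_bins(grid)
        like = AttractantLikelihood(bins, wound, grid)
        assert like.n_bins == grid.n_temporal * (grid.n_spatial - 1)
        assert all(b.j_space != 0 for b in like.bins)

    def test_all_excluded_raises(self, wound):
        grid = BinGrid(spatial_edges=(0.0, 70.0), temporal_edges=(0.0, 25.0))
        bins = _flat_bins(grid)
        with pytest.raises(ValueError, match="excluded"):
            AttractantLikelihood(bins, wound, grid)

    def test_flat_model_peaks_at_data_value(self, wound):
        bins = _flat_bins(GRID, b0=0.05, sd=0.01, rng=np.random.default_rng(1))
        base = dict(q=0.0, D=100.0, tau=10.0, m=0.0, R0=1.0, kd=1.0)
        ll = [
            theta_log_likelihood(
                AttractantParams(b0=b0, **base), bins, wound, GRID,
                exclude_first_spatial=False)
            for b0 in (0.03, 0.05, 0.07)
        ]
        assert ll[1] > ll[0] and ll[1] > ll[2]

    def test_single_bin_peak_density(self, wound, params):
        r = GRID.spatial_centers()[2]
        t = GRID.temporal_centers()[1]
        pred = predicted_bias(np.array(wound.center) + [r, 0.0], t, wound, params)
        b = BinPosterior(i_time=1, j_space=2, k_azimuth=None,
                         observed_bias_mean=pred, observed_bias_sd=0.01,
                         observed_persistence_mean=0.3, observed_persistence_sd=0.1,
                         n_steps=10)
        ll = theta_log_likelihood(params, [b], wound, GRID, exclude_first_spatial=False)
        assert ll == pytest.approx(-math.log(0.01 * math.sqrt(2 * math.pi)))

    def test_invariant_to_bin_ordering(self, wound, params):
        bins = _flat_bins(GRID)
        fwd = theta_log_likelihood(params, bins, wound, GRID, exclude_first_spatial=False)
        rev = theta_log_likelihood(params, bins[::-1], wound, GRID, exclude_first_spatial=False)
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_sd_floor_applied(self, wound, params):
        b = _flat_bins(GRID)[5]
        b.observed_bias_sd = 0.0
        like = AttractantLikelihood([b], wound, GRID, exclude_first_spatial=False)
        assert like.sds[0] == SD_FLOOR


class TestPriors:
    def test_wildtype_preset_supports(self, rng):
        wt = prior_presets("wildtype")
        draws = wt.sample(rng, 2000)
        assert np.all(draws[:, 1] >= 0)  # D truncated at 0
        assert np.all((draws[:, 6] >= 0) & (draws[:, 6] <= 1))  # b0 in [0,1]
        # tau ~ TN(18, 3): truncation at 0 is ~6 sd away, mean barely shifts
        assert draws[:, 2].mean() == pytest.approx(18.0, abs=0.3)

    def test_kd_preset_flat_tau(self, rng):
        kd = prior_presets("kd")
        draws = kd.sample(rng, 5000)
        tau = draws[:, 2]
        assert tau.min() >= 0 and tau.max() <= 25
        ks = stats.kstest(tau, stats.uniform(0, 25).cdf)
        assert ks.pvalue > 0.01

    def test_log_prior_vectorised_matches_scalar(self):
        wt = prior_presets("wildtype")
        thetas = wt.sample(np.random.default_rng(3), 10)
        vec = wt.log_prior(thetas)
        for k in range(10):
            assert vec[k] == pytest.approx(float(wt.log_prior(thetas[k])))

    def test_truncnorm_logpdf_matches_scipy(self):
        tn = TruncatedNormal(0.02, 0.02, 0.0, 1.0)
        ref = stats.truncnorm(-1.0, (1.0 - 0.02) / 0.02, loc=0.02, scale=0.02)
        for x in (0.001, 0.02, 0.09):
            assert tn.logpdf(x) == pytest.approx(ref.logpdf(x), rel=1e-9)
        assert tn.logpdf(-0.01) == -math.inf

    def test_uniform_outside_support(self):
        u = Uniform(0, 10)
        assert u.logpdf(11.0) == -math.inf
        assert u.logpdf(5.0) == pytest.approx(-math.log(10))


class TestSampleTheta:
    def test_b0_recovery_from_flat_bias(self, wound):
        bins = _flat_bins(GRID, b0=0.05, sd=0.01, rng=np.random.default_rng(7))
        post = sample_theta(bins, "kd", wound, GRID, max_steps=3000,
                            check_every=1500, seed=1, exclude_first_spatial=False)
        sd = post.samples["b0"].std()
        assert abs(post.means["b0"] - 0.05) < 2 * sd + 0.01
        assert set(post.weakly_identified) == {"q", "m", "R0", "kd"}

    def test_posterior_contraction_with_tighter_bins(self, wound):
        scen = control_scenario(seed=9)
        bins, _ = generate_binned_bias(scen, GRID, noise_sd=0.02, rng=5)
        tight = [BinPosterior(**{**b.to_dict()}) for b in bins]
        for b in tight:
            b.observed_bias_sd = b.observed_bias_sd / 2
        wide_post = sample_theta(bins, "kd", wound, GRID, max_steps=6000,
                                 check_every=3000, seed=2, exclude_first_spatial=False)
        tight_post = sample_theta(tight, "kd", wound, GRID, max_steps=6000,
                                  check_every=3000, seed=2, exclude_first_spatial=False)
        for name in ("D", "tau", "b0"):
            # central 80% interval; 10% slack absorbs finite-chain noise
            wide_w = np.diff(np.percentile(wide_post.samples[name], [10, 90]))[0]
            tight_w = np.diff(np.percentile(tight_post.samples[name], [10, 90]))[0]
            assert tight_w <= wide_w * 1.1, name

    def test_save_and_samples_csv(self, wound, tmp_path):
        bins = _flat_bins(GRID, rng=np.random.default_rng(8))
        post = sample_theta(bins, "kd", wound, GRID, max_steps=600, check_every=600,
                            seed=3, exclude_first_spatial=False)
        post.save(tmp_path / "theta.json", samples_csv=tmp_path / "s.csv")
        assert (tmp_path / "theta.json").exists()
        import pandas as pd

        df = pd.read_csv(tmp_path / "s.csv")
        assert list(df.columns) == ["q", "D", "tau", "m", "R0", "kd", "b0"]


def test_marginal_mode_of_peaked_samples(rng):
    samples = rng.normal(5.0, 0.3, 20000)
    assert marginal_mode(samples) == pytest.approx(5.0, abs=0.1)
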