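"""Code statistics: SNR, sparsity, uncertainty profiles, noise correlations,
tuning modulation, gain dynamics, and grating-mixture variability."""

import numpy as np
import pytest

from adaptcode.analysis import (
    binary_entropy,
    gain_dynamics_analysis,
    grating_bank,
    grating_mixture_analysis,
    noise_correlation_experiment,
    response_statistics,
    sine_belief_driver,
    snr_db,
    task_correlations,
    tuning_curve_analysis,
    tuning_curves,
    uncertainty_profile,
)
from adaptcode.stimuli import generate_patches


class TestSnr:
    def test_sentinels(self):
        x = np.ones((4, 4))
        assert snr_db(x, x) == np.inf
        assert snr_db(np.zeros((4, 4)), x) == -np.inf

    def test_zero_reconstruction_gives_zero_db(self):
        x = np.random.default_rng(0).standard_normal((8, 8))
        assert snr_db(x, np.zeros_like(x)) == pytest.approx(0.0)

    def test_ten_db_arithmetic(self):
        x = np.full(100, 1.0)
        xhat = x - np.sqrt(0.1)
        assert snr_db(x, xhat) == pytest.approx(10.0)

    def test_masked_evaluation(self):
        x = np.ones((4, 4))
        xhat = x.copy()
        xhat[0, 0] = 0.0  # error only outside the mask
        mask = np.zeros((4, 4), bool)
        mask[2:, 2:] = True
        assert snr_db(x, xhat, mask) == np.inf


class TestResponseStatistics:
    def test_gaussian_kurtosis(self):
        z = np.random.default_rng(1).standard_normal((1000, 100))
        assert response_statistics(z)["kurtosis"] == pytest.approx(3.0, abs=0.2)

    def test_silent_neuron_is_never_active(self):
        z = np.random.default_rng(2).standard_normal((50, 3))
        z[:, 1] = 0.0
        stats = response_statistics(z)
        assert not stats["active"][:, 1].any()

    def test_zero_variance_pool_gives_nan_kurtosis(self):
        assert np.isnan(response_statistics(np.ones((10, 2)))["kurtosis"])


def test_binary_entropy_bounds_and_extremes():
    p = np.linspace(0, 1, 101)
    h = binary_entropy(p)
    assert h.min() >= 0 and h.max() <= 1
    assert binary_entropy(0.5) == 1.0
    assert binary_entropy(0.0) == 0.0 and binary_entropy(1.0) == 0.0
    assert np.argmax(h) == 50


class TestUncertaintyProfile:
    def test_full_code_activity_is_flat_across_uncertainty(
        self, trace_factory, dictionary
    ):
        tr = trace_factory("detection", "full", seed=3, T=2000)
        up = uncertainty_profile(tr, dictionary, bins="deciles")
        acts = [b["mean_activity"] for b in up["bins"]]
        rel_range = (max(acts) - min(acts)) / np.mean(acts)
        assert rel_range < 0.10
        assert abs(up["spearman_uncertainty_activity"]) < 0.2

    def test_adaptive_activity_rises_with_uncertainty(self, trace_factory, dictionary):
        tr = trace_factory("detection", "adaptive", seed=3, T=2000)
        up = uncertainty_profile(tr, dictionary, bins="deciles")
        assert up["spearman_uncertainty_activity"] > 0.2

    def test_cumulative_variance_curves_are_proper(self, trace_factory, dictionary):
        tr = trace_factory("detection", "full", seed=3, T=2000)
        up = uncertainty_profile(tr, dictionary, bins="thirds")
        for b in up["bins"]:
            cum = b["cumulative_variance"]
            assert np.all(np.diff(cum) >= -1e-12)
            assert cum[-1] == pytest.approx(1.0)

    def test_fixed_thirds_binning(self, trace_factory, dictionary):
        tr = trace_factory("detection", "adaptive", seed=3, T=2000)
        up = uncertainty_profile(tr, dictionary, bins="thirds")
        assert len(up["bins"]) + len(up["empty_bins"]) == 3


class TestTaskCorrelations:
    def test_full_vs_full_is_identical(self):
        S = np.random.default_rng(3).standard_normal((200, 20))
        out = task_correlations(S, S, n_select=5)
        np.testing.assert_allclose(out["corr_full"], out["corr_adaptive"])
        np.testing.assert_allclose(np.diag(out["corr_full"]), 1.0)

    def test_adaptive_correlations_differ_from_full(self, trace_factory):
        full = trace_factory("detection", "full", seed=3, T=2000)
        adapt = trace_factory("detection", "adaptive", seed=3, T=2000)
        out = task_correlations(full.S, adapt.Z, n_select=10)
        assert np.linalg.norm(out["corr_full"] - out["corr_adaptive"]) > 0

    def test_constant_rows_are_flagged_not_nan(self):
        S = np.random.default_rng(4).standard_normal((100, 5))
        Z = S.copy()
        Z[:, 0] = 0.0
        out = task_correlations(S, Z, n_select=5)
        assert np.all(np.isfinite(out["corr_adaptive"]))


class TestNoiseCorrelations:
    def test_constant_belief_gives_uncorrelated_responses(
        self, dictionary, detection_table, sparse_cfg
    ):
        img = generate_patches(1, 16, seed=99, kind="dead_leaves")[0]
        driver = np.full(300, 0.5)
        out = noise_correlation_experiment(
            img, driver, detection_table, dictionary, sparse_cfg,
            n_rep=300, seed=5,
        )
        assert out["mean_abs_offdiag"] < 0.08  # only iid noise varies

    def test_full_code_correlations_are_near_zero(
        self, dictionary, sparse_cfg
    ):
        img = generate_patches(1, 16, seed=99, kind="dead_leaves")[0]
        out = noise_correlation_experiment(
            img, sine_belief_driver(1000), None, dictionary, sparse_cfg,
            n_rep=1000, seed=6,
        )
        assert out["mean_abs_offdiag_full"] < 0.05

    def test_belief_fluctuations_create_low_rank_structure(
        self, dictionary, detection_table, sparse_cfg
    ):
        img = generate_patches(1, 16, seed=99, kind="dead_leaves")[0]
        out = noise_correlation_experiment(
            img, sine_belief_driver(1000), detection_table, dictionary, sparse_cfg,
            n_rep=1000, seed=7,
        )
        sv, svf = out["singular_values"], out["singular_values_full"]
        share = sv[:5].sum() / sv.sum()
        share_full = svf[:5].sum() / svf.sum()
        assert share > share_full


class TestTuningCurves:
    def test_zero_thresholds_make_conditions_identical(self, dictionary, sparse_cfg):
        orients, stack = grating_bank(16, 8, frequencies=(3.0,), n_phase=4)
        c1 = tuning_curves(dictionary, sparse_cfg, np.zeros(128), orients, stack)
        c2 = tuning_curves(dictionary, sparse_cfg, np.zeros(128), orients, stack)
        np.testing.assert_array_equal(c1, c2)
        assert c1.shape == (128, 8)
        assert np.all(c1 >= 0)

    def test_attended_position_boosts_matched_neurons(
        self, dictionary, localization_table, localization_task, trace_factory
    ):
        """Neurons get a higher tuning peak under the thresholds of the
        belief that the target sits at their receptive field than under
        time-averaged thresholds."""
        tr = trace_factory("localization", "adaptive", seed=3, T=2000)
        res = tuning_curve_analysis(
            dictionary, localization_table, tr, localization_task.sparse_cfg,
            n_orient=16, fit=False,
        )
        ok = ~res["silent"]
        peak_att = res["attended"][ok].max(axis=1)
        peak_un = res["unattended"][ok].max(axis=1)
        assert peak_att.mean() >= peak_un.mean()

    def test_gaussian_fits_return_parameters(
        self, dictionary, localization_table, localization_task, trace_factory
    ):
        tr = trace_factory("localization", "adaptive", seed=3, T=2000)
        res = tuning_curve_analysis(
            dictionary, localization_table, tr, localization_task.sparse_cfg,
            n_orient=16, fit=True,
        )
        fitted = [f for f in res["fits"] if f is not None]
        assert len(fitted) > 100
        assert all(np.isfinite(f["attended"]["width"]) for f in fitted[:10])


class TestGainDynamics:
    def test_autocorrelation_normalized_at_lag_zero(self, trace_factory, dictionary):
        tr = trace_factory("localization", "adaptive", seed=3, T=2000)
        out = gain_dynamics_analysis(tr, dictionary, seed=8)
        np.testing.assert_allclose(out["autocorr"][:, 0], 1.0, atol=1e-9)

    def test_threshold_correlations_follow_tuning_similarity(
        self, trace_factory, dictionary
    ):
        from scipy.stats import spearmanr

        tr = trace_factory("localization", "adaptive", seed=3, T=2000)
        out = gain_dynamics_analysis(tr, dictionary, seed=8)
        rho = spearmanr(out["tuning_bin_centers"], out["xi_corr_by_tuning"]).statistic
        rho_shuf = spearmanr(
            out["tuning_bin_centers"], out["xi_corr_by_tuning_shuffled"]
        ).statistic
        assert rho > 0.5
        assert abs(rho_shuf) < rho

    def test_decay_times_are_positive_and_bounded(self, trace_factory, dictionary):
        tr = trace_factory("localization", "adaptive", seed=3, T=2000)
        out = gain_dynamics_analysis(tr, dictionary, seed=8)
        assert np.all(out["decay_times"] >= 1)
        assert np.all(out["decay_times"] <= len(out["lags"]))


class TestGratingMixture:
    def test_constant_gains_give_identical_trials(self, dictionary, sparse_cfg):
        res = grating_mixture_analysis(
            dictionary, np.zeros((5, 128)), sparse_cfg, seed=9,
            n_trials=10, n_present=20,
        )
        pop = res["population_responses"]
        assert np.abs(pop - pop.mean(axis=0)).max() < 1e-12

    def test_dominant_component_wins_the_fit(self, dictionary, sparse_cfg):
        """The 60-degree grating enters with weight 1 vs 0.2, so the fitted
        weight of its Gaussian exceeds the 150-degree one (full code)."""
        res = grating_mixture_analysis(
            dictionary, np.zeros((5, 128)), sparse_cfg, seed=9,
            n_trials=5, n_present=20,
        )
        coeffs = res["mixture_coeffs"]
        assert coeffs[:, 0].mean() > coeffs[:, 1].mean()

    def test_shuffling_a_tuning_aligned_gain_field_flattens_dpref(
        self, dictionary, sparse_cfg
    ):
        """Mechanism check on a synthetic gain ensemble: gains that
        co-modulate similarly tuned neurons produce a preferred-orientation
        dependence of noise correlations, destroyed by shuffling neuron
        identities."""
        from adaptcode.analysis import grating_bank, tuning_curves

        orients, stack = grating_bank(16, 16, frequencies=(3.0,), n_phase=4)
        curves = tuning_curves(dictionary, sparse_cfg, np.zeros(128), orients, stack)
        pref = orients[np.argmax(curves, axis=1)]
        rng = np.random.default_rng(10)
        # gain field: a drifting bump over preferred orientation
        T = 400
        centers = rng.uniform(0, 180, T)
        d = np.abs((pref[None, :] - centers[:, None] + 90) % 180 - 90)
        xi_traj = np.where(d < 40, 0.0, 3.0)
        res = grating_mixture_analysis(
            dictionary, xi_traj, sparse_cfg, seed=11, n_trials=5, n_present=150,
        )
        cb = res["corr_by_dpref"]
        cbs = res["corr_by_dpref_shuffled"]
        assert np.nanmax(cb) - np.nanmin(cb) > np.nanmax(cbs) - np.nanmin(cbs)
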