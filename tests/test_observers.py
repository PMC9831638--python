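"""Measurement functions and Bayesian belief updates for the three tasks."""

import numpy as np
import pytest

from adaptcode import observers as obs
from adaptcode.sparse import SparseConfig, encode
from adaptcode.stimuli import Template, generate_patches, make_grating, make_templates, superimpose_target


class TestDetectionMeasurement:
    def test_zero_code_projects_the_pca_mean(self, toy_orthonormal_dictionary):
        d = toy_orthonormal_dictionary
        objt = Template(pixels=np.arange(16.0).reshape(4, 4), kind="object")
        m = obs.measure_detection(np.zeros(16), d, objt, sigma_m2=0.0)
        assert m == pytest.approx(float(d.pca.mean @ objt.pixels.ravel()))

    def test_noise_free_measurement_is_deterministic(self, toy_orthonormal_dictionary):
        d = toy_orthonormal_dictionary
        objt = Template(pixels=np.ones((4, 4)), kind="object")
        z = np.random.default_rng(0).standard_normal(16)
        m1 = obs.measure_detection(z, d, objt, sigma_m2=0.0)
        m2 = obs.measure_detection(z, d, objt, sigma_m2=0.0)
        assert m1 == m2

    def test_noise_variance_scale(self, toy_orthonormal_dictionary):
        d = toy_orthonormal_dictionary
        objt = Template(pixels=np.ones((4, 4)), kind="object")
        rng = np.random.default_rng(1)
        z = np.zeros(16)
        ms = [obs.measure_detection(z, d, objt, 0.01, rng) for _ in range(1000)]
        assert np.var(ms) == pytest.approx(0.01, rel=0.2)

    def test_readout_is_the_linear_form_of_the_projection(
        self, toy_orthonormal_dictionary
    ):
        d = toy_orthonormal_dictionary
        objt = Template(
            pixels=np.random.default_rng(2).standard_normal((4, 4)), kind="object"
        )
        w, b = obs.detection_readout(d, objt)
        z = np.random.default_rng(3).standard_normal(16)
        direct = obs.measure_detection(z, d, objt, sigma_m2=0.0)
        assert z @ w + b == pytest.approx(direct, rel=1e-10)


class TestClassModels:
    def test_degenerate_class_gets_floored_sigma(self):
        models = obs.fit_class_models({"a": np.array([1.0, 1.0, 1.0])})
        assert models["a"].mu == 1.0
        assert models["a"].floored
        assert models["a"].sigma > 0

    def test_hand_arithmetic(self):
        models = obs.fit_class_models({"a": np.array([0.0, 2.0])})
        assert models["a"].mu == 1.0
        assert models["a"].sigma == pytest.approx(np.sqrt(2.0))

    def test_estimator_consistency(self):
        rng = np.random.default_rng(4)
        models = obs.fit_class_models(
            {"p": rng.normal(3.0, 1.0, 10_000), "a": rng.normal(0.0, 1.0, 10_000)}
        )
        assert models["p"].mu == pytest.approx(3.0, abs=0.05)
        assert models["a"].mu == pytest.approx(0.0, abs=0.05)


class TestBinaryUpdate:
    def test_uninformative_likelihood_keeps_the_prior(self):
        m = obs.ClassModel(0.0, 1.0)
        post, _ = obs.update_binary_belief(0.37, 1.23, m, m, hazard=0.0)
        assert post == pytest.approx(0.37, rel=1e-12)

    def test_half_hazard_forgets_everything(self):
        mp, mn = obs.ClassModel(1.0, 1.0), obs.ClassModel(-1.0, 1.0)
        _, pred = obs.update_binary_belief(0.9, 2.0, mp, mn, hazard=0.5)
        assert pred == pytest.approx(0.5, rel=1e-12)

    def test_matches_direct_density_ratio_arithmetic(self):
        """Posterior equals the brute-force Bayes computation to 1e-12."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            mp = obs.ClassModel(rng.normal(), abs(rng.normal()) + 0.5)
            mn = obs.ClassModel(rng.normal(), abs(rng.normal()) + 0.5)
            prior = rng.uniform(0.01, 0.99)
            m = rng.normal(scale=2)
            lp = np.exp(-0.5 * ((m - mp.mu) / mp.sigma) ** 2) / mp.sigma
            ln = np.exp(-0.5 * ((m - mn.mu) / mn.sigma) ** 2) / mn.sigma
            expected = lp * prior / (lp * prior + ln * (1 - prior))
            post, _ = obs.update_binary_belief(prior, m, mp, mn, hazard=0.01)
            assert post == pytest.approx(expected, abs=1e-12)

    def test_log_space_stability_for_extreme_measurements(self):
        mp, mn = obs.ClassModel(1.0, 0.1), obs.ClassModel(-1.0, 0.1)
        post, pred = obs.update_binary_belief(0.5, 1e6, mp, mn)
        assert np.isfinite(post) and np.isfinite(pred)
        post, _ = obs.update_binary_belief(0.5, -1e6, mp, mn)
        assert post == 0.0

    def test_exact_predictive_vs_low_hazard_approximation(self):
        mp, mn = obs.ClassModel(1.0, 1.0), obs.ClassModel(-1.0, 1.0)
        post, pred = obs.update_binary_belief(0.7, 0.9, mp, mn, hazard=0.01)
        _, pred_approx = obs.update_binary_belief(
            0.7, 0.9, mp, mn, hazard=0.01, approx_predictive=True
        )
        assert pred_approx == post
        assert abs(pred - post) < 0.02  # they agree closely at h = 0.01

    def test_invalid_inputs(self):
        m = obs.ClassModel(0.0, 1.0)
        with pytest.raises(ValueError):
            obs.update_binary_belief(1.2, 0.0, m, m)
        with pytest.raises(ValueError):
            obs.update_binary_belief(0.5, 0.0, m, m, hazard=2.0)


class TestLocalizationMeasurement:
    def test_peak_found_at_clean_cross(self, identity_dictionary):
        _, cross = make_templates(16, seed=0)
        img = superimpose_target(np.zeros((16, 16)), cross, (10.0, 12.0))
        # identity dictionary: the code IS the image
        peak = obs.measure_localization(img.ravel(), identity_dictionary, cross)
        assert peak == (10, 12)

    def test_tie_break_on_flat_correlation(self, identity_dictionary):
        _, cross = make_templates(16, seed=0)
        peak = obs.measure_localization(
            np.zeros(256), identity_dictionary, cross
        )
        assert peak == (1, 1)

    def test_robust_on_weak_backgrounds(self, identity_dictionary):
        """Full-code localization lands within 1 px of truth >= 95% of trials."""
        _, cross = make_templates(16, seed=0)
        rng = np.random.default_rng(6)
        hits = 0
        for trial in range(100):
            bg = generate_patches(1, 16, seed=1000 + trial)[0]
            pos = rng.integers(4, 13, size=2)
            img = superimpose_target(bg, cross, tuple(pos))
            peak = obs.measure_localization(img.ravel(), identity_dictionary, cross)
            if max(abs(peak[0] - pos[0]), abs(peak[1] - pos[1])) <= 1:
                hits += 1
        assert hits >= 95


class TestPositionBelief:
    def test_limits(self):
        b = obs.GaussBelief(np.array([5.0, 5.0]), np.array([4.0, 4.0]))
        out = obs.update_position_belief(b, (9.0, 1.0), sigma_m2=1e12, walk_var=0.0)
        np.testing.assert_allclose(out.mean, b.mean, atol=1e-9)
        out = obs.update_position_belief(b, (9.0, 1.0), sigma_m2=0.0, walk_var=0.0)
        np.testing.assert_allclose(out.mean, [9.0, 1.0])
        assert np.all(out.var < 1e-200)

    def test_hand_conjugate_arithmetic(self):
        b = obs.GaussBelief(np.array([10.0, 10.0]), np.array([4.0, 4.0]))
        out = obs.update_position_belief(b, (14.0, 14.0), sigma_m2=4.0, walk_var=0.0)
        np.testing.assert_allclose(out.mean, [12.0, 12.0])
        np.testing.assert_allclose(out.var, [2.0, 2.0])

    def test_equals_independent_kalman_step(self):
        """The conjugate update matches a textbook Kalman filter step
        (static state, measurement noise sigma_m^2) to 1e-10."""
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            mu = rng.normal(scale=10)
            var = rng.uniform(0.1, 25.0)
            m = rng.normal(scale=10)
            sm2 = rng.uniform(1e-6, 25.0)
            wv = rng.uniform(0.0, 9.0)
            # Kalman: K = P / (P + R); mu' = mu + K (m - mu); P' = (1-K) P
            K = var / (var + sm2)
            mu_k = mu + K * (m - mu)
            var_k = (1 - K) * var
            b = obs.GaussBelief(np.array([mu, mu]), np.array([var, var]))
            out = obs.update_position_belief(b, (m, m), sigma_m2=sm2, walk_var=wv)
            assert out.mean[0] == pytest.approx(mu_k, abs=1e-10)
            assert out.var[0] == pytest.approx(var_k + wv, abs=1e-10)


class TestOrientationMachinery:
    def test_log_ratio_floor_handles_silent_neurons(self):
        S = np.zeros((20, 4))
        S[:, 0] = np.random.default_rng(8).standard_normal(20)
        R = obs.log_ratio_features(S)
        assert np.all(np.isfinite(R))
        # a silent neuron contributes a constant feature
        assert np.ptp(R[:, 2]) == 0.0

    def test_grating_categories_separate_h_and_v(self, dictionary):
        """Clustering codes of 0-deg and 90-deg gratings recovers the two
        orientation categories with high purity."""
        rng = np.random.default_rng(9)
        imgs, labels = [], []
        for _ in range(120):
            ori = rng.choice([0.0, 90.0])
            f = rng.uniform(2.0, 5.0)
            ph = rng.uniform(0, 2 * np.pi)
            imgs.append(make_grating(ori, f, ph, 16))
            labels.append(ori)
        imgs = np.stack(imgs)
        labels = np.asarray(labels)
        cfg = SparseConfig(lam=0.05, sigma2=0.5)
        S = encode(dictionary.pca.reduce(imgs), dictionary, cfg)
        cats = obs.learn_orientation_categories(S, dictionary, k=4, seed=0)
        for key, want in (("H", 0.0), ("V", 90.0)):
            members = labels[cats[key]]
            assert len(members) > 0
            purity = (members == want).mean()
            assert purity >= 0.9

    def test_category_discovery_is_seed_deterministic(self, dictionary, sparse_cfg):
        imgs = generate_patches(150, 16, seed=10, kind="dead_leaves")
        S = encode(dictionary.pca.reduce(imgs), dictionary, sparse_cfg)
        c1 = obs.learn_orientation_categories(S, dictionary, seed=3)
        c2 = obs.learn_orientation_categories(S, dictionary, seed=3)
        np.testing.assert_array_equal(c1["labels"], c2["labels"])

    def test_discriminant_on_separated_clouds_matches_mean_difference(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (400, 6)) + np.array([3, 0, 0, 0, 0, 0])
        b = rng.normal(0, 1, (400, 6))
        disc = obs.learn_discriminant(a, b)
        diff = a.mean(0) - b.mean(0)
        cos = abs(disc.w @ diff) / np.linalg.norm(diff)
        assert cos > 0.99

    def test_discriminant_cross_checked_against_sklearn(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(12)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        L = np.linalg.cholesky(cov)
        a = rng.standard_normal((500, 2)) @ L.T + [1.0, 2.0]
        b = rng.standard_normal((500, 2)) @ L.T
        disc = obs.learn_discriminant(a, b, ridge=1e-9)
        skl = LinearDiscriminantAnalysis(solver="lsqr").fit(
            np.vstack([a, b]), np.r_[np.ones(500), np.zeros(500)]
        )
        w_skl = skl.coef_.ravel() / np.linalg.norm(skl.coef_)
        assert abs(disc.w @ w_skl) > 0.999

    def test_identical_classes_give_chance_accuracy(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((300, 5))
        disc = obs.learn_discriminant(x, x.copy())
        proj_a = x @ disc.w
        thresh = proj_a.mean()
        acc = 0.5 * ((proj_a > thresh).mean() + (x @ disc.w <= thresh).mean())
        assert abs(acc - 0.5) < 0.1

    def test_discriminant_scale_equivariance(self):
        rng = np.random.default_rng(14)
        a = rng.normal(1.0, 1.0, (200, 4))
        b = rng.normal(0.0, 1.0, (200, 4))
        d1 = obs.learn_discriminant(a, b)
        d2 = obs.learn_discriminant(2 * a, 2 * b)
        assert abs(d1.w @ d2.w) > 0.999

    def test_orientation_measurement(self):
        disc = obs.Discriminant(w=np.array([1.0, -2.0, 0.5]), meta={})
        assert obs.measure_orientation(np.zeros(3), disc, sigma_m2=0.0) == 0.0
        z = np.array([1.0, -3.0, 2.0])
        m1 = obs.measure_orientation(z, disc, sigma_m2=0.0)
        m2 = obs.measure_orientation(-z, disc, sigma_m2=0.0)
        assert m1 == m2
        rng = np.random.default_rng(15)
        ms = [obs.measure_orientation(z, disc, 1e-4, rng) for _ in range(10_000)]
        assert np.var(ms) == pytest.approx(1e-4, rel=0.2)


def test_atom_centroids_identity_dictionary(identity_dictionary):
    cent = obs.atom_centroids(identity_dictionary)
    # atom k is the k-th pixel, so its centroid is that pixel's coordinate
    assert tuple(cent[0]) == (1.0, 1.0)
    assert tuple(cent[17]) == (2.0, 2.0)


def test_atom_orientations_on_gratings():
    """A dictionary whose atoms are gratings recovers their orientations."""
    from adaptcode.sparse import Dictionary
    from adaptcode.stimuli import PcaMap

    angles = [0.0, 45.0, 90.0, 135.0]
    feats = np.stack([make_grating(a, 4.0, 0.0, 16).ravel() for a in angles])
    feats /= np.linalg.norm(feats, axis=1, keepdims=True)
    d = Dictionary(feats, PcaMap(np.zeros(256), np.eye(256)))
    est = obs.atom_orientations(d)
    for got, want in zip(est, angles):
        delta = abs((got - want + 90.0) % 180.0 - 90.0)
        assert delta < 15.0
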