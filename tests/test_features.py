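"""Hand-crafted feature bank: reference values, oracles, invariances."""

import numpy as np
import pytest

from pgesdet.crops import CropSpec, enumerate_crops
from pgesdet.features import (
    DEFAULT_BANDS,
    FeatureConfig,
    cross_channel_correlation,
    extract_feature_matrix,
    extract_feature_vector,
    moment_features,
    petrosian_fd,
    spectral_features,
    svd_entropy,
    temporal_ratio,
    train_feature_classifier,
)


class TestMoments:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 50)
        var, skew, kurt, deg = moment_features(x)
        assert (var, skew, kurt, deg) == (1.0, 0.0, 1.0, False)

    def test_gaussian_kurtosis_near_three(self):
        x = np.random.default_rng(0).standard_normal(200_00)
        _, skew, kurt, _ = moment_features(x)
        assert abs(skew) < 0.1
        assert abs(kurt - 3.0) < 0.2

    def test_constant_is_degenerate(self):
        var, skew, kurt, deg = moment_features(np.full(100, 5.0))
        assert deg and var == skew == kurt == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            moment_features(np.ones(3))


class TestSpectral:
    def test_sine_peak_and_median(self):
        rate, f0 = 200.0, 5.0
        t = np.arange(2000) / rate
        sf = spectral_features(np.sin(2 * np.pi * f0 * t), rate)
        bin_hz = rate / 2000
        assert abs(sf.peak_freq_hz - f0) <= bin_hz
        assert abs(sf.median_freq_hz - f0) <= bin_hz
        assert not sf.degenerate

    def test_sine_power_lands_in_its_band(self):
        rate = 200.0
        t = np.arange(2000) / rate
        sf = spectral_features(np.sin(2 * np.pi * 10.0 * t), rate)
        assert sf.band_power["alpha"] / sf.total_energy > 0.99
        assert abs(sum(sf.band_rir.values()) - sum(
            sf.band_psi[b] / sum(sf.band_psi[k] for k in sf.band_psi)
            for b in sf.band_psi)) < 1e-12

    def test_offset_does_not_change_anything(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        a = spectral_features(x, 200.0)
        b = spectral_features(x + 100.0, 200.0)
        assert a.peak_freq_hz == b.peak_freq_hz
        assert a.median_freq_hz == b.median_freq_hz
        np.testing.assert_allclose(a.total_energy, b.total_energy, rtol=1e-9)

    def test_zero_series_degenerate(self):
        sf = spectral_features(np.zeros(2000), 200.0)
        assert sf.degenerate
        assert sf.peak_freq_hz == sf.median_freq_hz == 0.0
        assert all(v == 0.0 for v in sf.band_rir.values())

    def test_contract_violations(self):
        with pytest.raises(ValueError, match="2 s"):
            spectral_features(np.ones(100), 200.0)
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_features(np.ones(100), 20.0, {"hf": (15.0, 30.0)})


class TestPetrosian:
    def test_constant_is_exactly_one(self):
        assert petrosian_fd(np.full(500, 3.0)) == 1.0

    def test_alternating_reference_value(self):
        x = np.array([(-1.0) ** i for i in range(100)])
        # N=100, Nd=98: log10(100) / (log10(100) + log10(100/139.2))
        expected = np.log10(100) / (np.log10(100) + np.log10(100 / 139.2))
        assert abs(petrosian_fd(x) - expected) < 1e-12

    def test_monotone_in_sign_changes(self):
        n = 200
        values = []
        for n_flips in (5, 20, 80):
            x = np.cumsum(np.ones(n))
            flip_at = np.linspace(1, n - 2, n_flips).astype(int)
            sign = np.ones(n)
            for f in flip_at:
                sign[f:] *= -1
            values.append(petrosian_fd(np.cumsum(sign)))
        assert values[0] < values[1] < values[2]

    def test_matches_bruteforce_reimplementation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.standard_normal(rng.integers(10, 400))
            d = np.diff(x)
            nd = sum(1 for i in range(len(d) - 1) if d[i] * d[i + 1] < 0)
            n = len(x)
            expected = np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * nd)))
            assert abs(petrosian_fd(x) - expected) < 1e-9


class TestSvdEntropy:
    def test_constant_zero_entropy(self):
        ent, deg = svd_entropy(np.full(300, 2.0), embed_dim=10)
        assert abs(ent) < 1e-9
        assert not deg  # constant nonzero is rank one, not degenerate

    def test_all_zero_flagged(self):
        ent, deg = svd_entropy(np.zeros(300), embed_dim=10)
        assert ent == 0.0 and deg

    def test_bounded_by_log_embed_dim(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            ent, _ = svd_entropy(rng.standard_normal(400), embed_dim=20)
            assert 0.0 <= ent <= np.log2(20) + 1e-9

    def test_noise_higher_than_sine(self):
        rng = np.random.default_rng(3)
        t = np.arange(2000) / 200.0
        ent_sine, _ = svd_entropy(np.sin(2 * np.pi * 5 * t))
        ent_noise, _ = svd_entropy(rng.standard_normal(2000))
        assert ent_noise > ent_sine

    def test_matches_bruteforce_reimplementation(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.standard_normal(120)
            dim, delay = 8, 2
            rows = [x[i: i + dim * delay: delay]
                    for i in range(len(x) - (dim - 1) * delay)]
            sv = np.linalg.svd(np.array(rows), compute_uv=False)
            p = sv / sv.sum()
            p = p[p > 0]
            expected = float(-(p * np.log2(p)).sum())
            got, _ = svd_entropy(x, embed_dim=dim, delay=delay)
            assert abs(got - expected) < 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            svd_entropy(np.ones(20), embed_dim=20)


class TestCorrelation:
    def test_pair_count_and_reference_values(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(500)
        x = np.vstack([base, base, -base, rng.standard_normal(500)])
        corr = cross_channel_correlation(x)
        assert corr.shape == (6,)
        assert abs(corr[0] - 1.0) < 1e-12   # (0,1) identical
        assert abs(corr[1] + 1.0) < 1e-12   # (0,2) negated
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)

    def test_constant_row_gives_zero(self):
        x = np.vstack([np.ones(100), np.random.default_rng(5).standard_normal(100)])
        assert cross_channel_correlation(x)[0] == 0.0

    def test_ten_rows_give_45_pairs(self):
        x = np.random.default_rng(6).standard_normal((10, 100))
        assert cross_channel_correlation(x).shape == (45,)


class TestTemporalRatio:
    def test_stationary_near_one(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((1, 4000))
        for prop in ("rms", "line_length"):
            r = temporal_ratio(x, 200.0, prop)
            assert abs(r[0] - 1.0) < 0.1

    def test_growing_amplitude_detected(self):
        x = np.concatenate([np.ones(1000), 10 * np.ones(1000)])
        x = (x * np.sin(np.arange(2000)))[None, :]
        r = temporal_ratio(x, 200.0, "rms")
        assert abs(r[0] - 10.0) < 0.5

    def test_silent_first_half_stays_finite(self):
        x = np.concatenate([np.zeros(1000), np.ones(1000)])[None, :]
        r = temporal_ratio(x, 200.0, "rms")
        assert np.isfinite(r[0]) and r[0] > 1e6

    def test_unknown_property_rejected(self):
        with pytest.raises(ValueError):
            temporal_ratio(np.ones((1, 100)), 200.0, "energy")


class TestFeatureVector:
    def test_length_matches_config(self):
        cfg = FeatureConfig()
        rng = np.random.default_rng(10)
        v = extract_feature_vector(rng.standard_normal((10, 2000)), 200.0, cfg)
        assert v.shape == (cfg.n_features(10),)
        assert cfg.n_features(10) == len(cfg.feature_names(10))
        assert len(set(cfg.feature_names(10))) == cfg.n_features(10)

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((10, 2000))
        np.testing.assert_array_equal(
            extract_feature_vector(x, 200.0), extract_feature_vector(x, 200.0)
        )

    def test_offset_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((10, 2000)) * 5.0
        a = extract_feature_vector(x, 200.0)
        b = extract_feature_vector(x + 100.0, 200.0)
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-9)

    def test_all_zero_crop_finite_with_flag(self):
        cfg = FeatureConfig()
        v = extract_feature_vector(np.zeros((10, 2000)), 200.0, cfg)
        assert np.all(np.isfinite(v))
        flags = [i for i, n in enumerate(cfg.feature_names(10))
                 if n.endswith("degenerate")]
        assert np.all(v[flags] == 1.0)

    def test_transition_crop_ratios_exceed_one(self, easy_montaged):
        # the window straddling the suppression end has its slow activity in
        # the second half
        cs = enumerate_crops(easy_montaged, CropSpec())
        straddle = next(c for c in cs.crops if abs(c.end_s - 30.0) < 1e-6)
        r = temporal_ratio(straddle.data, 200.0, "rms")
        assert np.median(r) > 1.5

    def test_matrix_rows_match_vectors(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((3, 4, 2000))
        M = extract_feature_matrix(X, 200.0)
        np.testing.assert_array_equal(M[1], extract_feature_vector(X[1], 200.0))


class TestFeatureClassifier:
    def test_fit_predict_deterministic(self, easy_montaged):
        cs = enumerate_crops(easy_montaged, CropSpec(10.0, 1.0, 10.0))
        a = train_feature_classifier(cs, seed=0)
        b = train_feature_classifier(cs, seed=0)
        X, _ = cs.stacked(dtype=np.float64)
        np.testing.assert_array_equal(
            a.predict_proba_crops(X[:5]), b.predict_proba_crops(X[:5])
        )

    def test_single_class_rejected(self, easy_montaged):
        cs = enumerate_crops(easy_montaged, CropSpec(10.0, 1.0, 10.0))
        only_neg = [c for c in cs.crops if c.label == 0]
        from pgesdet.crops import CropSet

        with pytest.raises(ValueError, match="both classes"):
            train_feature_classifier(CropSet(only_neg, cs.spec))

    def test_unknown_model_rejected(self):
        from pgesdet.features import FeatureClassifier

        with pytest.raises(ValueError, match="unknown model"):
            FeatureClassifier(model="svm")

    def test_importances_named(self, easy_montaged):
        cs = enumerate_crops(easy_montaged, CropSpec(10.0, 1.0, 10.0))
        clf = train_feature_classifier(cs, seed=0, model="random_forest")
        imp = clf.feature_importances_
        assert len(imp) == FeatureConfig().n_features(10)
        assert abs(sum(imp.values()) - 1.0) < 1e-6
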