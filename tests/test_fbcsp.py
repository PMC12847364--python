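"""Filter-bank and CSP correctness against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg as spl
from scipy import signal as sps
from scipy.optimize import minimize

from sibci.config import AnalysisConfig
from sibci.fbcsp import (
    BandEpochs,
    CSPError,
    FilterBankSpec,
    apply_filterbank,
    design_filterbank,
    extract_logvar_features,
    fit_csp_binary,
    fit_csp_multiclass,
    information_scores,
    joint_diagonalize,
)
from sibci.preprocess import EpochSet


def _trials_with_exact_cov(cov, n_trials, n_samples, rng):
    """Trials whose per-trial sample covariance equals ``cov`` exactly.

    Raw Gaussian noise is empirically whitened per trial, then colored by
    the matrix square root of the target covariance.
    """
    n_ch = cov.shape[0]
    left = spl.sqrtm(cov).real
    out = np.empty((n_trials, n_ch, n_samples))
    for t in range(n_trials):
        z = rng.standard_normal((n_ch, n_samples))
        emp = z @ z.T / n_samples
        out[t] = left @ np.linalg.inv(spl.sqrtm(emp).real) @ z
    return out


def _band_epochs(per_class_data, labels):
    data = np.concatenate(per_class_data)[None]  # single band
    return BandEpochs(
        data=data,
        bands=((8.0, 12.0),),
        fs=250.0,
        trials=pd.DataFrame({"task": labels}),
        window_s=(0.0, 4.0),
    )


class TestFilterDesign:
    def test_nine_palindromic_band_filters(self):
        coeffs = design_filterbank(FilterBankSpec(), fs=250.0)
        assert len(coeffs) == 9
        for taps in coeffs:
            np.testing.assert_allclose(taps, taps[::-1], atol=1e-15)

    def test_passband_tone_gain_near_unity(self):
        spec = FilterBankSpec(bands=((8.0, 12.0),))
        taps = design_filterbank(spec, fs=250.0)[0]
        t = np.arange(4000) / 250.0
        tone = np.sin(2 * np.pi * 10 * t)
        out = sps.fftconvolve(tone, taps, mode="same")[500:-500]
        assert abs(out.std() / (1 / np.sqrt(2)) - 1) < 0.05

    def test_stopband_attenuation(self):
        taps = design_filterbank(FilterBankSpec(bands=((8.0, 12.0),)), fs=250.0)[0]
        freqs, resp = sps.freqz(taps, worN=4096, fs=250.0)
        mag = 20 * np.log10(np.abs(resp) + 1e-12)
        inband = (freqs >= 9) & (freqs <= 11)
        stop = (freqs <= 6) | (freqs >= 14)
        assert mag[inband].min() >= -6
        assert mag[stop].max() <= -20

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_filterbank(FilterBankSpec(bands=((100.0, 140.0),)), fs=250.0)


class TestApplyFilterbank:
    def _epochs(self, data, fs=250.0):
        return EpochSet(
            data=data,
            fs=fs,
            window_s=(-0.5, 4.0),
            trials=pd.DataFrame({"task": ["L"] * len(data)}),
        )

    def test_zero_in_zero_out_and_window_arithmetic(self):
        ep = self._epochs(np.zeros((2, 3, 1125)))
        cfg = AnalysisConfig()
        coeffs = design_filterbank(FilterBankSpec(), 250.0)
        band = apply_filterbank(ep, coeffs, cfg.bands)
        assert band.data.shape == (9, 2, 3, 1000)  # 4.0 s x 250 Hz
        np.testing.assert_array_equal(band.data, 0.0)

    def test_band_variances_partition_broadband_power(self, rng):
        """Time-domain band variances match the frequency-response integral.

        Dual route: the variance of filtered white noise must equal the
        filter's equivalent noise bandwidth computed from the coefficients
        (Parseval), and the nine bands together must capture most — but,
        because of transition-band roll-off at 4-Hz bandwidths, not all —
        of the ideal 4-40 Hz power.
        """
        ep = self._epochs(rng.standard_normal((12, 2, 1125)))
        cfg = AnalysisConfig()
        coeffs = design_filterbank(FilterBankSpec(), 250.0)
        band = apply_filterbank(ep, coeffs, cfg.bands)
        band_vars = band.data.var(axis=(1, 2, 3))
        # frequency-domain oracle: var = integral of |H|^2 over [0, fs/2]
        expected = np.array(
            [np.mean(np.abs(sps.freqz(taps, worN=8192)[1]) ** 2) for taps in coeffs]
        )
        np.testing.assert_allclose(band_vars, expected, rtol=0.10)
        ideal = (40 - 4) / 125.0  # flat partition of white-noise power
        assert 0.6 * ideal < band_vars.sum() < 1.05 * ideal

    def test_epoch_shorter_than_filter_rejected(self):
        ep = self._epochs(np.zeros((1, 2, 100)))
        coeffs = design_filterbank(FilterBankSpec(), 250.0)
        with pytest.raises(ValueError, match="shorter"):
            apply_filterbank(ep, coeffs, AnalysisConfig().bands)


class TestBinaryCSP:
    def test_diagonal_covariance_closed_form(self, rng):
        """Sigma_1=diag(4,1), Sigma_2=diag(1,4): eigenvalues {0.8, 0.2}, axis filters."""
        d1 = _trials_with_exact_cov(np.diag([4.0, 1.0]), 6, 500, rng)
        d2 = _trials_with_exact_cov(np.diag([1.0, 4.0]), 6, 500, rng)
        band = _band_epochs([d1, d2], ["A"] * 6 + ["B"] * 6)
        model = fit_csp_binary(band, n_pairs=1)
        np.testing.assert_allclose(sorted(model.scores[0]), [0.2, 0.8], atol=1e-9)
        for w in model.filters[0]:
            direction = np.abs(w) / np.linalg.norm(w)
            np.testing.assert_allclose(sorted(direction), [0.0, 1.0], atol=1e-6)

    def test_equal_covariances_give_half_eigenvalues(self, rng):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        d1 = _trials_with_exact_cov(cov, 5, 400, rng)
        d2 = _trials_with_exact_cov(cov, 5, 400, rng)
        band = _band_epochs([d1, d2], ["A"] * 5 + ["B"] * 5)
        model = fit_csp_binary(band, n_pairs=1)
        np.testing.assert_allclose(model.scores[0], 0.5, atol=1e-9)

    def test_whitening_invariant_on_selected_filters(self, rng):
        covs = [np.cov(rng.standard_normal((4, 100))) for _ in range(2)]
        d1 = _trials_with_exact_cov(covs[0], 8, 600, rng)
        d2 = _trials_with_exact_cov(covs[1], 8, 600, rng)
        band = _band_epochs([d1, d2], ["A"] * 8 + ["B"] * 8)
        model = fit_csp_binary(band, n_pairs=2)
        w = model.filters[0]
        comp = (covs[0] / np.trace(covs[0])) + (covs[1] / np.trace(covs[1]))
        np.testing.assert_allclose(w @ comp @ w.T, np.eye(4), atol=1e-6)

    def test_scale_invariance_of_filter_directions(self, rng):
        d1 = _trials_with_exact_cov(np.diag([3.0, 1.0, 1.0]), 6, 500, rng)
        d2 = _trials_with_exact_cov(np.diag([1.0, 1.0, 3.0]), 6, 500, rng)
        labels = ["A"] * 6 + ["B"] * 6
        band = _band_epochs([d1, d2], labels)
        scaled = _band_epochs([7.5 * d1, 7.5 * d2], labels)
        w1 = fit_csp_binary(band, n_pairs=1).filters[0]
        w2 = fit_csp_binary(scaled, n_pairs=1).filters[0]
        for a, b in zip(w1, w2):
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos > 0.9999

    def test_matches_bruteforce_rayleigh_oracle(self, rng):
        """Top CSP filter vs direct maximization of the variance-ratio quotient."""
        q = spl.qr(rng.standard_normal((4, 4)))[0]
        c1 = q @ np.diag([5.0, 2.0, 1.0, 0.5]) @ q.T
        c2 = q @ np.diag([0.5, 1.5, 2.0, 3.0]) @ q.T
        d1 = _trials_with_exact_cov(c1, 6, 600, rng)
        d2 = _trials_with_exact_cov(c2, 6, 600, rng)
        band = _band_epochs([d1, d2], ["A"] * 6 + ["B"] * 6)
        model = fit_csp_binary(band, n_pairs=1)
        top = model.filters[0][0]

        s1, s2 = c1 / np.trace(c1), c2 / np.trace(c2)

        def neg_quotient(w):
            return -(w @ s1 @ w) / (w @ (s1 + s2) @ w)

        best, best_val = None, np.inf
        for start in rng.standard_normal((24, 4)):
            res = minimize(neg_quotient, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        angle = np.degrees(
            np.arccos(min(1.0, abs(top @ best) / (np.linalg.norm(top) * np.linalg.norm(best))))
        )
        assert angle < 2.0

    def test_rank_deficient_composite_suggests_loading(self, rng):
        x = rng.standard_normal((10, 4, 300))
        x[:, 3] = x[:, :3].sum(axis=1)  # exactly dependent channel
        x -= x.mean(axis=1, keepdims=True)  # average reference: rank 2 left
        band = _band_epochs([x[:5], x[5:]], ["A"] * 5 + ["B"] * 5)
        with pytest.raises(CSPError, match="loading"):
            fit_csp_binary(band, n_pairs=2)


class TestMulticlassCSP:
    def test_commuting_covariances_diagonalize_exactly(self, rng):
        q = spl.qr(rng.standard_normal((5, 5)))[0]
        mats = np.stack(
            [q @ np.diag(rng.uniform(0.5, 3.0, 5)) @ q.T for _ in range(4)]
        )
        rot, diag = joint_diagonalize(mats)
        off = sum(np.sum(d**2) - np.sum(np.diag(d) ** 2) for d in diag)
        assert off < 1e-8
        np.testing.assert_allclose(rot @ rot.T, np.eye(5), atol=1e-10)

    def test_equal_class_covariances_score_zero(self, rng):
        cov = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 1.5]])
        per_class = [_trials_with_exact_cov(cov, 4, 400, rng) for _ in range(3)]
        band = _band_epochs(per_class, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        model = fit_csp_multiclass(band, n_filters=3)
        np.testing.assert_allclose(model.scores, 0.0, atol=1e-9)

    def test_two_class_filters_span_binary_subspace(self, rng):
        c1 = np.diag([4.0, 1.0, 1.0, 1.0])
        c2 = np.diag([1.0, 1.0, 1.0, 4.0])
        d1 = _trials_with_exact_cov(c1, 8, 600, rng)
        d2 = _trials_with_exact_cov(c2, 8, 600, rng)
        band = _band_epochs([d1, d2], ["A"] * 8 + ["B"] * 8)
        wb = fit_csp_binary(band, n_pairs=1).filters[0]
        wm = fit_csp_multiclass(band, n_filters=2).filters[0]
        angles = np.degrees(spl.subspace_angles(wb.T, wm.T))
        assert angles.max() < 5.0

    def test_information_score_is_nonnegative_and_zero_iff_equal(self):
        priors = np.array([0.5, 0.5])
        equal = information_scores(np.array([[1.0, 2.0], [1.0, 2.0]]), priors)
        np.testing.assert_allclose(equal, 0.0, atol=1e-15)
        unequal = information_scores(np.array([[1.5, 2.0], [0.5, 2.0]]), priors)
        assert unequal[0] > 0 and abs(unequal[1]) < 1e-15


class TestLogVarFeatures:
    def test_default_dimensionality_is_90(self, tiny_epochs, fast_analysis):
        coeffs = design_filterbank(FilterBankSpec(), tiny_epochs.fs)
        band = apply_filterbank(tiny_epochs, coeffs, fast_analysis.bands)
        model = fit_csp_multiclass(band, n_filters=10)
        feats = extract_logvar_features(band, model)
        assert feats.X.shape == (tiny_epochs.n_trials, 90)
        assert np.all(np.isfinite(feats.X))
        assert list(feats.columns["band_idx"].unique()) == list(range(9))

    def test_amplitude_doubling_shifts_features_by_log4(self, rng):
        d = _trials_with_exact_cov(np.diag([2.0, 1.0, 1.0]), 4, 300, rng)
        band = _band_epochs([d, d], ["A"] * 4 + ["B"] * 4)
        model = fit_csp_binary(band, n_pairs=1)
        f1 = extract_logvar_features(band, model).X
        doubled = _band_epochs([2 * d, d], ["A"] * 4 + ["B"] * 4)
        f2 = extract_logvar_features(doubled, model).X
        np.testing.assert_allclose(f2[:4] - f1[:4], np.log(4.0), atol=1e-9)
        np.testing.assert_allclose(f2[4:], f1[4:], atol=1e-12)
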