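"""Filter-bank common spatial patterns (FBCSP) feature extraction.

Pipeline: decompose each epoch into nine 4-Hz bands (4-40 Hz) with
symmetric linear-phase FIR filters, fit CSP spatial filters per band
(generalized eigendecomposition for two classes, approximate joint
diagonalization with an information-based ranking for more), project, and
take the log-variance of each component over the 4-s imagery window.
Default dimensionality: 10 filters x 9 bands = 90 features per trial.

Binary CSP solves the generalized eigenproblem

    Sigma_1 w = lambda (Sigma_1 + Sigma_2) w

on trace-normalized class-mean covariances; eigenvalues lambda in (0, 1)
measure the fraction of (normalized) variance a component captures under
class 1, and the top/bottom ``n_pairs`` eigenvectors are kept.  Filters
are scaled so that w' (Sigma_1 + Sigma_2) w = 1.

Multiclass CSP whitens by the pooled covariance, then jointly
diagonalizes the whitened class-mean covariances with Jacobi rotations
(Cardoso-Souloumiac angle updates).  Filters are ranked by a Gaussian
mutual-information surrogate: score_j = -1/2 sum_c pi_c log(s_cj / s_j),
where s_cj is class c's variance in component j and s_j the pooled
variance; the score is zero iff the component's variance is
class-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import DEFAULT_BANDS
from .preprocess import EpochSet


class CSPError(RuntimeError):
    pass


@dataclass(frozen=True)
class FilterBankSpec:
    """Filter-bank design: ordered non-overlapping passbands + FIR order."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    numtaps: int = 251
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.numtaps % 2 != 1:
            raise ValueError("numtaps must be odd (type-I linear phase)")
        prev = 0.0
        for lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
            if lo < prev:
                raise ValueError("bands must be ascending, non-overlapping")
            prev = hi


def design_filterbank(spec: FilterBankSpec, fs: float) -> list[np.ndarray]:
    """Windowed-sinc bandpass coefficients, one symmetric vector per band."""
    coeffs = []
    for lo, hi in spec.bands:
        if hi >= fs / 2:
            raise ValueError(f"band ({lo}, {hi}) Hz exceeds Nyquist for fs={fs}")
        taps = sps.firwin(
            spec.numtaps, [lo, hi], pass_zero=False, window=spec.window, fs=fs
        )
        coeffs.append(taps)
    return coeffs


@dataclass
class BandEpochs:
    """Band-decomposed epochs: bands x trials x channels x samples."""

    data: np.ndarray
    bands: tuple[tuple[float, float], ...]
    fs: float
    trials: pd.DataFrame
    window_s: tuple[float, float]
    participant_id: str = "P01"

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.trials["task"].to_numpy()

    def select_trials(self, index) -> "BandEpochs":
        index = np.asarray(index)
        return BandEpochs(
            data=self.data[:, index],
            bands=self.bands,
            fs=self.fs,
            trials=self.trials.iloc[index].reset_index(drop=True),
            window_s=self.window_s,
            participant_id=self.participant_id,
        )


def apply_filterbank(
    epochs: EpochSet,
    coeffs: list[np.ndarray],
    bands: tuple[tuple[float, float], ...],
    analysis_window_s: tuple[float, float] = (0.0, 4.0),
) -> BandEpochs:
    """Filter every epoch through every band and crop to the analysis window.

    Group delay is compensated exactly (odd-length symmetric FIR), edges
    are reflect-padded, and the output is cropped to ``analysis_window_s``
    so the pre-onset segment serves only as edge padding.
    """
    numtaps = len(coeffs[0])
    if epochs.n_samples < numtaps:
        raise ValueError(
            f"epoch length {epochs.n_samples} shorter than filter length {numtaps}"
        )
    t0, _ = epochs.window_s
    a0, a1 = analysis_window_s
    start = int(round((a0 - t0) * epochs.fs))
    stop = int(round((a1 - t0) * epochs.fs))
    if not (0 <= start < stop <= epochs.n_samples):
        raise ValueError("analysis window outside the epoch window")

    half = numtaps // 2
    padded = np.pad(epochs.data, ((0, 0), (0, 0), (half, half)), mode="reflect")
    out = np.empty((len(coeffs), epochs.n_trials, epochs.n_channels, stop - start))
    for b, taps in enumerate(coeffs):
        filtered = sps.fftconvolve(padded, taps[None, None, :], mode="valid", axes=2)
        out[b] = filtered[:, :, start:stop]
    return BandEpochs(
        data=out,
        bands=tuple(bands),
        fs=epochs.fs,
        trials=epochs.trials.copy(),
        window_s=(a0, a1),
        participant_id=epochs.participant_id,
    )


# --------------------------------------------------------------------------
# Covariance estimation
# --------------------------------------------------------------------------

def _trial_covariances(x: np.ndarray, diag_loading: float) -> np.ndarray:
    """Trace-normalized sample covariance per trial; x: (trials, ch, samp)."""
    cov = np.einsum("tcs,tds->tcd", x, x)
    tr = np.trace(cov, axis1=1, axis2=2)
    cov = cov / tr[:, None, None]
    if diag_loading > 0:
        n_ch = x.shape[1]
        cov = cov + diag_loading / n_ch * np.eye(n_ch)
    return cov


def _class_mean_covs(
    x: np.ndarray, labels: np.ndarray, classes: list, diag_loading: float
) -> np.ndarray:
    covs = _trial_covariances(x, diag_loading)
    return np.stack([covs[labels == c].mean(axis=0) for c in classes])


def _subspace_whitener(cov: np.ndarray, rtol: float = 1e-10) -> tuple[np.ndarray, int]:
    """Whitening matrix restricted to the principal subspace of ``cov``.

    Returns (W, rank) with columns W[:, i] satisfying W' cov W = I_rank;
    eigenvalues below ``rtol`` times the largest are treated as null space
    (average-referenced EEG always has one).
    """
    lam, u = np.linalg.eigh(cov)
    keep = lam > rtol * lam[-1]
    rank = int(keep.sum())
    if rank == 0:
        raise CSPError("covariance matrix is zero")
    return u[:, keep] / np.sqrt(lam[keep]), rank


def _fix_signs(w: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude coefficient positive."""
    idx = np.argmax(np.abs(w), axis=1)
    signs = np.sign(w[np.arange(len(w)), idx])
    signs[signs == 0] = 1.0
    return w * signs[:, None]


@dataclass
class CSPModel:
    """Per-band spatial filters with per-filter scores."""

    filters: np.ndarray  # (n_bands, n_filters, n_channels)
    scores: np.ndarray  # (n_bands, n_filters)
    classes: list
    bands: tuple[tuple[float, float], ...]
    kind: str  # 'binary' | 'multiclass'

    @property
    def n_filters(self) -> int:
        return self.filters.shape[1]


def fit_csp_binary(
    band_epochs: BandEpochs,
    n_pairs: int = 5,
    diag_loading: float = 0.0,
) -> CSPModel:
    """Binary CSP per band: generalized eigendecomposition of (Sigma_1, Sigma_1+Sigma_2)."""
    labels = band_epochs.labels
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"binary CSP needs exactly 2 classes, got {classes}")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
    n_ch = band_epochs.data.shape[2]
    if 2 * n_pairs > n_ch:
        raise ValueError(f"2*n_pairs={2 * n_pairs} exceeds {n_ch} channels")

    filters, scores = [], []
    for b in range(band_epochs.n_bands):
        s1, s2 = _class_mean_covs(band_epochs.data[b], labels, classes, diag_loading)
        comp = s1 + s2
        # Solve the generalized eigenproblem on the range of the composite
        # covariance: average-referenced EEG is rank n_channels - 1 by
        # construction, so the null space is projected out rather than
        # inverted.  Only a rank too low for the requested filter count is
        # an error.
        whitener, rank = _subspace_whitener(comp)
        if rank < 2 * n_pairs:
            raise CSPError(
                f"composite covariance rank {rank} supports fewer than "
                f"{2 * n_pairs} filters; enable diagonal loading "
                "(diag_loading > 0) to regularize"
            )
        s1w = whitener.T @ s1 @ whitener
        lam, vec = np.linalg.eigh(s1w)  # ascending; (Wv)' comp (Wv) = I
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        keep = np.concatenate([np.arange(n_pairs), np.arange(rank - n_pairs, rank)])
        filters.append(_fix_signs((whitener @ vec[:, keep]).T))
        scores.append(lam[keep])
    return CSPModel(
        filters=np.stack(filters),
        scores=np.stack(scores),
        classes=classes,
        bands=band_epochs.bands,
        kind="binary",
    )


def _offdiag_energy(m: np.ndarray) -> float:
    return float(np.sum(m**2) - np.sum(m[:, np.arange(m.shape[1]), np.arange(m.shape[1])] ** 2))


def joint_diagonalize(
    mats: np.ndarray, tol: float = 1e-8, max_sweeps: int = 200, rel_tol: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal approximate joint diagonalization by Jacobi rotations.

    Minimizes the summed squared off-diagonal energy of a set of symmetric
    matrices; the rotation angle per (p, q) plane is the closed-form
    Cardoso-Souloumiac update.  Returns (rotation R, rotated matrices)
    with ``rotated[k] = R.T @ mats[k] @ R``.

    Convergence: either every rotation sine in a sweep falls below ``tol``
    (exactly diagonalizable sets reach this quadratically) or the
    objective's per-sweep decrease falls below ``rel_tol`` times the
    current off-diagonal energy — for sets with a genuine non-zero
    residual the objective has then plateaued and the remaining rotations
    are far below the estimation noise of any sample covariance.  Raises
    :class:`CSPError` if the sweep cap is hit first, reporting the
    residual off-diagonal energy.
    """
    m = np.array(mats, dtype=float, copy=True)
    n = m.shape[1]
    rot = np.eye(n)
    prev_off = _offdiag_energy(m)
    for _ in range(max_sweeps):
        biggest = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                h1 = m[:, p, p] - m[:, q, q]
                h2 = 2.0 * m[:, p, q]
                # 2x2 Gram matrix of the h-vectors; principal eigenvector
                # gives the optimal rotation (x, y) = (cos 2t, sin 2t)*r.
                g11, g12, g22 = h1 @ h1, h1 @ h2, h2 @ h2
                delta = np.hypot(g11 - g22, 2 * g12)
                x = (g11 - g22 + delta) / 2.0
                y = g12
                r = np.hypot(x, y)
                if r <= 0:
                    continue
                c = np.sqrt((x + r) / (2 * r))
                s = y / np.sqrt(2 * r * (x + r)) if (x + r) > 0 else 0.0
                if abs(s) <= tol:
                    continue
                biggest = max(biggest, abs(s))
                # Two-sided Givens update on every matrix.
                mp, mq = m[:, :, p].copy(), m[:, :, q].copy()
                m[:, :, p] = c * mp + s * mq
                m[:, :, q] = -s * mp + c * mq
                mp, mq = m[:, p, :].copy(), m[:, q, :].copy()
                m[:, p, :] = c * mp + s * mq
                m[:, q, :] = -s * mp + c * mq
                rp, rq = rot[:, p].copy(), rot[:, q].copy()
                rot[:, p] = c * rp + s * rq
                rot[:, q] = -s * rp + c * rq
        off = _offdiag_energy(m)
        if biggest <= tol or prev_off - off <= rel_tol * max(off, 1e-300):
            return rot, m
        prev_off = off
    off = _offdiag_energy(m)
    raise CSPError(
        f"joint diagonalization did not converge in {max_sweeps} sweeps; "
        f"residual off-diagonal energy {off:.3e}"
    )


def information_scores(diag_vars: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Gaussian information score per component from per-class variances.

    ``diag_vars``: (n_classes, n_components) projected variances.  Score_j
    = -1/2 * sum_c pi_c log(s_cj / s_j) with s_j the prior-weighted pooled
    variance; >= 0 by Jensen's inequality, 0 iff class-independent.
    """
    pooled = priors @ diag_vars
    ratio = diag_vars / pooled[None, :]
    return -0.5 * (priors @ np.log(ratio))


def fit_csp_multiclass(
    band_epochs: BandEpochs,
    n_filters: int = 10,
    diag_loading: float = 0.0,
    max_sweeps: int = 200,
) -> CSPModel:
    """Multiclass CSP per band: whiten, jointly diagonalize, rank by information.

    Ties in the information score break deterministically toward the lower
    component index.
    """
    labels = band_epochs.labels
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("multiclass CSP needs >= 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
    n_ch = band_epochs.data.shape[2]
    if n_filters > n_ch:
        raise ValueError(f"n_filters={n_filters} exceeds {n_ch} channels")
    priors = np.array([np.mean(labels == c) for c in classes])

    filters, scores = [], []
    for b in range(band_epochs.n_bands):
        covs = _class_mean_covs(band_epochs.data[b], labels, classes, diag_loading)
        pooled = np.tensordot(priors, covs, axes=1)
        whitener, rank = _subspace_whitener(pooled)
        if rank < n_filters:
            raise CSPError(
                f"pooled covariance rank {rank} supports fewer than "
                f"{n_filters} filters; enable diagonal loading"
            )
        white_covs = np.einsum("ij,kjl,lm->kim", whitener.T, covs, whitener)
        rot, diag = joint_diagonalize(white_covs, max_sweeps=max_sweeps)
        w_all = (whitener @ rot).T  # rows = spatial filters
        var_cj = np.stack([np.diag(diag[k]) for k in range(len(classes))])
        info = information_scores(var_cj, priors)
        # stable sort => ties keep ascending component index
        order = np.argsort(-info, kind="stable")[:n_filters]
        filters.append(_fix_signs(w_all[order]))
        scores.append(info[order])
    return CSPModel(
        filters=np.stack(filters),
        scores=np.stack(scores),
        classes=classes,
        bands=band_epochs.bands,
        kind="multiclass",
    )


def fit_csp(
    band_epochs: BandEpochs,
    n_pairs: int = 5,
    diag_loading: float = 0.0,
    force_multiclass: bool = False,
) -> CSPModel:
    """Dispatch: binary CSP for 2 classes unless forced multiclass."""
    n_classes = len(set(band_epochs.labels))
    if n_classes == 2 and not force_multiclass:
        return fit_csp_binary(band_epochs, n_pairs=n_pairs, diag_loading=diag_loading)
    return fit_csp_multiclass(
        band_epochs, n_filters=2 * n_pairs, diag_loading=diag_loading
    )


@dataclass
class TrialFeatureTable:
    """Trials x features log-variance matrix with per-column provenance."""

    X: np.ndarray  # (n_trials, n_features)
    columns: pd.DataFrame  # band_idx, filter_idx, band_lo, band_hi
    labels: np.ndarray
    participant_id: str = "P01"

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path) -> None:
        header = [
            f"b{int(r.band_idx)}f{int(r.filter_idx)}_{r.band_lo:g}-{r.band_hi:g}Hz"
            for r in self.columns.itertuples(index=False)
        ]
        df = pd.DataFrame(self.X, columns=header)
        df.insert(0, "task", self.labels)
        df.to_csv(path, sep="\t", index=False)


def extract_logvar_features(
    band_epochs: BandEpochs,
    model: CSPModel,
    normalized: bool = False,
    diag_loading: float = 0.0,
) -> TrialFeatureTable:
    """Log-variance of each CSP component, concatenated across bands.

    ``normalized=True`` uses each component's variance *fraction* within
    its band instead of the raw variance.
    """
    if model.bands != band_epochs.bands:
        raise ValueError("CSP model bands do not match the band epochs")
    n_trials = band_epochs.data.shape[1]
    feats, cols = [], []
    for b in range(band_epochs.n_bands):
        proj = np.einsum("fc,tcs->tfs", model.filters[b], band_epochs.data[b])
        var = proj.var(axis=2)
        if normalized:
            var = var / var.sum(axis=1, keepdims=True)
        if diag_loading > 0:
            var = var + diag_loading * var.mean()
        if np.any(var <= 0):
            raise CSPError(
                "zero-variance CSP projection; enable diagonal loading"
            )
        feats.append(np.log(var))
        lo, hi = band_epochs.bands[b]
        cols += [
            {"band_idx": b, "filter_idx": j, "band_lo": lo, "band_hi": hi}
            for j in range(model.n_filters)
        ]
    return TrialFeatureTable(
        X=np.concatenate(feats, axis=1),
        columns=pd.DataFrame(cols),
        labels=band_epochs.labels.copy(),
        participant_id=band_epochs.participant_id,
    )
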