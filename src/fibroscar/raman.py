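"""Raman spectral preprocessing and PLS-DA multiclass classification.

Spectra are conditioned with a conventional chemometrics chain —
despiking (median-filter residual z-score), asymmetric-least-squares
baseline removal, Savitzky-Golay smoothing, and per-spectrum vector
normalization — and classified into the four tissue types with partial
least squares discriminant analysis (PLS-DA): NIPALS PLS2 regression of
the spectra onto mean-centered one-hot class indicators, prediction by
argmax over the predicted indicator columns.

The first two latent variables (LV1, LV2) provide the standard score and
loading plots; each LV is sign-fixed so its largest-magnitude loading
element is positive.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, sparse
from scipy.sparse.linalg import spsolve

from .synthetic.raman import RamanSpectrumSet
from .tissue import CLASS_NAMES, CLASS_ORDER, TissueClass

# ------------------------------------------------------------ preprocessing


@dataclasses.dataclass(frozen=True)
class RamanPreprocessConfig:
    """Switchable steps of the spectral conditioning chain."""

    despike: bool = True
    despike_window: int = 7
    despike_z: float = 8.0
    baseline: bool = True
    baseline_lam: float = 1e5
    baseline_p: float = 0.01
    baseline_iterations: int = 10
    smooth: bool = True
    smooth_window: int = 9
    smooth_polyorder: int = 3
    normalize: bool = True


def despike_spectrum(y: np.ndarray, window: int = 7, z_thresh: float = 8.0) -> np.ndarray:
    """Replace single-channel cosmic-ray spikes by the local median.

    A channel is a spike when its residual against the running median
    exceeds ``z_thresh`` robust standard deviations.
    """
    y = np.asarray(y, dtype=float)
    med = signal.medfilt(y, kernel_size=window)
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale == 0:
        scale = resid.std() or 1.0
    out = y.copy()
    spikes = np.abs(resid) > z_thresh * scale
    out[spikes] = med[spikes]
    return out


def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                 n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate (iterative smoother).

    Minimizes Σ w_i (y_i − z_i)² + λ Σ (Δ²z)² with asymmetric weights
    w_i = p for points above the baseline, 1 − p below.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    D = sparse.diags([1, -2, 1], [0, -1, -2], shape=(n, n - 2), format="csc")
    penalty = lam * (D @ D.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w, format="csc")
        z = spsolve(W + penalty, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def vector_normalize(y: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm; all-zero spectra are rejected."""
    y = np.asarray(y, dtype=float)
    norm = np.linalg.norm(y)
    if norm == 0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return y / norm


def preprocess_spectra(raw: RamanSpectrumSet,
                       cfg: RamanPreprocessConfig | None = None) -> RamanSpectrumSet:
    """Run the conditioning chain: despike → baseline → smooth → normalize."""
    cfg = cfg or RamanPreprocessConfig()
    steps: list[str] = []
    X = raw.intensities.copy()
    if cfg.despike:
        X = np.array([despike_spectrum(x, cfg.despike_window, cfg.despike_z)
                      for x in X])
        steps.append("despike")
    if cfg.baseline:
        X = np.array([x - als_baseline(x, cfg.baseline_lam, cfg.baseline_p,
                                       cfg.baseline_iterations) for x in X])
        steps.append("baseline")
    if cfg.smooth:
        X = signal.savgol_filter(X, cfg.smooth_window, cfg.smooth_polyorder,
                                 axis=1)
        steps.append("smooth")
    if cfg.normalize:
        X = np.array([vector_normalize(x) for x in X])
        steps.append("normalize")
    return RamanSpectrumSet(axis=raw.axis.copy(), intensities=X,
                            labels=list(raw.labels),
                            preprocessing=raw.preprocessing + tuple(steps))


# ------------------------------------------------------------------ PLS-DA


def _one_hot(labels: Sequence[TissueClass]) -> np.ndarray:
    Y = np.zeros((len(labels), len(CLASS_ORDER)))
    for i, lab in enumerate(labels):
        Y[i, CLASS_ORDER.index(lab)] = 1.0
    return Y


class PLSDA:
    """PLS-DA model of a labelled spectrum set.

    Parameters
    ----------
    X : (n_spectra, n_channels) array
        Preprocessed spectra.
    labels : sequence of TissueClass
    n_components : int
        Number of latent variables k (default 4, one per class).
    axis : optional wavenumber axis carried through for loading plots.
    """

    def __init__(self, X: np.ndarray, labels: Sequence[TissueClass],
                 n_components: int = 4, axis: np.ndarray | None = None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.labels = list(labels)
        classes = {lab for lab in self.labels}
        if len(classes) < 2:
            raise ValueError("PLS-DA needs at least two classes")
        kmax = min(self.X.shape[0] - 1, self.X.shape[1])
        if not 1 <= n_components <= kmax:
            raise ValueError(f"n_components must be in [1, {kmax}]")
        self.n_components = n_components
        self.axis = None if axis is None else np.asarray(axis, dtype=float)

    @classmethod
    def from_spectrum_set(cls, sset: RamanSpectrumSet,
                          n_components: int = 4) -> "PLSDA":
        return cls(sset.intensities, sset.labels, n_components, axis=sset.axis)

    def fit(self, tol: float = 1e-13, max_iter: int = 3000) -> "PLSDAResults":
        """NIPALS PLS2 on mean-centered X and one-hot Y; returns Results."""
        X = self.X.copy()
        Y = _one_hot(self.labels)
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xc = X - x_mean
        Yc = Y - y_mean
        n, m = Xc.shape
        k = self.n_components
        W = np.zeros((m, k))
        P = np.zeros((m, k))
        Q = np.zeros((Y.shape[1], k))
        T = np.zeros((n, k))
        Xd, Yd = Xc.copy(), Yc.copy()
        x_residual_norms = []
        for a in range(k):
            u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
            w_old = None
            for _ in range(max_iter):
                w = Xd.T @ u
                w /= np.linalg.norm(w) or 1.0
                t = Xd @ w
                q = Yd.T @ t / (t @ t)
                u = Yd @ q / (q @ q)
                # w is unit-norm, so this is a scale-free convergence check
                if w_old is not None and np.linalg.norm(w - w_old) < tol:
                    break
                w_old = w
            p = Xd.T @ t / (t @ t)
            # sign convention: largest-|.| loading element positive
            if p[np.argmax(np.abs(p))] < 0:
                w, t, p, q = -w, -t, -p, -q
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, p, q, t
            Xd = Xd - np.outer(t, p)
            Yd = Yd - np.outer(t, q)
            x_residual_norms.append(float(np.linalg.norm(Xd)))
        B = W @ np.linalg.solve(P.T @ W, Q.T)
        return PLSDAResults(model=self, weights=W, x_loadings=P, y_loadings=Q,
                            scores=T, coefficients=B, x_mean=x_mean,
                            y_mean=y_mean,
                            x_residual_norms=np.asarray(x_residual_norms))


@dataclasses.dataclass
class PLSDAResults:
    """Fitted PLS-DA: weights, loadings, scores, regression coefficients."""

    model: PLSDA
    weights: np.ndarray        # (channels, k)
    x_loadings: np.ndarray     # (channels, k)
    y_loadings: np.ndarray     # (classes, k)
    scores: np.ndarray         # (spectra, k)
    coefficients: np.ndarray   # (channels, classes)
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_residual_norms: np.ndarray

    @property
    def class_order(self) -> tuple[str, ...]:
        return CLASS_NAMES

    def scores_loadings(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Training scores and X-loadings of ``LV1`` or ``LV2``."""
        idx = {"LV1": 0, "LV2": 1}.get(which.upper())
        if idx is None:
            raise ValueError("which must be 'LV1' or 'LV2'")
        if idx >= self.model.n_components:
            raise ValueError(f"model was fitted with fewer than {idx + 1} LVs")
        return self.scores[:, idx], self.x_loadings[:, idx]

    def predict_indicator(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError("channel count mismatch with training spectra")
        return (X - self.x_mean) @ self.coefficients + self.y_mean

    def predict(self, X: np.ndarray) -> list[TissueClass]:
        """Argmax over predicted class-indicator columns (ties → first
        class in canonical order)."""
        yhat = self.predict_indicator(X)
        return [CLASS_ORDER[int(np.argmax(row))] for row in yhat]

    def summary(self) -> str:
        n, k = self.scores.shape
        var0 = float(np.linalg.norm(self.model.X - self.model.X.mean(axis=0)))
        lines = [
            "PLS-DA (NIPALS PLS2 on one-hot class indicators)",
            "=" * 56,
            f"spectra: {n}   channels: {self.x_mean.size}   "
            f"latent variables: {k}",
            f"classes: {', '.join(self.class_order)}",
            "",
            "X residual Frobenius norm after each LV "
            f"(initial {var0:.4f}):",
        ]
        for a, r in enumerate(self.x_residual_norms, start=1):
            lines.append(f"  LV{a}: {r:.4f}")
        return "\n".join(lines)


def lv1_fingerprint_peaks(results: PLSDAResults,
                          fingerprint_max: float = 1800.0,
                          n_peaks: int = 2) -> np.ndarray:
    """Wavenumbers of the largest-magnitude local peaks of the LV1 loading
    within the fingerprint region, sorted ascending.

    The loading magnitude is scanned for local maxima below
    ``fingerprint_max`` cm⁻¹ and the ``n_peaks`` tallest are returned.
    """
    if results.model.axis is None:
        raise ValueError("model carries no wavenumber axis")
    axis = results.model.axis
    _, loading = results.scores_loadings("LV1")
    sel = axis <= fingerprint_max
    mag = np.abs(loading[sel])
    peaks, _ = signal.find_peaks(mag)
    if peaks.size < n_peaks:
        raise ValueError("fewer local peaks than requested")
    top = peaks[np.argsort(mag[peaks])[-n_peaks:]]
    return np.sort(axis[sel][top])


# ------------------------------------------------------------------ metrics


@dataclasses.dataclass
class MulticlassReport:
    """4x4 confusion matrix (rows = truth) and one-vs-rest rates."""

    confusion: np.ndarray
    class_order: tuple[str, ...] = CLASS_NAMES

    @property
    def sensitivity(self) -> np.ndarray:
        diag = np.diag(self.confusion).astype(float)
        truth = self.confusion.sum(axis=1)
        return np.divide(diag, truth, out=np.zeros_like(diag),
                         where=truth > 0)

    @property
    def specificity(self) -> np.ndarray:
        total = self.confusion.sum()
        out = np.zeros(len(self.class_order))
        for c in range(len(self.class_order)):
            fp = self.confusion[:, c].sum() - self.confusion[c, c]
            negatives = total - self.confusion[c].sum()
            out[c] = (negatives - fp) / negatives if negatives > 0 else 0.0
        return out

    @property
    def macro_sensitivity(self) -> float:
        return float(self.sensitivity.mean())

    @property
    def macro_specificity(self) -> float:
        return float(self.specificity.mean())

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
        }


def multiclass_metrics(predictions: Sequence[TissueClass],
                       truth: Sequence[TissueClass]) -> MulticlassReport:
    """Confusion matrix and per-class / macro sensitivity & specificity."""
    if len(predictions) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    k = len(CLASS_ORDER)
    conf = np.zeros((k, k), dtype=int)
    for p, t in zip(predictions, truth):
        if p not in CLASS_ORDER or t not in CLASS_ORDER:
            raise ValueError(f"unseen class label {p!r}/{t!r}")
        conf[CLASS_ORDER.index(t), CLASS_ORDER.index(p)] += 1
    return MulticlassReport(confusion=conf)


def loo_cross_validate(sset: RamanSpectrumSet,
                       n_components: int = 4) -> MulticlassReport:
    """Leave-one-out PLS-DA classification of a preprocessed spectrum set."""
    X = sset.intensities
    labels = sset.labels
    preds: list[TissueClass] = []
    for i in range(X.shape[0]):
        keep = np.arange(X.shape[0]) != i
        res = PLSDA(X[keep], [labels[j] for j in np.flatnonzero(keep)],
                    n_components).fit()
        preds.append(res.predict(X[i][None, :])[0])
    return multiclass_metrics(preds, labels)
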