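"""Spectral preprocessing, SNR estimation and multiclass classification.

Preprocessing is the standard fingerprint-region recipe: a 3rd-order
polynomial baseline is subtracted (least-squares fit over the whole axis)
and the residual is scaled to unit Euclidean norm.  The classifier is a
margin-based multiclass support vector machine (linear kernel by default)
wrapped as a scikit-learn estimator so it composes with sklearn model
selection; 5-fold stratified cross-validation and leave-one-patient-out
partitioning are provided on top.

Signal-to-noise ratio is the peak baseline-corrected intensity divided by
a robust noise standard deviation estimated from channel-to-channel first
differences (MAD-based, scaled by 1/sqrt(2) because differencing doubles
the noise variance).  It is used to flag spectra from tissue not in
contact with the cassette window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs, savgol_filter
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .library import CONTAMINANT_CLASSES, HEALTHY_CLASSES
from .phantom import Spectrum

#: Group labels used in confusion reporting (tumour vs everything else).
GROUP_OF: dict[str, str] = (
    {c: "healthy" for c in HEALTHY_CLASSES}
    | {c: "contaminants" for c in CONTAMINANT_CLASSES}
    | {"bcc": "bcc", "blood": "blood"}
)
GROUP_ORDER = ("healthy", "contaminants", "blood", "bcc")


def _baseline_matrix(wavenumbers: np.ndarray, order: int) -> np.ndarray:
    u = 2.0 * (wavenumbers - wavenumbers[0]) / (wavenumbers[-1] - wavenumbers[0]) - 1.0
    return np.vander(u, order + 1, increasing=True)


def _remove_baseline(X: np.ndarray, wavenumbers: np.ndarray, order: int) -> np.ndarray:
    B = _baseline_matrix(wavenumbers, order)
    coef, *_ = np.linalg.lstsq(B, X.T, rcond=None)
    return X - (B @ coef).T


def preprocess(raw: Spectrum, baseline_order: int = 3) -> Spectrum:
    """Baseline-subtract and vector-normalise one spectrum.

    Idempotent: a spectrum that is already baseline-free and unit-norm is
    returned unchanged (the least-squares polynomial fit of such a
    residual is zero).  Raises ``ValueError`` on an all-zero spectrum.
    """
    if raw.wavenumbers.size < 16:
        raise ValueError("spectrum too short to preprocess (need >= 16 points)")
    resid = _remove_baseline(
        raw.intensities[None, :], raw.wavenumbers, baseline_order
    )[0]
    norm = float(np.linalg.norm(resid))
    if norm == 0.0:
        raise ValueError("no signal: spectrum is constant/zero after baseline removal")
    return replace(raw, intensities=resid / norm)


#: Residual variance factor of the Savitzky-Golay high-pass below:
#: ||delta - c||_2 for the centre tap of the (11, 3) filter.
_SG_WINDOW, _SG_ORDER = 11, 3


def _sg_residual_factor() -> float:
    c = savgol_coeffs(_SG_WINDOW, _SG_ORDER)
    e = np.zeros(_SG_WINDOW)
    e[_SG_WINDOW // 2] = 1.0
    return float(np.sqrt(np.sum((e - c) ** 2)))


_SG_FACTOR = None  # computed lazily


def robust_noise_sd(intensities: np.ndarray, mask_window: int = 5) -> float:
    """Noise standard deviation of a spectrum, robust to band structure.

    A Savitzky-Golay smooth (window 11, order 3) tracks baselines and any
    other slowly varying structure exactly, so the high-pass residual
    ``x - savgol(x)`` contains only noise — except at the sparse, narrow
    Raman bands, which the local cubic cannot follow.  Channels near
    bands are masked out (moving-average magnitude above 4x a rough noise
    level or 5% of the structural peak), and the MAD of the remaining
    residuals, corrected for the filter's residual-variance factor, gives
    the noise sd.  Collapses to ~0 in the zero-noise limit.
    """
    global _SG_FACTOR
    x = np.asarray(intensities, float)
    if x.size < _SG_WINDOW + 2:
        d = np.diff(x)
        mad = np.median(np.abs(d - np.median(d))) if d.size else 0.0
        return float(1.4826 * mad / np.sqrt(2.0))
    if _SG_FACTOR is None:
        _SG_FACTOR = _sg_residual_factor()
    r = x - savgol_filter(x, _SG_WINDOW, _SG_ORDER)
    rough = 1.4826 * float(np.median(np.abs(r))) / _SG_FACTOR
    s = np.convolve(x - np.median(x), np.ones(mask_window) / mask_window, mode="same")
    s = s - np.median(s)
    thr = max(4.0 * rough / np.sqrt(mask_window), 0.05 * float(np.abs(s).max()))
    quiet = np.abs(s) <= thr
    rq = r[quiet] if quiet.sum() >= 16 else r
    return float(1.4826 * np.median(np.abs(rq - np.median(rq))) / _SG_FACTOR)


def snr(raw: Spectrum, baseline_order: int = 3) -> float:
    """Peak baseline-corrected intensity over robust noise sd.

    Returns 0 for a constant spectrum and ``inf`` in the zero-noise limit.
    """
    resid = _remove_baseline(
        raw.intensities[None, :], raw.wavenumbers, baseline_order
    )[0]
    # peak on a 3-channel moving average: a band is always several channels
    # wide, so this keeps the signal but suppresses single-channel noise
    # excursions that would otherwise dominate the max statistic
    smooth = np.convolve(resid, np.ones(3) / 3.0, mode="valid")
    peak = float(smooth.max())
    sigma = robust_noise_sd(resid)
    scale = float(np.max(np.abs(raw.intensities)))
    if peak <= max(1e-9, 1e-12 * max(scale, 1.0)):  # flat spectrum
        return 0.0
    if sigma == 0.0:
        return float("inf")
    return peak / sigma


class RamanClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass SVM on preprocessed Raman spectra.

    scikit-learn estimator: ``fit(X, y)`` takes raw intensity rows (shared
    wavenumber axis) and class-name labels; preprocessing (polynomial
    baseline removal + unit-norm) is part of the model so train and test
    spectra are always treated identically.

    Parameters
    ----------
    wavenumbers : array or None
        Shared axis; channel indices are used if omitted (the baseline
        fit only needs relative positions).
    kernel, C : SVM kernel and regularisation, linear/1.0 by default.
    baseline_order : polynomial order of the baseline, default 3.
    random_state : seed forwarded to the SVM (tie-breaking only; fitting
        a linear SVM on fixed data is deterministic).
    """

    def __init__(
        self,
        wavenumbers=None,
        kernel: str = "linear",
        C: float = 1.0,
        baseline_order: int = 3,
        random_state: int = 0,
    ):
        self.wavenumbers = wavenumbers
        self.kernel = kernel
        self.C = C
        self.baseline_order = baseline_order
        self.random_state = random_state

    def _axis(self, n_features: int) -> np.ndarray:
        if self.wavenumbers is None:
            return np.arange(n_features, dtype=float)
        wn = np.asarray(self.wavenumbers, float)
        if wn.size != n_features:
            raise ValueError("wavenumbers length does not match X columns")
        return wn

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_spectra, n_channels)")
        resid = _remove_baseline(X, self._axis(X.shape[1]), self.baseline_order)
        norms = np.linalg.norm(resid, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return resid / norms

    def fit(self, X, y):
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes to train")
        self._svm = SVC(
            kernel=self.kernel,
            C=self.C,
            decision_function_shape="ovr",
            random_state=self.random_state,
        )
        self._svm.fit(self._transform(X), y)
        self.classes_ = self._svm.classes_
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self._svm.predict(self._transform(X))

    def decision_function(self, X):
        check_is_fitted(self, "classes_")
        return self._svm.decision_function(self._transform(X))

    def predict_margin(self, X) -> np.ndarray:
        """Confidence of the winning class: its one-vs-rest decision value.

        Because spectra are unit-normalised, added noise dilutes the
        template component and this score shrinks as acquisition time
        drops — unlike the top-minus-second gap, which order-statistic
        spreading inflates under mild noise.
        """
        d = self.decision_function(X)
        if d.ndim == 1:  # binary
            return np.abs(d)
        return d.max(axis=1)

    def predict_spectrum(self, spectrum: Spectrum) -> str:
        return str(self.predict(spectrum.intensities[None, :])[0])


@dataclass
class ConfusionReport:
    """Aggregated held-out confusion with BCC-vs-rest summary metrics."""

    class_matrix: pd.DataFrame  # counts, true class x predicted class
    group_matrix: pd.DataFrame  # counts, true group x predicted group
    sensitivity: float  # % of BCC spectra detected as BCC
    specificity: float  # % of non-BCC spectra not called BCC

    @property
    def accuracy(self) -> float:
        m = self.class_matrix.to_numpy()
        return float(np.trace(m) / m.sum() * 100.0)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionReport:
    classes = sorted(set(y_true))
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        if p not in cm.columns:
            cm[p] = 0
        cm.loc[t, p] += 1
    groups = [g for g in GROUP_ORDER if any(GROUP_OF.get(c) == g for c in classes)]
    gm = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for t, p in zip(y_true, y_pred):
        gt, gp = GROUP_OF.get(t, t), GROUP_OF.get(p, p)
        if gt not in gm.index:
            gm.loc[gt] = 0
        if gp not in gm.columns:
            gm[gp] = 0
        gm.loc[gt, gp] += 1
    is_bcc_t = y_true == "bcc"
    is_bcc_p = y_pred == "bcc"
    tp = int(np.sum(is_bcc_t & is_bcc_p))
    fn = int(np.sum(is_bcc_t & ~is_bcc_p))
    tn = int(np.sum(~is_bcc_t & ~is_bcc_p))
    fp = int(np.sum(~is_bcc_t & is_bcc_p))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionReport(cm, gm, sens, spec)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    wavenumbers: np.ndarray | None = None,
    required_classes: tuple[str, ...] | None = None,
    min_per_class: int = 20,
    **params,
) -> RamanClassifier:
    """Fit a :class:`RamanClassifier`, validating the training design.

    Requires at least two classes and ``min_per_class`` spectra per class;
    if ``required_classes`` is given, every listed class must be present
    (missing ones are reported by name).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if required_classes is not None:
        missing = sorted(set(required_classes) - set(classes))
        if missing:
            raise ValueError(f"missing training classes: {', '.join(missing)}")
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    thin = [f"{c} ({n})" for c, n in zip(classes, counts) if n < min_per_class]
    if thin:
        raise ValueError(
            f"need >= {min_per_class} spectra per class; too few: {', '.join(thin)}"
        )
    return RamanClassifier(wavenumbers=wavenumbers, **params).fit(X, y)


def cross_validate_5fold(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    wavenumbers: np.ndarray | None = None,
    n_folds: int = 5,
    **params,
) -> ConfusionReport:
    """Stratified k-fold CV; confusion aggregated over held-out folds."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("cross-validation needs at least 2 classes")
    if counts.min() < n_folds:
        bad = ", ".join(c for c, n in zip(classes, counts) if n < n_folds)
        raise ValueError(f"cannot stratify {n_folds} folds: too few spectra in {bad}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        model = RamanClassifier(wavenumbers=wavenumbers, **params).fit(
            np.asarray(X)[train_idx], y[train_idx]
        )
        y_pred[test_idx] = model.predict(np.asarray(X)[test_idx])
    return _confusion(y, y_pred)


def lopo_partition(patient_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-patient-out index partitions.

    One (train_idx, test_idx) pair per distinct patient; the held-out
    patient's spectra never appear in its training set and the held-out
    sets cover every spectrum exactly once.
    """
    pid = np.asarray(patient_ids)
    patients = sorted(set(pid.tolist()))
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    out = []
    idx = np.arange(pid.size)
    for p in patients:
        held = pid == p
        out.append((idx[~held], idx[held]))
    return out
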