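"""Spectral pretreatments: SNV, Savitzky-Golay derivatives, mean centering,
and wavenumber-region selection.

Each step is a scikit-learn transformer operating on an n × p intensity
matrix, so plans compose as ordinary :class:`sklearn.pipeline.Pipeline`
objects.  Statistics estimated during fitting (mean-center column means) are
frozen and reapplied unchanged to test data — no test-set leakage.

Conventions: standard deviations use the n−1 (sample) denominator;
Savitzky-Golay derivatives are taken with respect to pixel index (the
commercial-chemometrics convention), polynomial order 2 by default, with
full-window polynomial extrapolation at the edges so the point count p never
changes; region bounds are closed intervals in cm⁻¹.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum has zero variance and cannot be SNV-scaled."""


# ---------------------------------------------------------------- functions


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: scale each spectrum to mean 0, sample sd 1.

    Accepts a single spectrum (1-d) or a matrix (rows are spectra).  Corrects
    multiplicative scatter between fruit surfaces.
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] < 2:
        raise DegenerateSpectrumError("SNV needs at least 2 points per spectrum")
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSpectrumError("zero-variance spectrum cannot be SNV-scaled")
    out = (X - X.mean(axis=1, keepdims=True)) / sd
    return out[0] if one_d else out


def savitzky_golay(
    x: np.ndarray, window: int = 15, poly_order: int = 2, deriv: int = 2
) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative along the spectral axis.

    Local least-squares polynomial of ``poly_order`` over an odd ``window``,
    differentiated ``deriv`` times with respect to pixel index.
    """
    x = np.asarray(x, dtype=float)
    p = x.shape[-1]
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= poly_order:
        raise ValueError("window must exceed polynomial order")
    if deriv > poly_order:
        raise ValueError("derivative order cannot exceed polynomial order")
    if window > p:
        raise ValueError(f"window {window} exceeds spectrum length {p}")
    return savgol_filter(x, window, poly_order, deriv=deriv, delta=1.0, axis=-1, mode="interp")


def mean_center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract column (per-wavenumber) means; returns (centered X, means)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    means = X.mean(axis=0)
    return X - means, means


def select_region(axis: np.ndarray, X: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Keep axis points with lo ≤ w ≤ hi (closed interval), order preserved."""
    if lo > hi:
        raise ValueError("region lower bound must not exceed upper bound")
    axis = np.asarray(axis, dtype=float)
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError(f"no axis points inside [{lo}, {hi}] cm-1")
    return axis[mask], np.atleast_2d(np.asarray(X, dtype=float))[:, mask]


# -------------------------------------------------------------- transformers


class SNVScaler(TransformerMixin, BaseEstimator):
    """Row-wise standard normal variate (stateless)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return snv(X)


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Savitzky-Golay filter step (stateless).

    Parameters
    ----------
    window : odd filter length in points (15 for regression pretreatment,
        25 for classification pretreatment in the default plans).
    poly_order : local polynomial order, default 2.
    deriv : derivative order, default 2 (removes slowly varying baseline).
    """

    def __init__(self, window: int = 15, poly_order: int = 2, deriv: int = 2):
        self.window = window
        self.poly_order = poly_order
        self.deriv = deriv

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return savitzky_golay(X, self.window, self.poly_order, self.deriv)


class MeanCenterer(TransformerMixin, BaseEstimator):
    """Column mean centering with frozen training means (``means_``)."""

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 1:
            raise ValueError("mean centering needs at least one row")
        self.means_ = X.mean(axis=0)
        return self

    def transform(self, X):
        if not hasattr(self, "means_"):
            raise RuntimeError("MeanCenterer must be fitted before transform")
        return np.atleast_2d(np.asarray(X, dtype=float)) - self.means_

    def inverse_transform(self, X):
        return np.atleast_2d(np.asarray(X, dtype=float)) + self.means_


class RegionSelector(TransformerMixin, BaseEstimator):
    """Restrict spectra to a closed wavenumber interval [lo, hi] cm⁻¹.

    Needs the shared wavenumber ``axis`` of the incoming matrix.  The
    selected sub-axis is exposed as ``axis_`` after fitting.
    """

    def __init__(self, lo: float = 1370.0, hi: float = 1700.0, axis=None):
        self.lo = lo
        self.hi = hi
        self.axis = axis

    def fit(self, X, y=None):
        if self.axis is None:
            raise ValueError("RegionSelector requires the wavenumber axis")
        axis = np.asarray(self.axis, dtype=float)
        self.mask_ = (axis >= self.lo) & (axis <= self.hi)
        if not self.mask_.any():
            raise ValueError(f"no axis points inside [{self.lo}, {self.hi}] cm-1")
        self.axis_ = axis[self.mask_]
        return self

    def transform(self, X):
        if not hasattr(self, "mask_"):
            raise RuntimeError("RegionSelector must be fitted before transform")
        return np.atleast_2d(np.asarray(X, dtype=float))[:, self.mask_]


_STEP_CLASSES = {
    "snv": SNVScaler,
    "sg": SavitzkyGolay,
    "region": RegionSelector,
    "mean_center": MeanCenterer,
}


def make_plan(steps: list[tuple[str, dict]], axis=None) -> Pipeline:
    """Build a preprocessing Pipeline from (step name, params) pairs.

    Step names: ``snv``, ``sg`` (window/poly_order/deriv), ``region``
    (lo/hi; the shared ``axis`` argument is injected), ``mean_center``.
    """
    objs = []
    for name, params in steps:
        if name not in _STEP_CLASSES:
            raise ValueError(f"unknown preprocessing step {name!r}")
        params = dict(params)
        if name == "region" and "axis" not in params:
            params["axis"] = axis
        objs.append((name, _STEP_CLASSES[name](**params)))
    return Pipeline(objs)


def plan_config(plan: Pipeline) -> list[tuple[str, dict]]:
    """Serializable (name, params) description of a plan, for model bundles."""
    out = []
    for name, step in plan.steps:
        params = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in step.get_params().items()
        }
        out.append((name, params))
    return out


def classification_plan(axis: np.ndarray, lo: float = 1370.0, hi: float = 1700.0) -> Pipeline:
    """Default classification pretreatment: SNV → SG(25, 2, d2) → region → center."""
    return make_plan(
        [
            ("snv", {}),
            ("sg", {"window": 25, "poly_order": 2, "deriv": 2}),
            ("region", {"lo": lo, "hi": hi}),
            ("mean_center", {}),
        ],
        axis=axis,
    )


def regression_plan() -> Pipeline:
    """Default calibration pretreatment: SG(15, 2, d2) with smoothing → center."""
    return make_plan(
        [
            ("sg", {"window": 15, "poly_order": 2, "deriv": 2}),
            ("mean_center", {}),
        ]
    )
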