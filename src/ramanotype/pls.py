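"""PLS1 regression (NIPALS) with leave-one-out latent-variable selection.

Calibrates a single response (pigment concentration, mg/100 g) against the
preprocessed spectral block by extracting orthogonal latent variables that
maximize covariance with the response.  Model quality is reported the way
calibration chemists do: r_cv / SECV under leave-one-out cross-validation
of the calibration set, r_pred / SEP on an external validation set.  SECV
and SEP use the divisor-n root-mean-square convention (no bias correction);
a bias-corrected variant is available via ``metrics(..., corrected=True)``.

The number of latent variables is the global SECV minimum over 1..max_a,
ties resolved toward the smaller (more parsimonious) model.  Any fitted
preprocessing (mean centering) is re-estimated inside every cross-validation
fold, so no held-out information leaks into the calibration statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted


def metrics(y: np.ndarray, y_hat: np.ndarray, corrected: bool = False) -> tuple[float, float]:
    """Pearson correlation and root-mean-square error of predictions.

    ``corrected=True`` divides the squared-error sum by n − 1 instead of n.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size or y.size < 2:
        raise ValueError("metrics need two equal-length vectors of length >= 2")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(y, y_hat)[0, 1])
    denom = y.size - 1 if corrected else y.size
    se = float(np.sqrt(np.sum((y - y_hat) ** 2) / denom))
    return r, se


class PLS1Regression(RegressorMixin, BaseEstimator):
    """NIPALS PLS1 for one response.

    Parameters
    ----------
    n_components : number of latent variables a ≥ 1.

    Attributes
    ----------
    W_ : p × a weight matrix (unit-norm columns, computed on deflated X).
    P_ : p × a X-loading matrix.
    q_ : inner regression coefficients, length a.
    b_ : p-vector regression coefficients in centered space, equal to
        W (PᵀW)⁻¹ q.
    x_mean_, y_mean_ : centering state applied at prediction time.
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        a = int(self.n_components)
        if y.size != n:
            raise ValueError("X and y length mismatch")
        if a < 1 or a > min(n - 1, p):
            raise ValueError(f"n_components={a} must be in 1..min(n-1, p)={min(n - 1, p)}")
        if np.var(y) == 0:
            raise ValueError("response has zero variance")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xd = X - self.x_mean_
        yd = y - self.y_mean_

        W = np.zeros((p, a))
        P = np.zeros((p, a))
        q = np.zeros(a)
        T = np.zeros((n, a))
        for i in range(a):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(f"X exhausted after {i} latent variables")
            w /= norm
            t = Xd @ w
            tt = t @ t
            p_vec = Xd.T @ t / tt
            q_i = yd @ t / tt
            Xd = Xd - np.outer(t, p_vec)
            yd = yd - q_i * t
            W[:, i], P[:, i], q[i], T[:, i] = w, p_vec, q_i, t

        self.W_, self.P_, self.q_, self.T_ = W, P, q, T
        self.b_ = W @ np.linalg.solve(P.T @ W, q)
        return self

    def predict(self, X):
        check_is_fitted(self, "b_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.b_.size:
            raise ValueError("wrong number of spectral variables")
        return (X - self.x_mean_) @ self.b_ + self.y_mean_


@dataclass
class CvReport:
    """Leave-one-out report: per-a r_cv and SECV (mg/100 g), chosen a,
    and the per-sample LOO residuals at the chosen a."""

    r_cv: np.ndarray
    secv: np.ndarray
    n_components: int
    residuals: np.ndarray = field(default=None)

    @property
    def r_cv_best(self) -> float:
        return float(self.r_cv[self.n_components - 1])

    @property
    def secv_best(self) -> float:
        return float(self.secv[self.n_components - 1])


def loo_cv(X, y, max_components: int = 10, preprocess=None) -> CvReport:
    """Leave-one-out cross-validation over 1..max_components latent variables.

    Each held-out sample is predicted by a PLS1 model (and a clone of the
    ``preprocess`` transformer, when given) fitted on the other n − 1
    samples.  SECV(a) = sqrt(Σe²/n); the chosen a is the global SECV
    minimum with smaller-a tie-break.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    max_a = int(max_components)
    if max_a > min(n - 2, X.shape[1]):
        raise ValueError(f"max_components={max_a} too large for n={n}, p={X.shape[1]}")

    pred = np.zeros((n, max_a))
    for i in range(n):
        keep = np.arange(n) != i
        X_tr, y_tr = X[keep], y[keep]
        x_te = X[i : i + 1]
        if preprocess is not None:
            plan = clone(preprocess)
            X_tr = plan.fit_transform(X_tr)
            x_te = plan.transform(x_te)
        for a in range(1, max_a + 1):
            model = PLS1Regression(n_components=a).fit(X_tr, y_tr)
            pred[i, a - 1] = model.predict(x_te)[0]

    secv = np.sqrt(np.mean((pred - y[:, None]) ** 2, axis=0))
    r_cv = np.array([np.corrcoef(y, pred[:, a])[0, 1] for a in range(max_a)])
    chosen = int(np.argmin(secv)) + 1  # argmin yields the smallest a on ties
    return CvReport(r_cv=r_cv, secv=secv, n_components=chosen,
                    residuals=y - pred[:, chosen - 1])


def residual_outliers(model: PLS1Regression, X, y, threshold_sd: float = 3.0) -> np.ndarray:
    """Flag calibration samples with |standardized residual| > threshold.

    Residuals are standardized by their sample standard deviation; a
    perfectly fitted set (zero residual spread) flags nothing.
    """
    y = np.asarray(y, dtype=float).ravel()
    resid = y - model.predict(X)
    sd = resid.std(ddof=1)
    if sd == 0:
        return np.zeros(y.size, dtype=bool)
    return np.abs(resid / sd) > threshold_sd


def fit_pls1(X, y, n_components: int) -> PLS1Regression:
    """Functional wrapper over :class:`PLS1Regression`."""
    return PLS1Regression(n_components=n_components).fit(X, y)
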