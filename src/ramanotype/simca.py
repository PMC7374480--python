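"""Soft independent modelling of class analogy (SIMCA).

Each class is described by its own principal-component model fitted to the
preprocessed training spectra of that class alone.  A new spectrum is
*admitted* to every class whose residual variance ratio passes an F-test,
and assigned to the nearest admitted class (smallest F-ratio); a spectrum
may match one class, several, or none.  Class separation is summarized by
the interclass distance (ICD) built from cross-fitted residual standard
deviations (ICD > 3 conventionally indicates well-separated classes) and by
the per-wavenumber discriminating power that localizes which bands drive a
separation — for carotenoid profiling this lands on the ν1 C=C stretch
region near 1520 cm⁻¹.

Conventions (the commercial implementations leave these unpublished):
  * s0² = Σ‖residual‖² / ((n_c − k − 1)(p − k)) on the training class;
  * F-test dof = (p − k) and (p − k)(n_c − k − 1), default alpha 0.05;
  * ICD(a,b) = sqrt((s_ab² + s_ba²) / (s_aa² + s_bb²)) − 1 with the pooled
    cross-fit variances s_xy² = Σ‖residual of class x on model y‖²
    / (n_x (p − k_y)); the “− 1” pins the self-distance at exactly 0;
  * per-class PC count chosen by leave-one-out cross-validated residual
    error, capped at min(n_c − 2, 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class SimcaClassModel:
    """Per-class PCA submodel: mean, orthonormal loadings, residual scale.

    ``effective_dof``, when set, replaces the nominal residual dimension
    p − k in the admission F-test: smoothing filters correlate neighbouring
    wavenumbers, so the residual has far fewer independent dimensions than
    pixels, and the nominal dof would make the F-test reject genuine class
    members en masse.
    """

    label: str
    mean: np.ndarray          # length p
    loadings: np.ndarray      # p × k, orthonormal columns
    k: int
    s0: float                 # pooled training residual sd
    score_var: np.ndarray     # per-PC score variance, length k
    n_train: int
    effective_dof: float | None = None

    @property
    def p(self) -> int:
        return self.mean.size

    def residuals(self, X: np.ndarray) -> np.ndarray:
        """Orthogonal-complement residual matrix of X under this model."""
        Xc = np.atleast_2d(X) - self.mean
        if self.k == 0:
            return Xc
        return Xc - (Xc @ self.loadings) @ self.loadings.T

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xc = np.atleast_2d(X) - self.mean
        if self.k == 0:
            return np.zeros((Xc.shape[0], 0))
        return Xc @ self.loadings


def fit_class_model(X_class: np.ndarray, k: int, label: str = "") -> SimcaClassModel:
    """Fit the k-component PCA submodel of one class.

    Loadings are the top-k right singular vectors of the class-centered
    matrix; s0² pools the residual sum of squares over the training rows
    with (n_c − k − 1)(p − k) degrees of freedom.
    """
    X_class = np.atleast_2d(np.asarray(X_class, dtype=float))
    n_c, p = X_class.shape
    if n_c < 2:
        raise ValueError("a class model needs at least 2 training samples")
    if k > min(n_c - 2, p - 1):
        raise ValueError(f"k={k} too large for class of {n_c} samples, {p} variables")
    mean = X_class.mean(axis=0)
    Xc = X_class - mean
    if not np.any(Xc):
        raise ValueError("degenerate (constant) class")
    if k > 0:
        _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = Vt[:k].T
        score_var = sv[:k] ** 2 / (n_c - 1)
    else:
        loadings = np.zeros((p, 0))
        score_var = np.zeros(0)
    resid = Xc - (Xc @ loadings) @ loadings.T
    dof = (n_c - k - 1) * (p - k)
    s0 = float(np.sqrt(np.sum(resid**2) / dof))
    return SimcaClassModel(
        label=label, mean=mean, loadings=loadings, k=k, s0=s0,
        score_var=score_var, n_train=n_c,
    )


def loo_press(
    X_class: np.ndarray, max_components: int = 10, per_sample: bool = False
) -> np.ndarray:
    """Leave-one-out PCA residual sum of squares for k = 0..cap.

    For each held-out sample the squared residual to the model fitted on the
    remaining rows is accumulated; entry k of the returned array is the total
    held-out RSS of the k-component class model.  Cap is
    min(n_c − 2, max_components, p − 1).  With ``per_sample`` the full
    n_c × (cap + 1) RSS matrix is returned instead of its column sums.
    """
    X_class = np.atleast_2d(np.asarray(X_class, dtype=float))
    n_c, p = X_class.shape
    cap = max(0, min(n_c - 2, max_components, p - 1))
    rss = np.zeros((n_c, cap + 1))
    for i in range(n_c):
        rest = np.delete(X_class, i, axis=0)
        mean = rest.mean(axis=0)
        _, _, Vt = np.linalg.svd(rest - mean, full_matrices=False)
        resid = X_class[i] - mean
        rss[i, 0] = resid @ resid
        for k in range(1, cap + 1):
            if k <= Vt.shape[0]:
                v = Vt[k - 1]
                resid = resid - (resid @ v) * v
            rss[i, k] = resid @ resid
    return rss if per_sample else rss.sum(axis=0)


def select_n_components(
    X_class: np.ndarray, max_components: int = 10, min_improvement: float = 0.05,
    press: np.ndarray | None = None,
) -> int:
    """Pick k by leave-one-out cross-validated residual variance.

    The per-dimension residual variance PRESS(k)/(p − k) is compared across
    k (raw PRESS decreases monotonically because every extra component
    absorbs part of the held-out vector, noise or not, so it must be
    normalized by the shrinking residual space).  Components are accepted
    greedily while they improve the normalized criterion by at least
    ``min_improvement`` (5%); noise components hover near flat and are
    rejected, keeping the model parsimonious.
    """
    X_class = np.atleast_2d(np.asarray(X_class, dtype=float))
    n_c, p = X_class.shape
    if n_c < 3:
        return 0
    if press is None:
        press = loo_press(X_class, max_components)
    cap = press.size - 1
    if cap == 0:
        return 0
    normalized = press / (p - np.arange(cap + 1))
    k = 0
    while k < cap and normalized[k + 1] < (1.0 - min_improvement) * normalized[k]:
        k += 1
    return k


def sample_distance(model: SimcaClassModel, x: np.ndarray) -> tuple[float, float]:
    """Residual sd s_i and F-ratio s_i²/s0² of one spectrum vs a class model."""
    x = np.asarray(x, dtype=float)
    if x.size != model.p:
        raise ValueError(f"spectrum length {x.size} != model dimension {model.p}")
    resid = model.residuals(x[None, :])[0]
    s_i2 = float(resid @ resid) / (model.p - model.k)
    f_ratio = s_i2 / model.s0**2 if model.s0 > 0 else np.inf * (s_i2 > 0)
    return float(np.sqrt(s_i2)), float(f_ratio)


def _pooled_cross_variance(X: np.ndarray, model: SimcaClassModel) -> float:
    """s_xy²: pooled residual variance of rows of X under ``model``."""
    resid = model.residuals(X)
    return float(np.sum(resid**2) / (X.shape[0] * (model.p - model.k)))


def interclass_distance(
    model_a: SimcaClassModel, model_b: SimcaClassModel,
    X_a: np.ndarray, X_b: np.ndarray,
) -> float:
    """ICD from cross-fitted residual sds; 0 for identical model/data pairs."""
    if model_a.p != model_b.p:
        raise ValueError("class models live on different axes")
    s_aa = _pooled_cross_variance(X_a, model_a)
    s_bb = _pooled_cross_variance(X_b, model_b)
    s_ab = _pooled_cross_variance(X_a, model_b)
    s_ba = _pooled_cross_variance(X_b, model_a)
    return float(np.sqrt((s_ab + s_ba) / (s_aa + s_bb)) - 1.0)


def discriminating_power(
    model_a: SimcaClassModel, model_b: SimcaClassModel,
    X_a: np.ndarray, X_b: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Per-wavenumber separation strength between two classes.

    DP_j = sqrt((s_ab,j² + s_ba,j²) / (s_aa,j² + s_bb,j²)), with residual
    variances restricted to variable j; ≈ 1 where the classes agree, large
    at the diagnostic bands.  The denominator is floored at ``eps``.
    """
    r_aa = np.mean(model_a.residuals(X_a) ** 2, axis=0)
    r_bb = np.mean(model_b.residuals(X_b) ** 2, axis=0)
    r_ab = np.mean(model_b.residuals(X_a) ** 2, axis=0)
    r_ba = np.mean(model_a.residuals(X_b) ** 2, axis=0)
    return np.sqrt((r_ab + r_ba) / np.maximum(r_aa + r_bb, eps))


def mahalanobis_outliers(
    model: SimcaClassModel, X_class: np.ndarray,
    score_quantile: float = 0.99, alpha: float = 0.05,
) -> dict[str, np.ndarray]:
    """Score-space Mahalanobis distance + residual F-ratio outlier flags.

    A sample is flagged when its score Mahalanobis distance exceeds
    sqrt(chi²(score_quantile; k)) or its residual F-ratio exceeds the
    F-critical value.  With k = 0 only the residual criterion applies.
    """
    X_class = np.atleast_2d(np.asarray(X_class, dtype=float))
    t = model.scores(X_class)
    if model.k > 0:
        d2 = np.sum(t**2 / np.maximum(model.score_var, 1e-30), axis=1)
        md = np.sqrt(d2)
        md_cut = float(np.sqrt(stats.chi2.ppf(score_quantile, df=model.k)))
        md_flag = md > md_cut
    else:
        md = np.zeros(X_class.shape[0])
        md_flag = np.zeros(X_class.shape[0], dtype=bool)
    resid = model.residuals(X_class)
    s_i2 = np.sum(resid**2, axis=1) / (model.p - model.k)
    f_ratio = s_i2 / model.s0**2 if model.s0 > 0 else np.where(s_i2 > 0, np.inf, 0.0)
    f_crit = _f_critical(model, alpha)
    return {
        "mahalanobis": md,
        "residual_sd": np.sqrt(s_i2),
        "f_ratio": f_ratio,
        "flag": md_flag | (f_ratio > f_crit),
    }


def residual_effective_dof(model: SimcaClassModel, X_class: np.ndarray) -> float:
    """Satterthwaite effective dimension of the class residual space.

    (Σλ)² / Σλ² over the eigenvalues λ of the training residual covariance;
    equals p − k for white residuals and shrinks when smoothing correlates
    neighbouring wavenumbers.
    """
    lam = np.linalg.svd(model.residuals(X_class), compute_uv=False) ** 2
    total = lam.sum()
    if total == 0:
        return float(model.p - model.k)
    return float(total**2 / np.sum(lam**2))


def _f_critical(model: SimcaClassModel, alpha: float) -> float:
    d1 = model.effective_dof if model.effective_dof is not None else model.p - model.k
    d2 = d1 * max(model.n_train - model.k - 1, 1)
    return float(stats.f.ppf(1.0 - alpha, d1, d2))


class SimcaClassifier(ClassifierMixin, BaseEstimator):
    """SIMCA classifier: one PCA submodel per class, F-test admission.

    Parameters
    ----------
    n_components : "auto" (per-class leave-one-out selection) or a fixed int.
    max_components : cap for the automatic selection rule.
    alpha : F-test level for class admission (default 0.05).
    s0_method : "loo" (default) estimates the class residual scale from the
        leave-one-out residuals, so it reflects *prediction* error; "train"
        uses the resubstitution formula of :func:`fit_class_model`, which
        understates prediction residuals when the class is small relative to
        the number of wavenumbers and then rejects genuine class members.
    f_calibration : "conformal" (default) sets each class's admission cutoff
        at the conformal (1 − alpha) quantile of the class's leave-one-out
        F-ratios — finite-sample valid without distributional assumptions,
        which matters because smoothing-correlated, per-sample-scaled
        residuals do not follow the nominal F distribution; "parametric"
        uses the F critical value at the effective degrees of freedom.

    Attributes
    ----------
    classes_ : sorted class labels seen in fit.
    class_models_ : dict label → :class:`SimcaClassModel`.
    icd_ : symmetric interclass-distance matrix (zero diagonal), ordered as
        ``classes_``.
    """

    def __init__(self, n_components="auto", max_components: int = 10,
                 alpha: float = 0.05, s0_method: str = "loo",
                 f_calibration: str = "conformal",
                 score_quantile: float | None = 0.999):
        self.n_components = n_components
        self.max_components = max_components
        self.alpha = alpha
        self.s0_method = s0_method
        self.f_calibration = f_calibration
        self.score_quantile = score_quantile

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        if self.s0_method not in ("loo", "train"):
            raise ValueError("s0_method must be 'loo' or 'train'")
        if self.f_calibration not in ("conformal", "parametric"):
            raise ValueError("f_calibration must be 'conformal' or 'parametric'")
        self.classes_ = np.unique(y)
        self.class_models_ = {}
        self._train_X = {}
        self.f_critical_ = {}
        for label in self.classes_:
            Xc = X[y == label]
            rss = loo_press(Xc, self.max_components, per_sample=True) if Xc.shape[0] >= 3 else None
            press = rss.sum(axis=0) if rss is not None else None
            if self.n_components == "auto":
                k = select_n_components(Xc, self.max_components, press=press)
            else:
                k = int(self.n_components)
            model = fit_class_model(Xc, k, label=str(label))
            if self.s0_method == "loo" and press is not None and k < press.size:
                model.s0 = float(np.sqrt(press[k] / (Xc.shape[0] * (model.p - k))))
            model.effective_dof = residual_effective_dof(model, Xc)
            self.class_models_[label] = model
            self._train_X[label] = Xc
            self.f_critical_[label] = self._calibrate_f_critical(model, rss, k)

        m = len(self.classes_)
        self.icd_ = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                a, b = self.classes_[i], self.classes_[j]
                d = interclass_distance(
                    self.class_models_[a], self.class_models_[b],
                    self._train_X[a], self._train_X[b],
                )
                self.icd_[i, j] = self.icd_[j, i] = d
        return self

    def _calibrate_f_critical(self, model, rss, k) -> float:
        """Class admission cutoff for the residual F-ratio."""
        if (self.f_calibration == "parametric" or rss is None
                or k >= rss.shape[1] or model.s0 == 0):
            return _f_critical(model, self.alpha)
        loo_f = rss[:, k] / (model.p - k) / model.s0**2
        n = loo_f.size
        rank = int(np.ceil((n + 1) * (1.0 - self.alpha)))
        if rank > n:
            return np.inf
        return float(np.sort(loo_f)[rank - 1])

    def decision_function(self, X) -> np.ndarray:
        """Residual F-ratio of every sample against every class (n × m)."""
        check_is_fitted(self, "class_models_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        F = np.empty((X.shape[0], len(self.classes_)))
        for j, label in enumerate(self.classes_):
            model = self.class_models_[label]
            resid = model.residuals(X)
            s_i2 = np.sum(resid**2, axis=1) / (model.p - model.k)
            F[:, j] = s_i2 / model.s0**2 if model.s0 > 0 else np.where(s_i2 > 0, np.inf, 0.0)
        return F

    def admitted(self, X) -> np.ndarray:
        """Boolean n × m matrix of class admissions.

        A sample is admitted when its residual F-ratio is within the class's
        critical value and (with ``score_quantile`` set) its score-space
        Mahalanobis distance is within the chi-square bound.  The score gate
        matters for samples lying *along* a class's principal components but
        far outside the training score range — e.g. a featureless spectrum is
        nearly collinear with the band-contrast component of every pigmented
        class and would otherwise show a deceptively small residual.
        """
        F = self.decision_function(X)
        crit = np.array([self.f_critical_[c] for c in self.classes_])
        adm = F <= crit
        if self.score_quantile is not None:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            for j, label in enumerate(self.classes_):
                model = self.class_models_[label]
                if model.k == 0:
                    continue
                t = model.scores(X)
                d2 = np.sum(t**2 / np.maximum(model.score_var, 1e-30), axis=1)
                cut = stats.chi2.ppf(self.score_quantile, df=model.k)
                adm[:, j] &= d2 <= cut
        return adm

    def combined_distance(self, X) -> np.ndarray:
        """Residual F-ratio plus per-component score Mahalanobis (n × m).

        g = F + d²/k, both terms ≈ 1 for genuine class members.  Ranking by
        g rather than F alone keeps a sample from being claimed by a class
        with a sloppier residual scale: the F-ratio normalizes by s0, so an
        alien sample lying inside a diffuse class's component span can show
        a *smaller* F there than in its own tight class; its extreme scores
        expose it.
        """
        check_is_fitted(self, "class_models_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        G = self.decision_function(X)
        for j, label in enumerate(self.classes_):
            model = self.class_models_[label]
            if model.k == 0:
                continue
            t = model.scores(X)
            d2 = np.sum(t**2 / np.maximum(model.score_var, 1e-30), axis=1)
            G[:, j] = G[:, j] + d2 / model.k
        return G

    def predict(self, X) -> np.ndarray:
        """Nearest admitted class per sample; ``None`` when admitted nowhere.

        Admission is by the class F-test (plus score gate); the nearest class
        among those admitted is the one with the smallest combined
        residual + score distance.
        """
        G = self.combined_distance(X)
        adm = self.admitted(X)
        out = np.empty(G.shape[0], dtype=object)
        for i in range(G.shape[0]):
            if adm[i].any():
                cand = np.where(adm[i])[0]
                out[i] = self.classes_[cand[np.argmin(G[i, cand])]]
            else:
                out[i] = None
        return out

    def predict_nearest(self, X) -> np.ndarray:
        """Nearest class by combined distance, ignoring admission."""
        G = self.combined_distance(X)
        return self.classes_[np.argmin(G, axis=1)]

    def score(self, X, y) -> float:
        """Fraction with the true class as nearest admitted class.

        Samples admitted nowhere (or with a different nearest class) count
        as errors, so accuracy is well-defined even with "none" outcomes.
        """
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([p is not None and p == t for p, t in zip(pred, y)]))

    def scores_3d(self, X) -> dict[str, np.ndarray]:
        """First-3-PC projections of X under every class model (for plotting).

        Classes with k < 3 are zero-padded to three columns.
        """
        check_is_fitted(self, "class_models_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = {}
        for label in self.classes_:
            t = self.class_models_[label].scores(X)
            if t.shape[1] < 3:
                t = np.hstack([t, np.zeros((t.shape[0], 3 - t.shape[1]))])
            out[label] = t[:, :3]
        return out

    def discriminating_power(self, label_a, label_b) -> np.ndarray:
        check_is_fitted(self, "class_models_")
        return discriminating_power(
            self.class_models_[label_a], self.class_models_[label_b],
            self._train_X[label_a], self._train_X[label_b],
        )
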