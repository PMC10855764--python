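"""Multivariate core: autoscaling, PCA, NIPALS PLS-DA, VIP marker selection.

Estimators follow the scikit-learn protocol (``fit``/``transform`` or
``fit``/``predict``, ``get_params``, fitted attributes with a trailing
underscore) so they compose with sklearn pipelines and model selection;
the module-level functions (``autoscale``, ``pca``, ``fit_plsda``, ...)
are thin wrappers kept for script use.

Conventions, stated once:

* variances use n-1 denominators throughout;
* autoscaling (mean-centering + unit variance) is the pre-processing
  default — GC-MS normalized areas span orders of magnitude, and without
  unit variance the abundant methyl esters would dominate every model;
* PCA component signs are fixed by making each component's largest-
  magnitude loading positive, for reproducible score plots;
* PLS-DA codes the response as one-versus-rest 0/1 indicators, one binary
  NIPALS PLS1 model per class, with hard labels by arg-max of the
  continuous class scores (or a 0.5 threshold in the binary case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import DataError, NumericalError

#: Variable-importance-in-projection cutoff used for marker selection.
DEFAULT_VIP_CUTOFF = 1.2


# ---------------------------------------------------------------------------
# autoscaling


class Autoscaler(TransformerMixin, BaseEstimator):
    """Column-wise mean-centering and unit-variance scaling (ddof = 1).

    Constant columns are centered and left at zero (with a warning at fit
    time): they carry no information and dividing by a zero standard
    deviation would poison downstream models.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.constant_mask_ = self.scale_ == 0
        if self.constant_mask_.any():
            warnings.warn(
                f"{int(self.constant_mask_.sum())} constant column(s) "
                "scaled to zero",
                stacklevel=2,
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        scale = np.where(self.constant_mask_, 1.0, self.scale_)
        return (X - self.mean_) / scale

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        scale = np.where(self.constant_mask_, 1.0, self.scale_)
        return np.asarray(X, dtype=float) * scale + self.mean_


@dataclass
class ScaledMatrix:
    """Autoscaled matrix together with the back-transform parameters."""

    values: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray


def autoscale(X) -> ScaledMatrix:
    """Functional wrapper over :class:`Autoscaler`."""
    sc = Autoscaler().fit(X)
    return ScaledMatrix(
        values=sc.transform(X),
        mean=sc.mean_,
        scale=sc.scale_,
        constant_mask=sc.constant_mask_,
    )


# ---------------------------------------------------------------------------
# PCA


class PrincipalComponents(TransformerMixin, BaseEstimator):
    """PCA by singular value decomposition of the (already scaled) matrix.

    ``explained_variance_ratio_`` is sigma_i^2 / sum_j sigma_j^2 over all
    singular values, so retained fractions sum to <= 1 and to 1 when every
    component is kept.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n, p = X.shape
        rank = int(np.linalg.matrix_rank(X))
        k = self.n_components
        if k > min(n, p):
            raise DataError(
                f"n_components={k} exceeds min(n_samples, n_features)={min(n, p)}"
            )
        if k > rank:
            warnings.warn(
                f"n_components={k} exceeds rank {rank}; truncating",
                stacklevel=2,
            )
            k = rank
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        # sign convention: largest-|loading| entry positive per component
        loadings = Vt[:k].T.copy()
        for j in range(k):
            idx = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[idx, j] < 0:
                loadings[:, j] *= -1
        self.loadings_ = loadings
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = s[:k] ** 2 / np.sum(s**2)
        self.n_components_ = k
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        return X @ self.loadings_


def pca(X_scaled, n_components: int = 2) -> PrincipalComponents:
    """Fit PCA on an autoscaled matrix; scores via ``model.transform``."""
    return PrincipalComponents(n_components=n_components).fit(X_scaled)


# ---------------------------------------------------------------------------
# group confidence ellipses


@dataclass(frozen=True)
class GroupEllipse:
    """Confidence ellipse of one group in a 2-D score space.

    ``shape`` is the group score covariance scaled by the chi-square(2)
    quantile at ``level``; a point lies inside iff its squared Mahalanobis
    distance from ``center`` (under the raw covariance) is <= the quantile.
    """

    label: str
    center: np.ndarray
    shape: np.ndarray
    level: float
    covariance: np.ndarray

    def contains(self, point) -> bool:
        d = np.asarray(point, dtype=float) - self.center
        md2 = float(d @ np.linalg.solve(self.covariance, d))
        return md2 <= stats.chi2.ppf(self.level, df=2)

    def boundary(self, n_points: int = 100) -> np.ndarray:
        """Points on the ellipse boundary, for plotting."""
        theta = np.linspace(0, 2 * np.pi, n_points)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(self.shape)
        return self.center + circle @ L.T


def confidence_ellipse(
    scores_2d, label: str = "", level: float = 0.95
) -> GroupEllipse:
    """Chi-square confidence ellipse of one group's 2-D scores."""
    S = np.asarray(scores_2d, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise DataError("confidence ellipse needs n x 2 scores")
    if S.shape[0] < 3:
        raise DataError("group needs at least 3 samples")
    if not 0 < level < 1:
        raise DataError("confidence level must lie in (0, 1)")
    center = S.mean(axis=0)
    cov = np.cov(S, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2:
        raise NumericalError(f"group {label!r} has a singular score covariance")
    q = stats.chi2.ppf(level, df=2)
    return GroupEllipse(
        label=label, center=center, shape=cov * q, level=level, covariance=cov
    )


# ---------------------------------------------------------------------------
# NIPALS PLS


def _nipals_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-10,
):
    """NIPALS with deflation for a (possibly multivariate) response.

    Returns weights W (p x A), X-loadings P (p x A), Y-loadings Q
    (m x A), X-scores T (n x A) and the extracted component count A. For
    a univariate y the inner loop converges in one pass; for multivariate
    Y it iterates until the weight vector changes by less than ``tol`` or
    ``max_iter`` passes.
    """
    Xa = X.copy()
    Ya = Y.astype(float).copy()
    if Ya.ndim == 1:
        Ya = Ya[:, None]
    n, p = Xa.shape
    m = Ya.shape[1]
    A = min(n_components, n - 1, p)
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((m, A))
    T = np.zeros((n, A))
    n_extracted = A
    for a in range(A):
        # start from the Y column with the largest remaining variance
        u = Ya[:, int(np.argmax(np.var(Ya, axis=0)))].copy()
        if float(u @ u) < 1e-15:
            n_extracted = a
            break
        w = np.zeros(p)
        converged = False
        for _ in range(max_iter):
            w_new = Xa.T @ u
            norm = np.linalg.norm(w_new)
            if norm < 1e-15:
                break
            w_new /= norm
            t = Xa @ w_new
            tt = float(t @ t)
            if tt < 1e-15:
                break
            q = Ya.T @ t / tt
            u = Ya @ q / max(float(q @ q), 1e-300)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                converged = True
                break
            w = w_new
        if np.linalg.norm(w) < 1e-15:
            n_extracted = a
            break
        if not converged and m > 1:
            warnings.warn(
                f"NIPALS did not converge for component {a + 1}; "
                "keeping the partial solution",
                stacklevel=3,
            )
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-15:
            n_extracted = a
            break
        p_load = Xa.T @ t / tt
        q = Ya.T @ t / tt
        W[:, a] = w
        P[:, a] = p_load
        Q[:, a] = q
        T[:, a] = t
        Xa -= np.outer(t, p_load)
        Ya -= np.outer(t, q)
    A = n_extracted
    return W[:, :A], P[:, :A], Q[:, :A], T[:, :A], A


def _pls_coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Coefficient matrix B (p x m) with Y_hat = X B, from NIPALS factors."""
    A = W.shape[1]
    if A == 0:
        return np.zeros((W.shape[0], Q.shape[0]))
    R = W @ np.linalg.inv(P.T @ W)  # maps X to scores: T = X R
    return R @ Q.T


class PLSRegressionNIPALS(BaseEstimator):
    """PLS regression by NIPALS, univariate or multivariate response.

    Centered/scaled inputs are the caller's responsibility when
    ``scale=False``; with ``scale=True`` the model autoscales X and
    centers Y internally and predictions are returned on the original Y
    scale. ``predict(X, n_components=a)`` evaluates the truncated model
    with the first ``a`` latent variables.
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        X = check_array(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self._y_1d = Y.ndim == 1
        if self._y_1d:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise DataError("X and Y length mismatch")
        if self.scale:
            self.scaler_ = Autoscaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        self.y_mean_ = Y.mean(axis=0)
        W, P, Q, T, A = _nipals_pls(
            Xs, Y - self.y_mean_, self.n_components, self.max_iter, self.tol
        )
        if A == 0:
            raise NumericalError("no PLS component could be extracted")
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = Q
        self.x_scores_ = T
        self.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        self.n_components_ = A
        self.coef_ = _pls_coefficients(W, P, Q)
        self.n_features_in_ = X.shape[1]
        return self

    def _prepare(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} variables, got {X.shape[1]}"
            )
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def _truncated(self, n_components: int | None):
        if n_components is None or n_components >= self.n_components_:
            return self.coef_
        a = max(1, n_components)
        return _pls_coefficients(
            self.x_weights_[:, :a],
            self.x_loadings_[:, :a],
            self.y_loadings_[:, :a],
        )

    def predict(self, X, n_components: int | None = None):
        Xs = self._prepare(X)
        Yh = Xs @ self._truncated(n_components) + self.y_mean_
        return Yh.ravel() if self._y_1d else Yh

    def transform(self, X, n_components: int | None = None):
        """Latent X-scores of new samples (T = X R)."""
        Xs = self._prepare(X)
        T = Xs @ self.x_rotations_
        if n_components is not None:
            T = T[:, : max(1, n_components)]
        return T


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA: NIPALS PLS2 on a one-hot class response.

    ``decision_function`` returns the continuous predicted class
    indicators (n x n_classes). Hard labels follow ``prediction_rule``:

    * ``"mahalanobis"`` (default) — nearest class centroid in latent
      X-score space under the pooled within-class score covariance;
    * ``"centroid"`` — nearest class centroid in latent score space,
      Euclidean;
    * ``"indicator"`` — arg-max of the predicted indicators; with two
      classes, positive iff the positive-class indicator exceeds
      ``threshold``.

    Distance-based rules are the chemometrics standard: arg-max on
    least-squares indicator predictions systematically masks classes
    whose mean lies between other class means (here: intermediate doses),
    however well separated the groups are.
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 prediction_rule: str = "mahalanobis",
                 threshold: float = 0.5, max_iter: int = 500,
                 tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.prediction_rule = prediction_rule
        self.threshold = threshold
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        if self.prediction_rule not in ("mahalanobis", "centroid", "indicator"):
            raise DataError(
                f"unknown prediction rule {self.prediction_rule!r}"
            )
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise DataError("X and labels length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise DataError("PLS-DA needs at least two classes present")
        Y = np.column_stack(
            [(y == cls).astype(float) for cls in self.classes_]
        )
        self.pls_ = PLSRegressionNIPALS(
            n_components=self.n_components,
            scale=self.scale,
            max_iter=self.max_iter,
            tol=self.tol,
        ).fit(X, Y)
        self.n_components_ = self.pls_.n_components_
        self.n_features_in_ = X.shape[1]
        # per-class centroids and pooled covariance in latent score space,
        # for every truncation level (cheap: A is small)
        T = self.pls_.x_scores_
        self._centroids = {}
        self._pooled_cov = {}
        for a in range(1, self.n_components_ + 1):
            Ta = T[:, :a]
            cents = np.vstack(
                [Ta[y == cls].mean(axis=0) for cls in self.classes_]
            )
            resid = Ta - cents[np.searchsorted(self.classes_, y)]
            dof = max(len(y) - len(self.classes_), 1)
            cov = resid.T @ resid / dof
            self._centroids[a] = cents
            self._pooled_cov[a] = cov
        return self

    def decision_function(self, X, n_components: int | None = None):
        """Continuous predicted class indicators, one column per class."""
        check_is_fitted(self, "pls_")
        return self.pls_.predict(X, n_components=n_components)

    def class_distances(self, X, n_components: int | None = None):
        """Squared distance of each sample to every class centroid in
        latent-score space (Mahalanobis under the pooled within-class
        covariance, or Euclidean for the centroid rule). Lower is closer;
        ``-distance`` is the natural per-class ranking score."""
        check_is_fitted(self, "pls_")
        a = (
            self.n_components_
            if n_components is None
            else min(max(1, n_components), self.n_components_)
        )
        T = self.pls_.transform(X, n_components=a)
        cents = self._centroids[a]
        diff = T[:, None, :] - cents[None, :, :]
        if self.prediction_rule == "centroid":
            return np.einsum("nka,nka->nk", diff, diff)
        cov = self._pooled_cov[a]
        try:
            VI = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            VI = np.linalg.pinv(cov)
        return np.einsum("nka,ab,nkb->nk", diff, VI, diff)

    def predict(self, X, n_components: int | None = None):
        check_is_fitted(self, "pls_")
        if self.prediction_rule == "indicator":
            scores = self.decision_function(X, n_components=n_components)
            if len(self.classes_) == 2:
                return np.where(
                    scores[:, 1] > self.threshold,
                    self.classes_[1],
                    self.classes_[0],
                )
            return self.classes_[np.argmax(scores, axis=1)]
        d2 = self.class_distances(X, n_components=n_components)
        return self.classes_[np.argmin(d2, axis=1)]


def fit_plsda(
    X_scaled, labels, n_lv: int = 2, **kwargs
) -> PLSDAClassifier:
    """Fit a one-vs-rest PLS-DA on an already-scaled matrix."""
    return PLSDAClassifier(n_components=n_lv, scale=False, **kwargs).fit(
        X_scaled, labels
    )


def predict_plsda(model: PLSDAClassifier, X_new):
    """Continuous class scores and hard labels for new samples."""
    return model.decision_function(X_new), model.predict(X_new)


# ---------------------------------------------------------------------------
# VIP


@dataclass(frozen=True)
class VIPVector:
    """Per-variable importance-in-projection scores with the cutoff used."""

    scores: np.ndarray
    cutoff: float = DEFAULT_VIP_CUTOFF
    variable_names: tuple[str, ...] = ()

    def as_series(self) -> pd.Series:
        names = (
            self.variable_names
            if self.variable_names
            else [f"var_{j + 1}" for j in range(len(self.scores))]
        )
        return pd.Series(self.scores, index=list(names), name="vip")


def _vip_from_ssy(W: np.ndarray, ssy: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    total = float(ssy.sum())
    if total <= 0:
        raise NumericalError("model explains no Y variance; VIP undefined")
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / total)


def _pls_factors(model):
    if isinstance(model, PLSRegressionNIPALS):
        return model
    if isinstance(model, PLSDAClassifier):
        check_is_fitted(model, "pls_")
        return model.pls_
    raise DataError(f"cannot compute VIP for {type(model).__name__}")


def vip_scores(
    model, cutoff: float = DEFAULT_VIP_CUTOFF,
    variable_names: Sequence[str] = (),
) -> VIPVector:
    """VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ).

    ``SSY_a = ||q_a||^2 t_a' t_a`` is the Y variance captured by latent
    variable a (q_a is a vector for a multivariate response); the
    normalization gives mean(VIP^2) = 1. Accepts a fitted
    :class:`PLSRegressionNIPALS` or :class:`PLSDAClassifier`.
    """
    pls = _pls_factors(model)
    tt = np.einsum("ij,ij->j", pls.x_scores_, pls.x_scores_)
    ssy = (pls.y_loadings_**2).sum(axis=0) * tt
    v = _vip_from_ssy(pls.x_weights_, ssy)
    return VIPVector(
        scores=v, cutoff=cutoff, variable_names=tuple(variable_names)
    )


def vip_per_class(
    model: PLSDAClassifier, variable_names: Sequence[str] = ()
) -> dict:
    """Per-class VIP: SSY weighted by each class's own indicator loadings."""
    pls = _pls_factors(model)
    tt = np.einsum("ij,ij->j", pls.x_scores_, pls.x_scores_)
    out = {}
    for j, cls in enumerate(model.classes_):
        ssy = pls.y_loadings_[j] ** 2 * tt
        out[cls] = VIPVector(
            scores=_vip_from_ssy(pls.x_weights_, ssy),
            variable_names=tuple(variable_names),
        )
    return out


def select_markers(
    vip: VIPVector, cutoff: float | None = None
) -> list[str]:
    """Variables with VIP >= cutoff, sorted by descending VIP."""
    cut = vip.cutoff if cutoff is None else cutoff
    if cut <= 0:
        raise DataError("VIP cutoff must be positive")
    s = vip.as_series()
    sel = s[s >= cut].sort_values(ascending=False)
    return list(sel.index)
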