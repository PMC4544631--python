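"""The five GEBV prediction methods, as scikit-learn style estimators.

All estimators implement ``fit(X, y)`` / ``predict(X)`` on a lines x markers
design (0/1 dominant calls, possibly mean-imputed fractions) and compose
with scikit-learn pipelines and model selection:

* :class:`RidgeBLUP` — closed-form ridge regression (RR-BLUP) with the
  shrinkage parameter tied to a heritability.
* :class:`BayesianRidgeGEBV` — Gibbs sampler, Gaussian prior with a variance
  common to all marker effects.
* :class:`BayesianLassoGEBV` — Gibbs sampler, double-exponential prior
  giving marker-specific shrinkage.
* :class:`GBLUP` — mixed-model BLUP on a marker-derived relationship
  matrix, variance ratio estimated by spectral REML.
* :class:`KernelRidgeGEBV` — Gaussian-kernel (RKHS) regression.
* :class:`RandomForestGEBV` — bagged regression trees with random feature
  selection at each split.

Marker columns are centered with the *training* means; target genotypes are
always centered with the stored training means, never their own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import _gibbs
from .io import MarkerMatrix

logger = logging.getLogger(__name__)

METHOD_NAMES = ("GBLUP", "BRR", "BLASSO", "RKHS", "RF", "RIDGE")


def center_markers(X, means=None):
    """Center marker columns; target sets must reuse the training means.

    Returns ``(X_centered, column_means)``.
    """
    X = np.asarray(X, dtype=float)
    if means is None:
        means = X.mean(axis=0)
    return X - means[None, :], means


@dataclass
class GibbsConfig:
    """Priors and chain lengths for the Bayesian samplers.

    Defaults are the standard whole-genome-regression settings used
    throughout the package: scaled-inverse-chi-square priors with residual
    scale 4.5 (df 3) and marker-effect scale 0.009 (df 3), shrinkage
    initialised from a heritability of 0.37, 20,000 burn-in iterations out
    of 60,000.
    """

    S_eps: float = 4.5
    df_eps: float = 3.0
    S_beta: float = 0.009
    df_beta: float = 3.0
    h2_lambda: float = 0.37
    burn_in: int = 20_000
    n_iter: int = 60_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.S_eps <= 0 or self.S_beta <= 0:
            raise ValueError("prior scales must be positive")
        if self.df_eps <= 0 or self.df_beta <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if not 0 < self.h2_lambda < 1:
            raise ValueError("h2_lambda must be in (0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def scaled_down(self, burn_in: int = 2_000, n_iter: int = 10_000) -> "GibbsConfig":
        """Copy with shorter chains (for cross-validation loops)."""
        return GibbsConfig(
            self.S_eps, self.df_eps, self.S_beta, self.df_beta, self.h2_lambda,
            burn_in, n_iter, self.thin, self.seed,
        )


class _MarkerRegressor(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing: validation and training-mean centering."""

    def _prepare_fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.n_features_in_ = X.shape[1]
        Xc, self.column_means_ = center_markers(X)
        self.intercept_ = float(np.mean(y))
        return Xc, y - self.intercept_

    def _prepare_predict(self, X):
        check_is_fitted(self, "column_means_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} markers, expected {self.n_features_in_}"
            )
        return X - self.column_means_[None, :]


class _LinearMarkerRegressor(_MarkerRegressor):
    """Linear methods predict ``intercept_ + Xc @ marker_effects_``."""

    def predict(self, X):
        Xc = self._prepare_predict(X)
        return self.intercept_ + Xc @ self.marker_effects_


class RidgeBLUP(_LinearMarkerRegressor):
    """Ridge regression BLUP of marker effects (RR-BLUP).

    The ridge parameter is tied to a line-mean heritability through the
    additive variance partition ``Vg = s2_beta * sum_j Var(x_j)``:

        ``lambda = (1 - h2) / h2 * sum_j Var(x_j)``

    so that effects are shrunk exactly as a mixed model with the implied
    variance ratio would shrink them.  ``h2`` defaults to 0.37 when the
    trait's heritability is not supplied.

    Parameters
    ----------
    h2 : float in (0, 1)
        Heritability used to set the shrinkage.
    lam : float, optional
        Explicit ridge parameter; overrides ``h2`` when given.
    """

    def __init__(self, h2: float = 0.37, lam: float | None = None):
        self.h2 = h2
        self.lam = lam

    def fit(self, X, y):
        Xc, yc = self._prepare_fit(X, y)
        if self.lam is not None:
            lam = float(self.lam)
        else:
            if not 0 < self.h2 < 1:
                raise ValueError("h2 must be in (0, 1)")
            lam = (1.0 - self.h2) / self.h2 * float(Xc.var(axis=0, ddof=0).sum())
        self.lambda_ = lam
        n, p = Xc.shape
        if p <= n:
            A = Xc.T @ Xc + lam * np.eye(p)
            self.marker_effects_ = np.linalg.solve(A, Xc.T @ yc)
        else:
            # dual form: beta = X' (XX' + lam I)^-1 y
            A = Xc @ Xc.T + lam * np.eye(n)
            self.marker_effects_ = Xc.T @ np.linalg.solve(A, yc)
        return self


class BayesianRidgeGEBV(_LinearMarkerRegressor):
    """Bayesian ridge regression by Gibbs sampling.

    Gaussian prior with a single variance common to every marker effect;
    scaled-inverse-chi-square priors on the effect and residual variances.
    Reported effects and intercept are posterior means over the post-burn-in
    samples.  With matched variance ratio the posterior-mean effects agree
    with :class:`RidgeBLUP` up to Monte-Carlo error.
    """

    def __init__(self, config: GibbsConfig | None = None, seed: int | None = None):
        self.config = config
        self.seed = seed

    def fit(self, X, y):
        cfg = self.config if self.config is not None else GibbsConfig()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite phenotype values")
        Xc, yc = self._prepare_fit(X, y)
        seed = cfg.seed if self.seed is None else self.seed
        mu, beta, s2e, s2b = _gibbs.brr_gibbs(
            np.ascontiguousarray(Xc), np.ascontiguousarray(yc, dtype=float),
            cfg.S_eps, cfg.df_eps, cfg.S_beta, cfg.df_beta,
            cfg.burn_in, cfg.n_iter, cfg.thin, int(seed) % 2**31,
        )
        self.intercept_ += mu
        self.marker_effects_ = beta
        self.sigma2_e_samples_ = s2e
        self.sigma2_beta_samples_ = s2b
        self.diagnostics_ = {
            "sigma2_e_mean": float(s2e.mean()),
            "sigma2_beta_mean": float(s2b.mean()),
            "n_samples": int(len(s2e)),
        }
        return self


def _lasso_lambda2_from_h2(Xc, h2):
    """Shrinkage level implied by a heritability.

    The double-exponential prior has marginal effect variance
    ``2 * s2_e / lambda2``; equating the implied genetic variance
    ``sum_j Var(x_j) * 2 * s2_e / lambda2`` with ``s2_e * h2 / (1 - h2)``
    gives ``lambda2 = 2 * sum_j Var(x_j) * (1 - h2) / h2``.
    """
    sv = float(Xc.var(axis=0, ddof=0).sum())
    return 2.0 * max(sv, 1e-12) * (1.0 - h2) / h2


class BayesianLassoGEBV(_LinearMarkerRegressor):
    """Bayesian LASSO regression by Gibbs sampling.

    Marker effects get a double-exponential prior through the normal-
    exponential mixture ``beta_j ~ N(0, s2_e tau2_j)``,
    ``tau2_j ~ Exp(lambda2/2)``, giving each marker its own shrinkage.
    ``lambda2`` receives a Gamma(1, rate) hyperprior whose mean equals the
    shrinkage level implied by ``config.h2_lambda``, and the chain is
    initialised there.
    """

    def __init__(self, config: GibbsConfig | None = None, seed: int | None = None):
        self.config = config
        self.seed = seed

    def fit(self, X, y):
        cfg = self.config if self.config is not None else GibbsConfig()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite phenotype values")
        Xc, yc = self._prepare_fit(X, y)
        lam2_0 = _lasso_lambda2_from_h2(Xc, cfg.h2_lambda)
        gamma_shape = 1.0
        gamma_rate = gamma_shape / lam2_0  # prior mean = lam2_0
        seed = cfg.seed if self.seed is None else self.seed
        mu, beta, s2e, lam2 = _gibbs.blasso_gibbs(
            np.ascontiguousarray(Xc), np.ascontiguousarray(yc, dtype=float),
            cfg.S_eps, cfg.df_eps, lam2_0, gamma_shape, gamma_rate,
            cfg.burn_in, cfg.n_iter, cfg.thin, int(seed) % 2**31,
        )
        self.intercept_ += mu
        self.marker_effects_ = beta
        self.sigma2_e_samples_ = s2e
        self.lambda2_samples_ = lam2
        self.diagnostics_ = {
            "sigma2_e_mean": float(s2e.mean()),
            "lambda2_mean": float(lam2.mean()),
            "n_samples": int(len(s2e)),
        }
        return self


# ---------------------------------------------------------------------------
# GBLUP


def reml_variance_ratio(K, y, bounds=(1e-4, 1e4)):
    """Spectral REML estimate of ``delta = s2_e / s2_g`` for
    ``y = 1 mu + g + e`` with ``g ~ N(0, s2_g K)``.

    Works in the eigenbasis of the centered kinship, profiling out the
    variance scale so the restricted likelihood is one-dimensional in
    ``delta``.  Returns ``(delta, s2_g, s2_e)``.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    J = np.eye(n) - np.ones((n, n)) / n
    A = J @ K @ J
    w, U = np.linalg.eigh((A + A.T) / 2)
    # drop the null direction along the intercept
    keep = np.argsort(w)[1:]
    xi = np.clip(w[keep], 0.0, None)
    eta = U[:, keep].T @ (y - y.mean())

    def neg_restricted_ll(log_delta):
        d = np.exp(log_delta)
        denom = xi + d
        s2 = np.sum(eta**2 / denom) / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2) + np.sum(np.log(denom)))

    res = minimize_scalar(
        neg_restricted_ll, bounds=np.log(bounds), method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(np.exp(res.x))
    s2_g = float(np.sum(eta**2 / (xi + delta)) / (n - 1))
    return delta, s2_g, delta * s2_g


def gblup(K, y, train_idx=None, delta=None, jitter: float = 1e-6, strict: bool = False):
    """Mixed-model BLUP of breeding values from a kinship matrix.

    ``K`` covers the union of training and target lines; ``train_idx``
    indexes the training lines (default: the first ``len(y)`` rows).  The
    variance ratio ``delta = s2_e / s2_g`` is estimated by REML on the
    training block unless supplied.  Solves

        ``g_hat = K[:, t] (K[t, t] + delta I)^{-1} (y - ybar)``

    and returns ``ybar + g_hat`` for every line in ``K``.

    A rank-deficient training kinship (e.g. duplicated lines) makes the
    animal-model equations unstable; with ``strict=True`` this raises a
    "kinship singular" error, otherwise ``jitter`` is added to the diagonal
    with a warning.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if train_idx is None:
        train_idx = np.arange(len(y))
    train_idx = np.asarray(train_idx)
    Ktt = K[np.ix_(train_idx, train_idx)]
    if not np.allclose(Ktt, Ktt.T, atol=1e-8):
        raise ValueError("kinship matrix is not symmetric")
    if delta is None:
        delta, _, _ = reml_variance_ratio(Ktt, y)
    w = np.linalg.eigvalsh(Ktt)
    if strict and w[0] < max(1e-10, 1e-10 * max(w[-1], 1.0)):
        raise np.linalg.LinAlgError(
            "kinship singular: training kinship is rank deficient "
            "(excessively related or duplicated lines)"
        )
    if w[0] + delta < max(1e-8, 1e-12 * max(w[-1], 1.0)):
        # the mixed-model system itself is (near-)singular
        logger.warning(
            "mixed-model equations near singular; adding diagonal jitter %g", jitter
        )
        Ktt = Ktt + jitter * np.eye(len(train_idx))
    ybar = y.mean()
    alpha = scipy.linalg.solve(
        Ktt + delta * np.eye(len(train_idx)), y - ybar, assume_a="pos"
    )
    return ybar + K[:, train_idx] @ alpha, delta


class GBLUP(_MarkerRegressor):
    """Genomic BLUP: an animal-model BLUP on a marker-derived relationship.

    ``fit`` builds the linear kinship ``K = Xc Xc' / c`` from training
    markers (``c`` = mean diagonal, so the relationship averages 1 on the
    diagonal) and estimates the variance ratio by REML; ``predict`` extends
    the kinship to target lines through the cross-products of their centered
    genotypes.  Equivalent to :class:`RidgeBLUP` with ``lambda = c * delta``.

    Parameters
    ----------
    delta : float, optional
        Variance ratio ``s2_e/s2_g``; estimated by REML when ``None``.
    jitter : float
        Diagonal jitter added when the training kinship is rank deficient.
    strict : bool
        Raise instead of jittering (mirrors animal-model failures on
        excessively related training sets).
    """

    def __init__(self, delta: float | None = None, jitter: float = 1e-6, strict: bool = False):
        self.delta = delta
        self.jitter = jitter
        self.strict = strict

    def fit(self, X, y):
        Xc, yc = self._prepare_fit(X, y)
        self._Xc_train = Xc
        G = Xc @ Xc.T
        c = float(np.mean(np.diag(G)))
        if c <= 0:
            raise ValueError("all training genotypes identical: kinship has zero diagonal")
        self.kinship_scale_ = c
        K = G / c
        if self.delta is None:
            self.delta_, self.sigma2_g_, self.sigma2_e_ = reml_variance_ratio(K, yc + self.intercept_)
        else:
            self.delta_ = float(self.delta)
        w = np.linalg.eigvalsh(K)
        # centering always leaves one null direction; deficiency beyond it
        # signals duplicated or excessively related lines
        if self.strict and w[1] < max(1e-10, 1e-10 * max(w[-1], 1.0)):
            raise np.linalg.LinAlgError(
                "kinship singular: training kinship is rank deficient"
            )
        if w[0] + self.delta_ < 1e-8:
            logger.warning("mixed-model equations near singular; adding jitter %g", self.jitter)
            K = K + self.jitter * np.eye(K.shape[0])
        self._alpha = scipy.linalg.solve(
            K + self.delta_ * np.eye(K.shape[0]), yc, assume_a="pos"
        )
        return self

    def predict(self, X):
        Xc = self._prepare_predict(X)
        K_cross = Xc @ self._Xc_train.T / self.kinship_scale_
        return self.intercept_ + K_cross @ self._alpha


class KernelRidgeGEBV(_MarkerRegressor):
    """RKHS regression: kernel ridge with a Gaussian kernel over genotypes.

    ``K_ij = exp(-d2_ij / bandwidth)`` with ``d2`` the squared Euclidean
    marker distance.  The default bandwidth is the median of the pairwise
    squared distances among training lines (median heuristic).

    Parameters
    ----------
    bandwidth : float, optional
        Kernel bandwidth theta; median heuristic when ``None``.
    regularization : float
        Ridge term added to the kernel diagonal.
    """

    def __init__(self, bandwidth: float | None = None, regularization: float = 1.0):
        self.bandwidth = bandwidth
        self.regularization = regularization

    def fit(self, X, y):
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        X, y = check_X_y(X, y, y_numeric=True)
        self.n_features_in_ = X.shape[1]
        self.column_means_ = np.zeros(X.shape[1])  # distances need no centering
        self._X_train = np.asarray(X, dtype=float)
        self.intercept_ = float(np.mean(y))
        d2 = euclidean_distances(self._X_train, squared=True)
        if self.bandwidth is None:
            off = d2[np.triu_indices_from(d2, k=1)]
            med = float(np.median(off)) if off.size else 1.0
            self.bandwidth_ = med if med > 0 else 1.0
        else:
            if self.bandwidth <= 0:
                raise ValueError("bandwidth must be positive")
            self.bandwidth_ = float(self.bandwidth)
        K = np.exp(-d2 / self.bandwidth_)
        n = K.shape[0]
        A = K + self.regularization * np.eye(n)
        if self.regularization == 0:
            A = A + 1e-10 * np.eye(n)  # numerical floor for exact interpolation
        self._alpha = scipy.linalg.solve(A, y - self.intercept_, assume_a="pos")
        return self

    def predict(self, X):
        check_is_fitted(self, "_alpha")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} markers, expected {self.n_features_in_}")
        d2 = euclidean_distances(np.asarray(X, dtype=float), self._X_train, squared=True)
        return self.intercept_ + np.exp(-d2 / self.bandwidth_) @ self._alpha


class RandomForestGEBV(RegressorMixin, BaseEstimator):
    """Random-forest regression of phenotypes on markers.

    Bagged regression trees with ``mtry`` candidate markers per split
    (default ``n_markers // 3``, the standard regression choice) and 500
    trees; prediction is the mean over trees.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.n_features_in_ = X.shape[1]
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        mtry = self.mtry if self.mtry is not None else max(1, X.shape[1] // 3)
        if not 1 <= mtry <= X.shape[1]:
            raise ValueError("mtry out of range")
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=mtry,
            random_state=int(self.seed) % 2**31,
            n_jobs=1,
        ).fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(check_array(X))


# ---------------------------------------------------------------------------
# named-method registry and MarkerMatrix-level API


def make_estimator(method: str, h2: float | None = None, config: GibbsConfig | None = None,
                   seed: int = 0, **kwargs):
    """Build the estimator for a method name (GBLUP/BRR/BLASSO/RKHS/RF/RIDGE)."""
    m = method.upper()
    if m == "RIDGE":
        return RidgeBLUP(h2=h2 if h2 is not None else 0.37, **kwargs)
    if m == "BRR":
        return BayesianRidgeGEBV(config=config, seed=seed, **kwargs)
    if m == "BLASSO":
        return BayesianLassoGEBV(config=config, seed=seed, **kwargs)
    if m == "GBLUP":
        return GBLUP(**kwargs)
    if m == "RKHS":
        return KernelRidgeGEBV(**kwargs)
    if m == "RF":
        return RandomForestGEBV(seed=seed, **kwargs)
    raise ValueError(f"unknown method {method!r}; choose from {METHOD_NAMES}")


@dataclass
class FittedPredictor:
    """A fitted GEBV model bound to its training marker panel."""

    method: str
    estimator: object
    marker_ids: list
    training_line_ids: list

    @property
    def intercept(self) -> float:
        return getattr(self.estimator, "intercept_", float("nan"))

    @property
    def marker_effects(self):
        return getattr(self.estimator, "marker_effects_", None)

    @property
    def diagnostics(self) -> dict:
        return getattr(self.estimator, "diagnostics_", {})


def fit_predictor(method, train: MarkerMatrix, y, **kwargs) -> FittedPredictor:
    """Fit a named method (or a ready estimator) on a MarkerMatrix."""
    if isinstance(method, str):
        est = make_estimator(method, **kwargs)
        name = method.upper()
    else:
        est = clone(method)
        name = type(method).__name__
    if train.has_missing():
        raise ValueError("training genotypes contain missing values; impute first")
    est.fit(train.genotypes, np.asarray(y, dtype=float))
    return FittedPredictor(
        method=name,
        estimator=est,
        marker_ids=list(train.marker_ids),
        training_line_ids=list(train.line_ids),
    )


def predict(p: FittedPredictor, target: MarkerMatrix):
    """GEBVs for target lines; marker ids must match training in id and order."""
    if list(target.marker_ids) != list(p.marker_ids):
        bad = [
            (a, b) for a, b in zip(p.marker_ids, target.marker_ids) if a != b
        ][:5]
        raise ValueError(
            f"target markers do not match training markers; first mismatches: {bad}"
            if bad
            else "target marker count differs from training"
        )
    if target.has_missing():
        raise ValueError("target genotypes contain missing values; impute first")
    return p.estimator.predict(target.genotypes)


# thin functional wrappers over the estimators


def ridge_rrblup(X, y, h2: float = 0.37, lam=None) -> RidgeBLUP:
    return RidgeBLUP(h2=h2, lam=lam).fit(X, y)


def bayes_ridge_gibbs(X, y, cfg: GibbsConfig | None = None) -> BayesianRidgeGEBV:
    return BayesianRidgeGEBV(config=cfg).fit(X, y)


def bayes_lasso_gibbs(X, y, cfg: GibbsConfig | None = None) -> BayesianLassoGEBV:
    return BayesianLassoGEBV(config=cfg).fit(X, y)


def rkhs_fit(X, y, bandwidth=None, regularization: float = 1.0) -> KernelRidgeGEBV:
    return KernelRidgeGEBV(bandwidth=bandwidth, regularization=regularization).fit(X, y)


def random_forest_fit(X, y, n_trees: int = 500, mtry=None, seed: int = 0) -> RandomForestGEBV:
    return RandomForestGEBV(n_trees=n_trees, mtry=mtry, seed=seed).fit(X, y)
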