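"""Maximum-likelihood cumulative-logit (proportional-odds) and logistic fits.

This is the self-contained numerical engine behind every estimation
strategy in the package.  Both fitters maximize the exact log-likelihood by
Newton-Raphson with step-halving, report standard errors from the inverse
observed information at the optimum, and never silently return a
non-converged fit as converged.  The proportional-odds model is

    logit P(Y <= k | x) = alpha_k + x beta,        k = 1..K-1,

with strictly increasing cut-points alpha_k, so a *negative* coefficient
shifts probability mass away from the low (worst) outcome categories.

The estimators follow the scikit-learn protocol (``fit`` / ``predict_proba``
/ ``get_params``) and compose with sklearn model-selection utilities; the
module-level ``fit_proportional_odds`` / ``fit_logistic`` functions are thin
wrappers returning a :class:`FitResult`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from ._errors import DegenerateInputError

__all__ = [
    "FitResult",
    "ProportionalOddsRegressor",
    "LogisticRegressionMLE",
    "fit_proportional_odds",
    "fit_logistic",
    "nagelkerke_r2",
    "pseudo_r2",
    "collinearity_screen",
]

_TINY = 1e-300
# |log-odds| beyond this is treated as (quasi-)separation: the likelihood has
# no interior maximum and the Newton path diverges.
_PARAM_BOUND = 30.0


class CollinearityWarning(UserWarning):
    pass


def collinearity_screen(X: np.ndarray, names: Sequence[str] | None = None, tol: float = 1e-8):
    """Greedy rank screen against an implicit intercept.

    Walks the columns in order and drops (with a warning naming them) any
    column whose residual variance after projection on the intercept and the
    previously kept columns falls below ``tol`` relative to its own sum of
    squares.  A constant column is therefore always dropped — in ordinal and
    logistic models it is absorbed by the cut-points / intercept.

    Returns ``(kept_indices, dropped_indices)``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    A = np.column_stack([np.ones(n), X])
    G = A.T @ A
    kept: list[int] = []
    dropped: list[int] = []
    sel = [0]  # intercept always in the projection basis
    for j in range(p):
        gj = G[j + 1, j + 1]
        if gj <= 0.0:
            dropped.append(j)
            continue
        K = G[np.ix_(sel, sel)]
        g = G[sel, j + 1]
        try:
            resid = gj - g @ np.linalg.solve(K, g)
        except np.linalg.LinAlgError:
            resid = 0.0
        if resid <= tol * gj:
            dropped.append(j)
        else:
            kept.append(j)
            sel.append(j + 1)
    if dropped:
        warnings.warn(
            "dropping collinear/degenerate design columns: "
            + ", ".join(str(names[j]) for j in dropped),
            CollinearityWarning,
            stacklevel=3,
        )
    return kept, dropped


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood cumulative-logit or logistic fit.

    ``coef`` / ``se`` are aligned with the *input* design columns; entries for
    columns removed by the collinearity screen are NaN.  ``cutpoints`` holds
    the K-1 ordered intercepts of an ordinal fit; a binary logistic fit
    stores its single intercept in ``intercept`` instead.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_iter: int
    n_obs: int
    cutpoints: np.ndarray | None = None
    se_cutpoints: np.ndarray | None = None
    intercept: float | None = None
    se_intercept: float | None = None
    dropped: list[str] = field(default_factory=list)

    def beta(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def stderr(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def to_json(self) -> str:
        def _arr(a):
            return None if a is None else np.asarray(a).tolist()

        return json.dumps(
            {
                "names": list(self.names),
                "coef": _arr(self.coef),
                "se": _arr(self.se),
                "cutpoints": _arr(self.cutpoints),
                "se_cutpoints": _arr(self.se_cutpoints),
                "intercept": self.intercept,
                "se_intercept": self.se_intercept,
                "loglik": self.loglik,
                "loglik_null": self.loglik_null,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "n_obs": self.n_obs,
                "dropped": list(self.dropped),
            }
        )


def _validate_design(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if len(y) != X.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if X.shape[0] == 0:
        raise DegenerateInputError("empty design matrix")
    return X, y


def _po_ll_parts(alpha, beta, X, c, K):
    """Log-likelihood plus the per-observation pieces needed for derivatives."""
    eta = X @ beta
    F = expit(alpha[None, :] + eta[:, None])  # (n, K-1)
    n = len(c)
    idx = np.arange(n)
    valid_u = c <= K - 2
    valid_l = c >= 1
    Fu = np.where(valid_u, F[idx, np.minimum(c, K - 2)], 1.0)
    Fl = np.where(valid_l, F[idx, np.maximum(c - 1, 0)], 0.0)
    pi = np.clip(Fu - Fl, _TINY, None)
    ll = float(np.log(pi).sum())
    gu = np.where(valid_u, Fu * (1.0 - Fu), 0.0)
    gl = np.where(valid_l, Fl * (1.0 - Fl), 0.0)
    hu = np.where(valid_u, gu * (1.0 - 2.0 * Fu), 0.0)
    hl = np.where(valid_l, gl * (1.0 - 2.0 * Fl), 0.0)
    return ll, pi, gu, gl, hu, hl, valid_u, valid_l


def _po_loglik(alpha, beta, X, c, K) -> float:
    return _po_ll_parts(alpha, beta, X, c, K)[0]


def po_score_hessian(alpha, beta, X, c, K):
    """Analytic gradient and Hessian of the proportional-odds log-likelihood.

    Parameter order: (alpha_1..alpha_{K-1}, beta_1..beta_p).
    """
    n, p = X.shape
    q = K - 1
    ll, pi, gu, gl, hu, hl, valid_u, valid_l = _po_ll_parts(alpha, beta, X, c, K)
    wu, wl = gu / pi, gl / pi
    cu, cl = hu / pi, hl / pi
    u_cut = np.minimum(c, K - 2)  # cut index of the upper bound (valid_u only)
    l_cut = np.maximum(c - 1, 0)

    grad = np.zeros(q + p)
    grad[:q] = np.bincount(u_cut[valid_u], weights=wu[valid_u], minlength=q) - np.bincount(
        l_cut[valid_l], weights=wl[valid_l], minlength=q
    )
    grad[q:] = X.T @ (wu - wl)

    H = np.zeros((q + p, q + p))
    # alpha-alpha block: diagonal plus the adjacent-cut band from -s s'
    diag = (
        np.bincount(u_cut[valid_u], weights=(cu - wu**2)[valid_u], minlength=q)
        - np.bincount(l_cut[valid_l], weights=(cl + wl**2)[valid_l], minlength=q)
    )
    H[np.arange(q), np.arange(q)] = diag
    both = valid_u & valid_l
    if np.any(both):
        band = np.bincount(l_cut[both], weights=(wu * wl)[both], minlength=q)
        for k in range(q - 1):
            H[k + 1, k] += band[k]
            H[k, k + 1] += band[k]
    # alpha-beta block
    au = cu - wu * (wu - wl)
    al = -cl + wl * (wu - wl)
    for k in range(q):
        w = np.zeros(n)
        mu = valid_u & (u_cut == k)
        ml = valid_l & (l_cut == k)
        w[mu] += au[mu]
        w[ml] += al[ml]
        H[k, q:] = w @ X
        H[q:, k] = H[k, q:]
    # beta-beta block
    wbb = cu - cl - (wu - wl) ** 2
    H[q:, q:] = X.T @ (X * wbb[:, None])
    return ll, grad, H


def _newton(theta0, ll_grad_hess, loglik, is_valid, max_iter, tol, grad_tol):
    """Newton-Raphson with step-halving; returns (theta, ll, converged, iters, info_ok)."""
    theta = np.asarray(theta0, dtype=float)
    ll, grad, H = ll_grad_hess(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -grad, rcond=None)[0]
        t = 1.0
        ll_new, theta_new = -np.inf, theta
        # acceptance slack scaled to |ll|: near the optimum the true Newton
        # gain can fall below the float noise of the summed log-likelihood
        slack = 1e-10 * (abs(ll) + 1.0)
        for _ in range(40):
            cand = theta + t * step
            if is_valid(cand):
                ll_cand = loglik(cand)
                if ll_cand > ll - slack:
                    ll_new, theta_new = ll_cand, cand
                    break
            t *= 0.5
        if not np.isfinite(ll_new):  # no admissible improving step
            break
        rel = abs(ll_new - ll) / (abs(ll_new) + 1e-10)
        theta = theta_new
        ll, grad, H = ll_grad_hess(theta)
        if rel < tol and np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
    if np.max(np.abs(theta)) > _PARAM_BOUND:
        converged = False  # (quasi-)separation: estimates diverging
    return theta, ll, converged, it, H


def _invert_information(H):
    """Standard errors from the inverse observed information -H; None if not PD."""
    info = -H
    try:
        L = np.linalg.cholesky(info)
    except np.linalg.LinAlgError:
        return None
    inv = np.linalg.inv(info)
    d = np.diag(inv)
    if np.any(d <= 0):
        return None
    return np.sqrt(d)


def _null_loglik_multinomial(counts: np.ndarray) -> float:
    n = counts.sum()
    nz = counts[counts > 0]
    return float((nz * np.log(nz / n)).sum())


class ProportionalOddsRegressor(BaseEstimator):
    """Proportional-odds (cumulative-logit) regression by full Newton-Raphson.

    Parameters
    ----------
    max_iter : int
        Newton iteration cap; hitting it flags the fit as not converged.
    tol : float
        Relative log-likelihood change required for convergence.
    grad_tol : float
        Max absolute score component required for convergence.
    collinearity_tol : float
        Relative tolerance of the rank screen that drops collinear columns.

    Attributes (after ``fit``)
    --------------------------
    coef_, se_ : arrays aligned with input columns (NaN where dropped);
    cutpoints_, se_cutpoints_ : the K-1 ordered intercepts;
    loglik_, loglik_null_, converged_, n_iter_, classes_, result_.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-10,
                 grad_tol: float = 1e-6, collinearity_tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol
        self.grad_tol = grad_tol
        self.collinearity_tol = collinearity_tol

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X, y = _validate_design(X, y)
        classes, c = np.unique(y, return_inverse=True)
        K = len(classes)
        if K < 2:
            raise DegenerateInputError("y must have at least 2 observed categories")
        p = X.shape[1]
        names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
        if len(names) != p:
            raise ValueError("feature_names length does not match design columns")
        kept, dropped = collinearity_screen(X, names, tol=self.collinearity_tol)
        Xk = X[:, kept]
        q = K - 1

        counts = np.bincount(c, minlength=K)
        cum = np.cumsum(counts)[:-1] / len(c)
        alpha0 = logit(np.clip(cum, 1e-12, 1 - 1e-12))
        theta0 = np.concatenate([alpha0, np.zeros(len(kept))])

        def unpack(th):
            return th[:q], th[q:]

        def is_valid(th):
            a = th[:q]
            return bool(np.all(np.diff(a) > 0)) if q > 1 else True

        def lgh(th):
            a, b = unpack(th)
            return po_score_hessian(a, b, Xk, c, K)

        def ll_only(th):
            a, b = unpack(th)
            return _po_loglik(a, b, Xk, c, K)

        theta, ll, converged, n_iter, H = _newton(
            theta0, lgh, ll_only, is_valid, self.max_iter, self.tol, self.grad_tol
        )
        se_all = _invert_information(H) if converged else None
        if converged and se_all is None:
            converged = False

        alpha, beta_k = unpack(theta)
        coef = np.full(p, np.nan)
        se = np.full(p, np.nan)
        coef[kept] = beta_k
        if se_all is not None:
            se[kept] = se_all[q:]
            se_cut = se_all[:q]
        else:
            se_cut = np.full(q, np.nan)

        self.classes_ = classes
        self.feature_names_ = names
        self.kept_idx_ = kept
        self.coef_ = coef
        self.se_ = se
        self.cutpoints_ = alpha
        self.se_cutpoints_ = se_cut
        self.loglik_ = ll
        self.loglik_null_ = _null_loglik_multinomial(counts)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_obs_ = len(c)
        self.result_ = FitResult(
            names=names, coef=coef, se=se, loglik=ll, loglik_null=self.loglik_null_,
            converged=converged, n_iter=n_iter, n_obs=len(c),
            cutpoints=alpha, se_cutpoints=se_cut,
            dropped=[names[j] for j in dropped],
        )
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = np.nan_to_num(self.coef_, nan=0.0) @ X.T
        F = expit(self.cutpoints_[:, None] + eta[None, :])
        cum = np.vstack([np.zeros_like(eta), F, np.ones_like(eta)])
        return np.diff(cum, axis=0).T

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class LogisticRegressionMLE(BaseEstimator):
    """Binary logistic regression by Newton-Raphson (exact ML, no penalty).

    Unlike sklearn's default ridge-penalized solver this is the plain
    maximum-likelihood fit with observed-information standard errors, and
    separation is surfaced as ``converged_ = False`` rather than a finite
    penalized estimate.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-10,
                 grad_tol: float = 1e-6, collinearity_tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol
        self.grad_tol = grad_tol
        self.collinearity_tol = collinearity_tol

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X, y = _validate_design(X, y)
        yb = np.asarray(y, dtype=float)
        uniq = np.unique(yb)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("y must be binary 0/1")
        if len(uniq) < 2:
            raise DegenerateInputError("y is constant; logistic model is degenerate")
        p = X.shape[1]
        names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
        kept, dropped = collinearity_screen(X, names, tol=self.collinearity_tol)
        A = np.column_stack([np.ones(X.shape[0]), X[:, kept]])

        def lgh(th):
            eta = A @ th
            pr = expit(eta)
            ll = float(np.sum(yb * np.log(np.clip(pr, _TINY, None))
                              + (1 - yb) * np.log(np.clip(1 - pr, _TINY, None))))
            grad = A.T @ (yb - pr)
            W = pr * (1 - pr)
            H = -(A.T @ (A * W[:, None]))
            return ll, grad, H

        def ll_only(th):
            return lgh(th)[0]

        k = np.mean(yb)
        theta0 = np.concatenate([[logit(np.clip(k, 1e-12, 1 - 1e-12))], np.zeros(len(kept))])
        theta, ll, converged, n_iter, H = _newton(
            theta0, lgh, ll_only, lambda th: True, self.max_iter, self.tol, self.grad_tol
        )
        se_all = _invert_information(H) if converged else None
        if converged and se_all is None:
            converged = False

        coef = np.full(p, np.nan)
        se = np.full(p, np.nan)
        coef[kept] = theta[1:]
        if se_all is not None:
            se[kept] = se_all[1:]
            se_int = float(se_all[0])
        else:
            se_int = float("nan")
        n1 = int(yb.sum())
        n = len(yb)
        ll_null = _null_loglik_multinomial(np.array([n - n1, n1]))

        self.classes_ = np.array([0, 1])
        self.feature_names_ = names
        self.kept_idx_ = kept
        self.coef_ = coef
        self.se_ = se
        self.intercept_ = float(theta[0])
        self.se_intercept_ = se_int
        self.loglik_ = ll
        self.loglik_null_ = ll_null
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_obs_ = n
        self.result_ = FitResult(
            names=names, coef=coef, se=se, loglik=ll, loglik_null=ll_null,
            converged=converged, n_iter=n_iter, n_obs=n,
            intercept=self.intercept_, se_intercept=se_int,
            dropped=[names[j] for j in dropped],
        )
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ np.nan_to_num(self.coef_, nan=0.0)

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def fit_proportional_odds(design, y, feature_names=None, **options) -> FitResult:
    """Functional wrapper: proportional-odds ML fit returning a FitResult."""
    return ProportionalOddsRegressor(**options).fit(design, y, feature_names).result_


def fit_logistic(design, y, feature_names=None, **options) -> FitResult:
    """Functional wrapper: binary-logistic ML fit returning a FitResult."""
    return LogisticRegressionMLE(**options).fit(design, y, feature_names).result_


def pseudo_r2(fit: FitResult, n: int | None = None, kind: str = "nagelkerke") -> float:
    """Pseudo-R² of a converged ML fit.

    Nagelkerke (default) is Cox–Snell 1 − exp(2(ll0 − ll)/n) rescaled by its
    maximum 1 − exp(2 ll0 / n); McFadden is 1 − ll/ll0.
    """
    if fit.loglik_null is None or not np.isfinite(fit.loglik_null):
        raise ValueError("fit has no null log-likelihood")
    n = fit.n_obs if n is None else n
    if kind == "mcfadden":
        return float(1.0 - fit.loglik / fit.loglik_null)
    cs = 1.0 - np.exp(2.0 * (fit.loglik_null - fit.loglik) / n)
    if kind == "cox_snell":
        return float(cs)
    if kind == "nagelkerke":
        denom = 1.0 - np.exp(2.0 * fit.loglik_null / n)
        return float(cs / denom) if denom > 0 else 0.0
    raise ValueError(f"unknown pseudo-R² kind {kind!r}")


def nagelkerke_r2(fit: FitResult, n: int | None = None) -> float:
    """Nagelkerke pseudo-R² (Cox–Snell rescaled to a [0, 1] maximum)."""
    return pseudo_r2(fit, n=n, kind="nagelkerke")
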