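"""Maximum-likelihood isoform abundance estimation under the linear
Poisson read-count model.

For condition k with category counts ``n_kj`` and rate vectors ``a_kj`` the
log-likelihood (dropping terms constant in the abundances) is

    l_k(θ_k) = Σ_j n_kj · log(Σ_i a_kij θ_ki) − Σ_i a_ki θ_ki .

Three nested models describe how the K condition-specific abundance vectors
relate:

* model 0 — no differential expression: θ_k = θ̃ for every k (I free
  parameters);
* model 1 — differential expression without differential splicing:
  θ_k = τ_k · θ̃, with the identifiability constraint Σ_k τ_k = K
  (I + K − 1 free parameters);
* model 2 — differential splicing: each θ_k free (K·I parameters).

All three MLEs are computed by EM; model 1 uses an
expectation/conditional-maximization scheme alternating the θ̃ and τ
updates, which keeps the likelihood monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .gene_model import ReadCategoryTable

__all__ = [
    "AbundanceEstimate",
    "IsoformAbundanceModel",
    "loglik",
    "fit_model0",
    "fit_model1",
    "fit_model2",
    "confidence_intervals",
]

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10000


@dataclass
class AbundanceEstimate:
    """Fitted abundances for one gene under one of the three models.

    ``theta`` is always the K×I abundance matrix; for models 0 and 1 it is
    derived from ``theta_tilde`` (and ``tau``).  ``df`` is the number of
    free parameters: I, I+K−1 or K·I.
    """

    model_id: int
    theta: np.ndarray
    loglik: float
    df: int
    n_iter: int
    converged: bool
    theta_tilde: np.ndarray | None = None
    tau: np.ndarray | None = None
    boundary: bool = False
    loglik_path: list[float] = field(default_factory=list, repr=False)

    @property
    def n_conditions(self) -> int:
        return self.theta.shape[0]

    @property
    def n_isoforms(self) -> int:
        return self.theta.shape[1]


def loglik(theta_k: np.ndarray, table: ReadCategoryTable) -> float:
    """Reduced Poisson log-likelihood of one condition at abundances θ_k.

    Returns −inf when a category with reads has zero expected rate.
    Negative abundances raise a ``ValueError``.
    """
    theta = np.asarray(theta_k, dtype=float)
    if theta.shape != (table.n_isoforms,):
        raise ValueError(
            f"theta has shape {theta.shape}, expected ({table.n_isoforms},)"
        )
    if np.any(theta < 0):
        raise ValueError("isoform abundances must be non-negative")
    mu = table.rates @ theta
    n = table.counts
    pos = n > 0
    if np.any(mu[pos] <= 0):
        return -np.inf
    return float(n[pos] @ np.log(mu[pos]) - table.isoform_totals @ theta)


def _check_tables(tables: Sequence[ReadCategoryTable]) -> int:
    if len(tables) == 0:
        raise ValueError("at least one condition is required")
    I = tables[0].n_isoforms
    if any(t.n_isoforms != I for t in tables):
        raise ValueError("conditions disagree on the number of isoforms")
    return I


def _em_single(
    counts: np.ndarray,
    rates: np.ndarray,
    totals: np.ndarray,
    tol: float,
    max_iter: int,
    theta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    """EM for a single Poisson likelihood (one condition, or model 0 on the
    stacked categories with pooled totals)."""
    I = totals.shape[0]
    mask = totals > 0
    theta = np.zeros(I)
    total_n = counts.sum()
    if total_n == 0 or not mask.any():
        ll = float(-(totals @ theta))  # zero
        return theta, ll, 0, True, [ll]
    if theta0 is not None:
        theta = np.where(mask, np.maximum(theta0, 0.0), 0.0)
        if theta[mask].sum() == 0:
            theta0 = None
    if theta0 is None:
        theta[mask] = total_n / (totals[mask].sum() * mask.sum())
    pos = counts > 0
    n_pos = counts[pos]
    r_pos = rates[pos]
    ll_old = -np.inf
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = r_pos @ theta
        w = n_pos / mu
        theta_new = np.zeros(I)
        theta_new[mask] = theta[mask] * (r_pos[:, mask].T @ w) / totals[mask]
        theta = theta_new
        ll = float(n_pos @ np.log(r_pos @ theta) - totals @ theta)
        path.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    return theta, path[-1], it, converged, path


def _fit_model2(tables, tol, max_iter):
    I = _check_tables(tables)
    K = len(tables)
    theta = np.zeros((K, I))
    ll = 0.0
    iters = 0
    conv = True
    path_total: list[float] = []
    for k, t in enumerate(tables):
        th, l, it, c, path = _em_single(
            t.counts, t.rates, t.isoform_totals, tol, max_iter
        )
        theta[k] = th
        ll += l
        iters = max(iters, it)
        conv &= c
        path_total = path if not path_total else path_total
    return AbundanceEstimate(
        model_id=2,
        theta=theta,
        loglik=ll,
        df=K * I,
        n_iter=iters,
        converged=conv,
        boundary=bool(np.any(theta == 0)),
        loglik_path=path_total,
    )


def _fit_model0(tables, tol, max_iter):
    I = _check_tables(tables)
    K = len(tables)
    counts = np.concatenate([t.counts for t in tables])
    rates = np.vstack([t.rates for t in tables])
    totals = np.sum([t.isoform_totals for t in tables], axis=0)
    theta_t, ll, it, conv, path = _em_single(counts, rates, totals, tol, max_iter)
    return AbundanceEstimate(
        model_id=0,
        theta=np.tile(theta_t, (K, 1)),
        theta_tilde=theta_t,
        loglik=ll,
        df=I,
        n_iter=it,
        converged=conv,
        boundary=bool(np.any(theta_t == 0)),
        loglik_path=path,
    )


def _model1_loglik(theta_t, tau, tables):
    return sum(loglik(tau[k] * theta_t, t) for k, t in enumerate(tables))


def _fit_model1(tables, tol, max_iter):
    I = _check_tables(tables)
    K = len(tables)
    if K < 2:
        raise ValueError("model 1 requires at least two conditions")
    totals = np.vstack([t.isoform_totals for t in tables])  # K×I
    pooled = totals.sum(axis=0)
    mask = pooled > 0
    tau = np.ones(K)
    grand_total = sum(t.counts.sum() for t in tables)
    theta_t = np.zeros(I)
    if grand_total == 0 or not mask.any():
        return AbundanceEstimate(
            model_id=1,
            theta=np.zeros((K, I)),
            theta_tilde=theta_t,
            tau=tau,
            loglik=0.0,
            df=I + K - 1,
            n_iter=0,
            converged=True,
            boundary=True,
            loglik_path=[0.0],
        )
    theta_t[mask] = grand_total / (pooled[mask].sum() * mask.sum())
    ll_old = -np.inf
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # expected reads per (condition, isoform); tau cancels in the
        # responsibilities so E depends only on theta_tilde
        E = np.zeros((K, I))
        for k, t in enumerate(tables):
            pos = t.counts > 0
            if not pos.any():
                continue
            mu = t.rates[pos] @ theta_t
            E[k] = theta_t * (t.rates[pos].T @ (t.counts[pos] / mu))
        denom = tau @ totals  # Σ_k τ_k a_ki
        theta_new = np.zeros(I)
        ok = mask & (denom > 0)
        theta_new[ok] = E.sum(axis=0)[ok] / denom[ok]
        theta_t = theta_new
        scale = totals @ theta_t  # Σ_i a_ki θ̃_i per condition
        tau = np.where(scale > 0, E.sum(axis=1) / np.where(scale > 0, scale, 1.0), 0.0)
        ll = _model1_loglik(theta_t, tau, tables)
        path.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    # rescale to the identifiability constraint Σ_k τ_k = K (likelihood-neutral)
    s = tau.sum()
    if s > 0:
        theta_t = theta_t * (s / K)
        tau = tau * (K / s)
    theta = np.outer(tau, theta_t)
    return AbundanceEstimate(
        model_id=1,
        theta=theta,
        theta_tilde=theta_t,
        tau=tau,
        loglik=path[-1],
        df=I + K - 1,
        n_iter=it,
        converged=converged,
        boundary=bool(np.any(tau <= 1e-12) or np.any(theta_t[mask] == 0)),
        loglik_path=path,
    )


class IsoformAbundanceModel(BaseEstimator):
    """Scikit-learn-style estimator for one of the three nested Poisson
    abundance models.

    Parameters
    ----------
    model : {0, 1, 2}
        Which model to fit (shared, proportional, or free abundance rows).
    tol : float
        Relative log-likelihood change declaring EM convergence.
    max_iter : int
        Iteration cap; non-convergence is reported, not raised.

    Attributes (after :meth:`fit`)
    ------------------------------
    theta_ : ndarray of shape (K, I)
        Fitted abundance matrix.
    theta_tilde_ : ndarray of shape (I,) or None
        Basic abundance vector (models 0 and 1).
    tau_ : ndarray of shape (K,) or None
        Condition fold vector with Σ τ_k = K (model 1 only).
    loglik_ : float
        Maximized reduced log-likelihood.
    df_ : int
        Number of free parameters.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, model: int = 2, tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER):
        self.model = model
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, tables: Sequence[ReadCategoryTable], y=None) -> "IsoformAbundanceModel":
        if self.model not in (0, 1, 2):
            raise ValueError("model must be 0, 1 or 2")
        fitters = {0: _fit_model0, 1: _fit_model1, 2: _fit_model2}
        est = fitters[self.model](list(tables), self.tol, self.max_iter)
        self.estimate_ = est
        self.theta_ = est.theta
        self.theta_tilde_ = est.theta_tilde
        self.tau_ = est.tau
        self.loglik_ = est.loglik
        self.df_ = est.df
        self.n_iter_ = est.n_iter
        self.converged_ = est.converged
        return self


def fit_model0(tables, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER) -> AbundanceEstimate:
    """MLE of the shared abundance vector θ̃ (no differential expression)."""
    return IsoformAbundanceModel(0, tol, max_iter).fit(tables).estimate_


def fit_model1(tables, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER) -> AbundanceEstimate:
    """MLE of (θ̃, τ) — differential expression, common splicing pattern."""
    return IsoformAbundanceModel(1, tol, max_iter).fit(tables).estimate_


def fit_model2(tables, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER) -> AbundanceEstimate:
    """Per-condition independent MLEs (differential splicing)."""
    return IsoformAbundanceModel(2, tol, max_iter).fit(tables).estimate_


def _observed_information(theta, counts, rates, boundary_eps=1e-10):
    """Observed information Σ_j n_j a_ij a_i'j / μ_j² for one Poisson block."""
    mu = rates @ theta
    pos = counts > 0
    if not pos.any():
        return np.zeros((theta.size, theta.size))
    w = counts[pos] / mu[pos] ** 2
    A = rates[pos]
    return (A * w[:, None]).T @ A


def _wald_interval(theta, info, totals, level):
    """Per-parameter Wald intervals; boundary parameters one-sided."""
    I = theta.size
    z = stats.norm.ppf(0.5 + level / 2)
    out = np.full((I, 2), np.nan)
    interior = theta > 0
    bnd = ~interior
    # one-sided exact-Poisson-style upper bound for zero estimates
    out[bnd, 0] = 0.0
    with np.errstate(divide="ignore"):
        out[bnd, 1] = np.where(
            totals[bnd] > 0, -np.log(1 - level) / totals[bnd], np.nan
        )
    if interior.any():
        sub = info[np.ix_(interior, interior)]
        try:
            cov = np.linalg.inv(sub)
            with np.errstate(invalid="ignore"):
                se = np.sqrt(np.diag(cov))
            if np.any(~np.isfinite(se)):
                raise np.linalg.LinAlgError
            out[interior, 0] = np.maximum(0.0, theta[interior] - z * se)
            out[interior, 1] = theta[interior] + z * se
        except np.linalg.LinAlgError:
            pass  # singular information: leave intervals as NA
    return out


def _numerical_hessian(f, x, rel_step=1e-4):
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                fpp = f(x + 2 * h[i] * _unit(n, i))
                fmm = f(x - 2 * h[i] * _unit(n, i))
                f0 = f(x)
                H[i, i] = (fpp - 2 * f0 + fmm) / (4 * h[i] ** 2)
            else:
                e_i, e_j = _unit(n, i), _unit(n, j)
                fpp = f(x + h[i] * e_i + h[j] * e_j)
                fpm = f(x + h[i] * e_i - h[j] * e_j)
                fmp = f(x - h[i] * e_i + h[j] * e_j)
                fmm = f(x - h[i] * e_i - h[j] * e_j)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _unit(n, i):
    e = np.zeros(n)
    e[i] = 1.0
    return e


def confidence_intervals(
    est: AbundanceEstimate,
    tables: Sequence[ReadCategoryTable],
    level: float = 0.95,
) -> dict[str, np.ndarray]:
    """Wald confidence intervals from the observed Fisher information of
    the fitted model's free parameters.

    Returns a dict keyed by parameter block: ``{"theta": (K,I,2)}`` for
    model 2, ``{"theta_tilde": (I,2)}`` for model 0, and
    ``{"theta_tilde": (I,2), "tau": (K,2)}`` for model 1.  Intervals are
    truncated below at 0; parameters estimated at the 0 boundary get a
    one-sided [0, upper]; a singular information matrix yields NA bounds.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if est.model_id == 2:
        K, I = est.theta.shape
        out = np.full((K, I, 2), np.nan)
        for k, t in enumerate(tables):
            info = _observed_information(est.theta[k], t.counts, t.rates)
            out[k] = _wald_interval(est.theta[k], info, t.isoform_totals, level)
        return {"theta": out}
    if est.model_id == 0:
        counts = np.concatenate([t.counts for t in tables])
        rates = np.vstack([t.rates for t in tables])
        totals = np.sum([t.isoform_totals for t in tables], axis=0)
        info = _observed_information(est.theta_tilde, counts, rates)
        return {"theta_tilde": _wald_interval(est.theta_tilde, info, totals, level)}
    # model 1: numerical observed information on (θ̃ interior, τ_1..τ_{K-1})
    K, I = est.theta.shape
    theta_t = est.theta_tilde
    tau = est.tau
    z = stats.norm.ppf(0.5 + level / 2)
    interior = theta_t > 0
    n_t = int(interior.sum())

    def negfree(x):
        th = np.zeros(I)
        th[interior] = x[:n_t]
        tv = np.empty(K)
        tv[: K - 1] = x[n_t:]
        tv[-1] = K - tv[: K - 1].sum()
        if np.any(th < 0) or np.any(tv < 0):
            return -np.inf
        return _model1_loglik(th, tv, tables)

    x0 = np.concatenate([theta_t[interior], tau[:-1]])
    th_ci = np.full((I, 2), np.nan)
    tau_ci = np.full((K, 2), np.nan)
    th_ci[~interior, 0] = 0.0
    pooled = np.sum([t.isoform_totals for t in tables], axis=0)
    with np.errstate(divide="ignore"):
        th_ci[~interior, 1] = np.where(
            pooled[~interior] > 0, -np.log(1 - level) / pooled[~interior], np.nan
        )
    try:
        H = _numerical_hessian(negfree, x0)
        cov = np.linalg.inv(-H)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
        if np.any(~np.isfinite(se)):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, ValueError):
        return {"theta_tilde": th_ci, "tau": tau_ci}
    th_ci[interior, 0] = np.maximum(0.0, theta_t[interior] - z * se[:n_t])
    th_ci[interior, 1] = theta_t[interior] + z * se[:n_t]
    tau_ci[: K - 1, 0] = np.maximum(0.0, tau[:-1] - z * se[n_t:])
    tau_ci[: K - 1, 1] = tau[:-1] + z * se[n_t:]
    # τ_K = K − Σ τ_free: its variance is 1'Σ1 over the free τ block
    var_last = float(np.sum(cov[n_t:, n_t:]))
    if var_last >= 0:
        se_last = np.sqrt(var_last)
        tau_ci[-1] = [max(0.0, tau[-1] - z * se_last), tau[-1] + z * se_last]
    return {"theta_tilde": th_ci, "tau": tau_ci}
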