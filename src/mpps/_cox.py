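"""Cox proportional-hazards core: Efron partial likelihood, Newton fitting.

Small dense problems only (p up to a few dozen, n up to a few thousand),
which is all the pair-selection chain ever needs. Ties in event times use
the Efron approximation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxFit", "cox_loglik", "fit_cox", "logrank_zstat"]


@dataclass
class CoxFit:
    """Result of a Newton fit of the Cox partial likelihood."""

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.coef)

    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    def wald_p(self) -> np.ndarray:
        from scipy import stats

        return 2.0 * stats.norm.sf(np.abs(self.wald_z()))


def _event_groups(time: np.ndarray, event: np.ndarray):
    """Indices of subjects grouped by distinct event time, plus risk-set order.

    Returns (order, starts, death_lists) where `order` sorts time descending,
    so the risk set of an event time is a prefix of `order`.
    """
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    groups = []  # (prefix_len, death_positions_in_order)
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        deaths = [k for k in range(i, j) if e_sorted[k] == 1]
        if deaths:
            groups.append((j, np.asarray(deaths)))
        i = j
    return order, groups


def _loglik_grad_hess_fast(X, time, event, beta, want_derivs):
    """Vectorized path for data with no tied event times (Efron == Breslow)."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    order = np.argsort(-time, kind="stable")
    t_desc = time[order]
    e_desc = event[order]
    Xo = X[order]
    wo = w[order]
    eo = eta[order]

    cum_w = np.cumsum(wo)
    ev = np.flatnonzero(e_desc == 1)
    # risk set of an event extends through any censored subjects tied with it
    pref = np.searchsorted(-t_desc, -t_desc[ev], side="right") - 1
    S = cum_w[pref]
    ll = float(eo[ev].sum() - np.log(S).sum())
    if not want_derivs:
        return ll, None, None

    wXo = wo[:, None] * Xo
    cum_wX = np.cumsum(wXo, axis=0)
    Z = cum_wX[pref]  # (m, p)
    grad = Xo[ev].sum(axis=0) - (Z / S[:, None]).sum(axis=0)
    cum_wXX = np.cumsum(wXo[:, :, None] * Xo[:, None, :], axis=0)
    B = cum_wXX[pref]
    ZS = Z / S[:, None]
    hess = -((B / S[:, None, None]).sum(axis=0) - np.einsum("mi,mj->ij", ZS, ZS))
    return ll, grad, hess


def _loglik_grad_hess(X, time, event, beta, want_derivs=True):
    n, p = X.shape
    ev_times = time[event == 1]
    if len(np.unique(ev_times)) == len(ev_times):
        return _loglik_grad_hess_fast(X, time, event, beta, want_derivs)
    eta = X @ beta
    eta = eta - eta.max()  # guards exp overflow; cancels in all ratios
    w = np.exp(eta)
    order, groups = _event_groups(time, event)
    Xo = X[order]
    wo = w[order]
    eo = eta[order]
    wXo = wo[:, None] * Xo

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    cum_w = np.cumsum(wo)
    cum_wX = np.cumsum(wXo, axis=0)
    # cumulative sum of w * x x^T, built lazily only if derivatives wanted
    if want_derivs:
        wXXo = wXo[:, :, None] * Xo[:, None, :]
        cum_wXX = np.cumsum(wXXo, axis=0)

    for prefix, deaths in groups:
        d = len(deaths)
        S_R = cum_w[prefix - 1]
        S_D = wo[deaths].sum()
        ll += eo[deaths].sum()
        if want_derivs:
            Z_R = cum_wX[prefix - 1]
            Z_D = wXo[deaths].sum(axis=0)
            M_R = cum_wXX[prefix - 1]
            M_D = (wXo[deaths][:, :, None] * Xo[deaths][:, None, :]).sum(axis=0)
            grad += Xo[deaths].sum(axis=0)
        for l in range(d):
            frac = l / d
            phi = S_R - frac * S_D
            ll -= np.log(phi)
            if want_derivs:
                z = Z_R - frac * Z_D
                grad -= z / phi
                hess -= (M_R - frac * M_D) / phi - np.outer(z, z) / phi**2

    return ll, grad, hess


def cox_loglik(X, time, event, beta) -> float:
    """Efron partial log-likelihood at a fixed coefficient vector."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    ll, _, _ = _loglik_grad_hess(X, np.asarray(time, float), np.asarray(event, int), beta, want_derivs=False)
    return float(ll)


def fit_cox(X, time, event, tol: float = 1e-7, max_iter: int = 100) -> CoxFit:
    """Newton-Raphson with step-halving on the Efron partial likelihood.

    Convergence is declared when the log partial likelihood changes by less
    than `tol` between iterations.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if event.sum() == 0:
        raise ValueError("no events in cohort: Cox model cannot be fitted")

    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(X, time, event, beta)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # hess is the Hessian of the loglik (negative semidefinite)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving until the likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, _, _ = _loglik_grad_hess(X, time, event, cand, want_derivs=False)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            break
        beta = cand
        improved = ll_new - ll
        ll, grad, hess = _loglik_grad_hess(X, time, event, beta)
        if abs(improved) < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    if not converged or not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)) or np.any(se == 0):
        converged = converged and bool(np.all(np.isfinite(beta)))
    return CoxFit(coef=beta, se=se, loglik=float(ll), loglik_null=float(ll_null), n_iter=it, converged=converged)


def logrank_zstat(high: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E)/sqrt(V) for `high` vs rest.

    Uses the hypergeometric variance at each distinct event time. Returns 0.0
    when the variance is zero (e.g. one group has left the risk set).
    """
    high = np.asarray(high, dtype=bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    h = high[order]
    n = len(t)

    n_at_risk = n
    n1_at_risk = int(h.sum())
    O = 0.0
    E = 0.0
    V = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0 and 0 < n1_at_risk < n_at_risk:
            d1 = int((e[i:j] & h[i:j]).sum())
            O += d1
            E += d * n1_at_risk / n_at_risk
            if n_at_risk > 1:
                V += (
                    d
                    * (n1_at_risk / n_at_risk)
                    * (1 - n1_at_risk / n_at_risk)
                    * (n_at_risk - d)
                    / (n_at_risk - 1)
                )
        elif d > 0:
            d1 = int((e[i:j] & h[i:j]).sum())
            O += d1
            E += d * n1_at_risk / n_at_risk
        n_at_risk -= j - i
        n1_at_risk -= int(h[i:j].sum())
        i = j
    if V <= 0:
        return 0.0
    return float((O - E) / np.sqrt(V))
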