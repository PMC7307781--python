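"""Survival and regression estimators, implemented from first principles.

Kaplan-Meier product-limit curves, the Mantel-Haenszel logrank test,
univariate Cox proportional hazards (Newton-Raphson on the partial
likelihood, Breslow or Efron ties), univariate ordinary least squares and
the Pearson product-moment correlation.  The estimators are
scikit-learn-style classes (``fit``, ``get_params``/``set_params``,
trailing-underscore fitted attributes); the module-level functions are thin
wrappers over them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats as spstats
from sklearn.base import BaseEstimator

__all__ = [
    "KaplanMeierEstimator",
    "CoxPHRegressor",
    "SimpleLinearRegression",
    "LogrankResult",
    "km_fit",
    "logrank_test",
    "cox_fit_univariate",
    "ols_univariate",
    "pearson_corr",
    "significance_stars",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _check_survival(time, event):
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel().astype(int)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if time.size == 0:
        raise ValueError("need at least one subject")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and > 0")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicators must be 0 or 1")
    return time, event


class KaplanMeierEstimator(BaseEstimator):
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Fitted attributes: ``event_times_`` (distinct event times),
    ``survival_`` (S at those times), ``at_risk_`` (n_i), ``events_`` (d_i).
    """

    def fit(self, time, event=None):
        if event is None:
            event = np.ones_like(np.asarray(time, dtype=float))
        time, event = _check_survival(time, event)
        order = np.argsort(time, kind="stable")
        t, e = time[order], event[order]
        n = t.size
        uniq = np.unique(t[e == 1])
        at_risk, d, surv = [], [], []
        s = 1.0
        for u in uniq:
            ni = int(np.sum(t >= u))
            di = int(np.sum((t == u) & (e == 1)))
            s *= 1.0 - di / ni
            at_risk.append(ni)
            d.append(di)
            surv.append(s)
        self.event_times_ = uniq
        self.survival_ = np.asarray(surv)
        self.at_risk_ = np.asarray(at_risk)
        self.events_ = np.asarray(d)
        self.n_subjects_ = n
        return self

    def predict(self, times) -> np.ndarray:
        """Step-function survival probability at arbitrary times."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if self.event_times_.size == 0:
            return np.ones_like(times)
        idx = np.searchsorted(self.event_times_, times, side="right") - 1
        return np.where(idx < 0, 1.0, self.survival_[np.clip(idx, 0, None)])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def _cox_loglik(beta: float, time, event, x, ties: str):
    """Partial log-likelihood with gradient and negative Hessian (information)."""
    order = np.argsort(-time, kind="stable")  # descending: cumulative = risk set
    t, e, xv = time[order], event[order], x[order]
    theta = np.exp(beta * xv)
    s0 = np.cumsum(theta)
    s1 = np.cumsum(xv * theta)
    s2 = np.cumsum(xv * xv * theta)

    ll = grad = info = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        # risk set for time t[i] is everything up to index j (times >= t[i])
        ev = np.flatnonzero(e[i : j + 1] == 1) + i
        d = ev.size
        if d > 0:
            S0, S1, S2 = s0[j], s1[j], s2[j]
            xs = xv[ev]
            if ties == "breslow" or d == 1:
                ll += beta * xs.sum() - d * math.log(S0)
                grad += xs.sum() - d * S1 / S0
                info += d * (S2 / S0 - (S1 / S0) ** 2)
            elif ties == "efron":
                td = np.exp(beta * xs)
                D0, D1, D2 = td.sum(), (xs * td).sum(), (xs * xs * td).sum()
                ll += beta * xs.sum()
                for k in range(d):
                    f = k / d
                    R0 = S0 - f * D0
                    R1 = S1 - f * D1
                    R2 = S2 - f * D2
                    ll -= math.log(R0)
                    grad += -R1 / R0
                    info += R2 / R0 - (R1 / R0) ** 2
                grad += xs.sum()
            else:
                raise ValueError("ties must be 'breslow' or 'efron'")
        i = j + 1
    return ll, grad, info


class CoxPHRegressor(BaseEstimator):
    """Univariate Cox proportional hazards via Newton-Raphson from beta = 0.

    Parameters
    ----------
    ties : {"breslow", "efron"}
        Tie-handling convention for the partial likelihood.
    tol : float
        Convergence threshold on |delta beta|.
    max_iter : int
        Newton iteration cap.

    Fitted attributes include ``coef_``, ``se_``, ``hazard_ratio_``,
    ``conf_int_`` (95% Wald), ``z_``, ``p_value_``, ``log_likelihood_``,
    and the three auxiliary tests ``lrt_``, ``wald_test_``, ``score_test_``
    as ``(statistic, p)`` pairs.
    """

    def __init__(self, ties: str = "breslow", tol: float = 1e-9, max_iter: int = 50):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y_time, y_event):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("univariate model: X must have one column")
            x = x[:, 0]
        time, event = _check_survival(y_time, y_event)
        if x.shape != time.shape:
            raise ValueError("X must match the number of subjects")
        if event.sum() == 0:
            raise ValueError("no events observed")
        if np.ptp(x[event == 1]) == 0 and np.ptp(x) == 0:
            raise ValueError("covariate is constant")

        ll0, grad0, info0 = _cox_loglik(0.0, time, event, x, self.ties)
        if info0 <= 0:
            raise ValueError("covariate is constant within every risk set")

        beta, converged = 0.0, False
        ll = ll0
        for it in range(1, self.max_iter + 1):
            ll, grad, info = _cox_loglik(beta, time, event, x, self.ties)
            if info <= 0:
                break
            step = grad / info
            beta += step
            if abs(step) < self.tol:
                converged = True
                break
        if not converged or abs(beta) * np.ptp(x) > 500:
            if not converged:
                warnings.warn(
                    "Cox partial likelihood did not converge "
                    "(monotone likelihood / separation?); beta may diverge",
                    RuntimeWarning,
                )
        ll, grad, info = _cox_loglik(beta, time, event, x, self.ties)
        if info <= 0:
            raise ValueError(
                "degenerate fit: no covariate information in the risk sets"
            )
        se = 1.0 / math.sqrt(info)

        self.coef_ = beta
        self.se_ = se
        self.hazard_ratio_ = math.exp(beta)
        self.conf_int_ = (math.exp(beta - Z_95 * se), math.exp(beta + Z_95 * se))
        self.z_ = beta / se
        self.p_value_ = 2.0 * spstats.norm.sf(abs(self.z_))
        self.log_likelihood_ = ll
        self.null_log_likelihood_ = ll0
        lrt = 2.0 * (ll - ll0)
        self.lrt_ = (lrt, float(spstats.chi2.sf(lrt, 1)))
        wald = self.z_**2
        self.wald_test_ = (wald, float(spstats.chi2.sf(wald, 1)))
        score = grad0**2 / info0
        self.score_test_ = (score, float(spstats.chi2.sf(score, 1)))
        self.converged_ = converged
        self.n_iter_ = it
        self.n_subjects_ = time.size
        self.n_events_ = int(event.sum())
        return self

    def predict(self, X) -> np.ndarray:
        """Partial hazard exp(beta * x)."""
        x = np.asarray(X, dtype=float).ravel()
        return np.exp(self.coef_ * x)


class SimpleLinearRegression(BaseEstimator):
    """Closed-form univariate least squares, y = intercept + slope*x.

    Fitted attributes: ``slope_``, ``intercept_``, ``se_slope_``, ``t_``,
    ``f_`` (on (1, n-2) df), ``r_squared_`` (the squared Pearson r of x and
    y), ``p_value_``, ``n_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        n = x.size
        if n < 3:
            raise ValueError("need n >= 3 for inference")
        sxx = np.sum((x - x.mean()) ** 2)
        if sxx == 0:
            raise ValueError("x is constant")
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - (intercept + slope * x)
        sse = float(np.sum(resid**2))
        syy = float(np.sum((y - y.mean()) ** 2))
        sigma2 = sse / (n - 2)
        se = math.sqrt(sigma2 / sxx) if sigma2 > 0 else 0.0
        t = slope / se if se > 0 else math.inf * np.sign(slope)
        r2 = 1.0 - sse / syy if syy > 0 else 0.0
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.se_slope_ = se
        self.t_ = float(t)
        self.f_ = float(t * t)
        self.r_squared_ = float(r2)
        self.p_value_ = float(2.0 * spstats.t.sf(abs(t), n - 2)) if se > 0 else 0.0
        self.n_ = n
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return self.intercept_ + self.slope_ * x


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def km_fit(time, event=None) -> KaplanMeierEstimator:
    return KaplanMeierEstimator().fit(time, event)


def logrank_test(time1, event1, time2, event2) -> LogrankResult:
    """Two-group Mantel-Haenszel logrank test (df = 1).

    chi2 = (sum_j (O_1j - E_1j))^2 / sum_j V_j with the hypergeometric
    variance V_j at each distinct event time; identical to the Cox score
    test with a binary group indicator under Breslow ties.
    """
    t1, e1 = _check_survival(time1, event1)
    t2, e2 = _check_survival(time2, event2)
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in either group: logrank undefined")
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros_like(t1), np.ones_like(t2)])
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(t[e == 1]):
        at = t >= u
        n = at.sum()
        n1 = int((at & (g == 1)).sum())
        d = int(((t == u) & (e == 1)).sum())
        d1 = int(((t == u) & (e == 1) & (g == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        raise ValueError("degenerate risk sets: zero logrank variance")
    chi2 = o_minus_e**2 / var
    return LogrankResult(
        statistic=float(chi2), df=1, p_value=float(spstats.chi2.sf(chi2, 1))
    )


def cox_fit_univariate(time, event, x, ties: str = "breslow") -> CoxPHRegressor:
    return CoxPHRegressor(ties=ties).fit(np.asarray(x, dtype=float), time, event)


def ols_univariate(x, y) -> SimpleLinearRegression:
    return SimpleLinearRegression().fit(x, y)


def pearson_corr(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    xd, yd = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(np.sum(xd**2)), np.sqrt(np.sum(yd**2))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.clip(np.sum(xd * yd) / (sx * sy), -1.0, 1.0))


def f_stat_from_r_squared(r_squared: float, n: int) -> float:
    """F statistic of a univariate regression implied by its R^2:
    F = (n - 2) * R^2 / (1 - R^2) on (1, n - 2) df."""
    if not 0 <= r_squared < 1:
        raise ValueError("R^2 must lie in [0, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    return (n - 2) * r_squared / (1.0 - r_squared)


__all__.append("f_stat_from_r_squared")
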