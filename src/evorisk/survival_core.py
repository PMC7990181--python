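"""Censored-outcome statistical kernel.

Implements the Cox partial likelihood under the sign convention used
throughout the package: the hazard of sample *i* is ``h(t) * exp(-beta' X_i)``
and the risk score is ``eta_i = -beta' X_i`` (larger eta = larger hazard).
Ties in event times are handled with the Breslow approximation.  Also
provides the concordance index with strict inequalities, the two-group
logrank test and the Kaplan-Meier product-limit estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class DegenerateLikelihoodError(ValueError):
    """Partial likelihood carries no information (e.g. all samples censored)."""


class UndefinedMetricError(ValueError):
    """A metric has no defined value on this input (e.g. no comparable pairs)."""


@dataclass
class CoxModel:
    """Fitted Cox model: coefficients over named features plus diagnostics."""

    feature_names: list[str]
    beta: np.ndarray
    converged: bool = True
    n_iter: int = 0
    final_nll: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def risk_scores(self, X: np.ndarray) -> np.ndarray:
        """eta = -beta' X for each row of X."""
        return -np.asarray(X, dtype=float) @ self.beta

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_names),
            "beta": [float(b) for b in self.beta],
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "final_nll": float(self.final_nll),
            "flags": list(self.flags),
        }


@dataclass
class KMCurve:
    """Product-limit estimate: survival probability after each event time."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class LogrankResult:
    z2: float
    p: float


def _as_arrays(y, delta):
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if y.shape != delta.shape:
        raise ValueError("y and delta must have the same shape")
    return y, delta


# ---------------------------------------------------------------------------
# Partial likelihood
# ---------------------------------------------------------------------------


def _risk_set_index(y_desc: np.ndarray) -> np.ndarray:
    """For each position k in a descending-time sort, the index of the last
    position sharing the same time (risk set = everything up to that index)."""
    return np.searchsorted(-y_desc, -y_desc, side="right") - 1


def cox_nll(beta, X, y, delta, want_hess: bool = False):
    """Negative log partial likelihood (Breslow ties) with gradient.

    Parameters follow the package sign convention: the log-hazard linear
    predictor is ``theta_i = -X_i beta``.  Returns ``(nll, grad)`` or
    ``(nll, grad, hess)`` when ``want_hess``.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    y, delta = _as_arrays(y, delta)
    if delta.sum() == 0:
        raise DegenerateLikelihoodError("all samples censored: partial likelihood is constant")
    order = np.argsort(-y, kind="stable")
    Xs, ys, ds = X[order], y[order], delta[order]
    theta = -Xs @ beta
    m = theta.max()
    w = np.exp(theta - m)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
    tie_end = _risk_set_index(ys)
    ev = ds == 1
    denom = cum_w[tie_end[ev]]
    nll = float(np.sum(np.log(denom) + m - theta[ev]))
    xbar = cum_wx[tie_end[ev]] / denom[:, None]
    grad = np.sum(Xs[ev] - xbar, axis=0)
    if not want_hess:
        return nll, grad
    cum_wxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    s2 = cum_wxx[tie_end[ev]] / denom[:, None, None]
    hess = np.sum(s2 - xbar[:, :, None] * xbar[:, None, :], axis=0)
    return nll, grad, hess


def _soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def cox_fit(
    X,
    y,
    delta,
    feature_names=None,
    l1_penalty: float = 0.0,
    tol: float = 1e-7,
    max_iter: int = 500,
    separation_bound: float = 15.0,
) -> CoxModel:
    """Fit the Cox model by Newton iteration (l1_penalty=0) or proximal
    gradient (lasso).

    Non-convergence or apparent separation (coefficients running off to the
    ``separation_bound``) is flagged on the returned model rather than
    raised, per the "flagged model, not silent success" contract.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one column")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    beta = np.zeros(p)
    flags: list[str] = []

    if l1_penalty < 0:
        raise ValueError("l1_penalty must be >= 0")

    if l1_penalty == 0.0:
        nll, grad, hess = cox_nll(beta, X, y, delta, want_hess=True)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            ridge = 1e-9 * max(1.0, float(np.trace(hess)) / p)
            try:
                step = np.linalg.solve(hess + ridge * np.eye(p), -grad)
            except np.linalg.LinAlgError:
                step = -grad
            alpha = 1.0
            for _ in range(40):
                cand = beta + alpha * step
                new_nll, new_grad, new_hess = cox_nll(cand, X, y, delta, want_hess=True)
                if np.isfinite(new_nll) and new_nll <= nll:
                    break
                alpha *= 0.5
            else:  # no descent: fall back to a small gradient step
                cand = beta - 1e-4 * grad
                new_nll, new_grad, new_hess = cox_nll(cand, X, y, delta, want_hess=True)
            improved = nll - new_nll
            beta, nll, grad, hess = cand, new_nll, new_grad, new_hess
            if np.max(np.abs(beta)) > separation_bound:
                flags.append("separation")
                break
            if improved < tol:
                converged = True
                break
        if np.max(np.abs(beta)) > separation_bound and "separation" not in flags:
            flags.append("separation")  # converged numerically but |beta| exploded
        if "separation" in flags:
            converged = False
        elif not converged:
            flags.append("non_convergence")
        return CoxModel(list(feature_names), beta, converged, it, nll, flags)

    # lasso: ISTA with backtracking on the smooth part
    nll, grad = cox_nll(beta, X, y, delta)
    step_size = 1.0
    converged = False
    it = 0
    for it in range(1, max(max_iter, 2000) + 1):
        while True:
            cand = _soft_threshold(beta - step_size * grad, step_size * l1_penalty)
            diff = cand - beta
            cand_nll, cand_grad = cox_nll(cand, X, y, delta)
            quad = nll + grad @ diff + (diff @ diff) / (2 * step_size)
            if cand_nll <= quad + 1e-12 or step_size < 1e-12:
                break
            step_size *= 0.5
        move = float(np.max(np.abs(cand - beta)))
        beta, nll, grad = cand, cand_nll, cand_grad
        if move < 1e-6:
            converged = True
            break
    if not converged:
        flags.append("non_convergence")
    if np.max(np.abs(beta)) > separation_bound:
        flags.append("separation")
    return CoxModel(list(feature_names), beta, converged, it, float(nll), flags)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def concordance_index(eta, y, delta) -> float:
    """Concordance index with strict inequalities.

    ``CI = sum_{i,j} delta_i 1(y_j > y_i, eta_j < eta_i) /
    sum_{i,j} delta_i 1(y_j > y_i)``; ties in time or risk contribute
    nothing to the numerator.
    """
    eta = np.asarray(eta, dtype=float)
    y, delta = _as_arrays(y, delta)
    later = y[None, :] > y[:, None]  # y_j > y_i
    comparable = (delta == 1)[:, None] & later
    den = int(comparable.sum())
    if den == 0:
        raise UndefinedMetricError("no comparable pairs: concordance index undefined")
    concordant = comparable & (eta[None, :] < eta[:, None])
    return float(concordant.sum()) / den


def logrank(y_a, delta_a, y_b, delta_b) -> LogrankResult:
    """Two-group logrank test: ``z^2 = (sum(O - E))^2 / sum(V)`` with the
    hypergeometric variance at each distinct event time; p from chi^2_1."""
    y_a, delta_a = _as_arrays(y_a, delta_a)
    y_b, delta_b = _as_arrays(y_b, delta_b)
    if len(y_a) == 0 or len(y_b) == 0:
        raise ValueError("both groups must be non-empty")
    if delta_a.sum() + delta_b.sum() == 0:
        raise UndefinedMetricError("no events in either group: logrank undefined")
    event_times = np.unique(np.concatenate([y_a[delta_a == 1], y_b[delta_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int((y_a >= t).sum())
        n_b = int((y_b >= t).sum())
        n = n_a + n_b
        d_a = int(((y_a == t) & (delta_a == 1)).sum())
        d_b = int(((y_b == t) & (delta_b == 1)).sum())
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0.0:
        return LogrankResult(z2=0.0, p=1.0)
    z2 = o_minus_e**2 / var
    return LogrankResult(z2=float(z2), p=float(stats.chi2.sf(z2, df=1)))


def km_curve(y, delta) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored times reduce risk sets without introducing steps; the curve is
    evaluated after each distinct event time.
    """
    y, delta = _as_arrays(y, delta)
    if len(y) == 0:
        raise ValueError("need at least one record")
    event_times = np.unique(y[delta == 1])
    surv = []
    s = 1.0
    for t in event_times:
        n_t = int((y >= t).sum())
        d_t = int(((y == t) & (delta == 1)).sum())
        s *= 1.0 - d_t / n_t
        surv.append(s)
    return KMCurve(times=event_times, survival=np.asarray(surv, dtype=float))
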