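"""Univariate Cox proportional-hazards regression on log2 expression.

The model is h(t | x) = h0(t) * exp(beta * x) with x the log2-transformed
expression, so exp(beta) is the hazard ratio per one log2 unit, i.e. per
2-fold expression increase.  The partial likelihood uses the Efron tie
correction (Breslow available), maximized by Newton iteration from beta = 0
with the standard error taken from the inverse observed information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .survival import SurvivalCohort

_Z975 = 1.959964  # Phi^{-1}(0.975)


class CoxConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class CoxResult:
    """Fitted univariate Cox model.

    ``hr`` = exp(beta) is the hazard multiplier per +1 unit of the covariate;
    with a log2 covariate that is the multiplier per 2-fold expression
    increase.  ``ci95`` = exp(beta -/+ 1.959964 * se).
    """

    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    n: int
    n_events: int
    ties_method: str
    n_iter: int
    loglik: float

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"Cox univariate (ties={self.ties_method}): "
            f"beta={self.beta:.4f} (se={self.se:.4f}), "
            f"HR per 2-fold={self.hr:.3f} [{lo:.3f}, {hi:.3f}], "
            f"Wald p={self.wald_p:.3g}, n={self.n}, events={self.n_events}"
        )

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "hr": self.hr,
            "ci95": list(self.ci95),
            "wald_p": self.wald_p,
            "n": self.n,
            "n_events": self.n_events,
            "ties_method": self.ties_method,
        }


def _loglik_grad_hess(
    beta: float,
    x: np.ndarray,
    first: np.ndarray,
    d_count: np.ndarray,
    event_sorted: np.ndarray,
    ties: str,
) -> tuple[float, float, float]:
    """Efron/Breslow partial log-likelihood and derivatives, one covariate.

    Arrays are pre-sorted by ascending time; ``first`` indexes the start of
    each distinct-time block, ``d_count`` the number of deaths per block.
    """
    eta = beta * x
    w = np.exp(eta)
    xw = x * w
    x2w = x * xw
    # suffix (risk-set) sums evaluated at each block start
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(xw[::-1])[::-1]
    s2 = np.cumsum(x2w[::-1])[::-1]
    r0, r1, r2 = s0[first], s1[first], s2[first]

    dmask = event_sorted > 0
    # per-block sums over the deaths
    dw = np.add.reduceat(np.where(dmask, w, 0.0), first)
    dxw = np.add.reduceat(np.where(dmask, xw, 0.0), first)
    dx2w = np.add.reduceat(np.where(dmask, x2w, 0.0), first)
    dx = np.add.reduceat(np.where(dmask, x, 0.0), first)

    ev = d_count > 0
    d = d_count[ev].astype(float)
    if ties == "efron":
        # expand each event block into d rows with fractions l/d, l=0..d-1
        reps = d_count[ev].astype(int)
        idx = np.repeat(np.arange(d.size), reps)
        l_over_d = (
            np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
        ) / np.repeat(d, reps)
        phi0 = r0[ev][idx] - l_over_d * dw[ev][idx]
        phi1 = r1[ev][idx] - l_over_d * dxw[ev][idx]
        phi2 = r2[ev][idx] - l_over_d * dx2w[ev][idx]
    else:  # breslow
        reps = d_count[ev].astype(int)
        idx = np.repeat(np.arange(d.size), reps)
        phi0, phi1, phi2 = r0[ev][idx], r1[ev][idx], r2[ev][idx]

    loglik = float(beta * dx[ev].sum() - np.log(phi0).sum())
    mean = phi1 / phi0
    grad = float(dx[ev].sum() - mean.sum())
    hess = float((phi2 / phi0 - mean**2).sum())  # observed information
    return loglik, grad, hess


def cox_univariate(
    cohort: SurvivalCohort,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
    beta_bound: float = 50.0,
) -> CoxResult:
    """Fit the univariate Cox model by Newton iteration from beta = 0.

    Raises on a constant covariate, on monotone-likelihood separation
    (|beta| exceeding ``beta_bound``) and on non-convergence.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if cohort.n_events < 2:
        raise ValueError("need at least 2 events")

    order = np.argsort(cohort.time, kind="stable")
    t = cohort.time[order]
    e = cohort.event[order]
    x = cohort.expr[order].astype(float)
    _, first = np.unique(t, return_index=True)
    d_count = np.add.reduceat(e.astype(int), first)

    if np.ptp(x) == 0:
        raise ValueError("covariate has no variation")
    # center for numerical stability; beta is translation-invariant
    shift = float(x.mean())
    xc = x - shift

    beta = 0.0
    loglik = np.nan
    for it in range(1, max_iter + 1):
        loglik, grad, hess = _loglik_grad_hess(beta, xc, first, d_count, e, ties)
        if hess <= 0 or not np.isfinite(hess):
            if it == 1:
                raise ValueError("covariate has no variation")
            # the information vanishes while the score does not: monotone
            # likelihood, the estimate is drifting without bound
            raise CoxConvergenceError("separation detected")
        step = grad / hess
        # dampen wild steps far from the optimum
        step = float(np.clip(step, -5.0, 5.0))
        beta_new = beta + step
        if abs(beta_new) > beta_bound:
            raise CoxConvergenceError("separation detected")
        converged = abs(beta_new - beta) < tol
        beta = beta_new
        if converged:
            break
    else:
        raise CoxConvergenceError("Newton iteration did not converge")

    _, _, hess = _loglik_grad_hess(beta, xc, first, d_count, e, ties)
    se = float(1.0 / np.sqrt(hess))
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - _Z975 * se)), float(np.exp(beta + _Z975 * se)))
    z = beta / se
    wald_p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=hr,
        ci95=ci,
        wald_p=wald_p,
        n=cohort.n,
        n_events=cohort.n_events,
        ties_method=ties,
        n_iter=it,
        loglik=float(loglik),
    )


class CoxUnivariate:
    """Model-object wrapper: ``CoxUnivariate(cohort).fit()`` -> CoxResult."""

    def __init__(self, cohort: SurvivalCohort):
        self.cohort = cohort

    @classmethod
    def from_dataframe(cls, df, time="time", event="event", expr="expr"):
        return cls(SurvivalCohort.from_dataframe(df, time, event, expr))

    def fit(self, **kwargs) -> CoxResult:
        return cox_univariate(self.cohort, **kwargs)
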