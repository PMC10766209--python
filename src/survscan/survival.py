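"""Right-censored survival primitives: cohorts, Kaplan-Meier, log-rank.

The log-rank statistic is computed simultaneously for many binary splits of
the same cohort (one split per candidate expression threshold); the
single-split public function is a thin wrapper over that grid kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateSplitError(ValueError):
    """Raised when a requested two-group comparison is undefined."""


@dataclass(frozen=True)
class SurvivalCohort:
    """Per-patient follow-up time, event indicator and one continuous covariate.

    Parameters
    ----------
    time : array of positive follow-up times (consistent unit, e.g. months).
    event : array of {0, 1}; 1 = event observed, 0 = right-censored.
    expr : array of log2-transformed expression values, one per patient.
    patient_ids : optional identifiers; defaults to 0..n-1 as strings.
    """

    time: np.ndarray
    event: np.ndarray
    expr: np.ndarray
    patient_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        expr = np.asarray(self.expr, dtype=float)
        if not (time.ndim == event.ndim == expr.ndim == 1):
            raise ValueError("time, event and expr must be 1-dimensional")
        n = time.size
        if not (event.size == n and expr.size == n):
            raise ValueError("time, event and expr must have equal length")
        if n < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if np.any(time <= 0) or not np.all(np.isfinite(time)):
            raise ValueError("all times must be finite and > 0")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if not np.all(np.isfinite(expr)):
            raise ValueError("expression values must be finite")
        pids = self.patient_ids
        if pids is None:
            pids = np.array([str(i) for i in range(n)], dtype=object)
        else:
            pids = np.asarray(pids, dtype=object)
            if pids.size != n:
                raise ValueError("patient_ids length mismatch")
            if len(set(pids)) != n:
                raise ValueError("patient_ids must be unique")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))
        object.__setattr__(self, "expr", expr)
        object.__setattr__(self, "patient_ids", pids)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        event: str = "event",
        expr: str = "expr",
        patient_id: str | None = None,
    ) -> "SurvivalCohort":
        pids = df[patient_id].to_numpy() if patient_id else None
        return cls(
            time=df[time].to_numpy(float),
            event=df[event].to_numpy(),
            expr=df[expr].to_numpy(float),
            patient_ids=pids,
        )

    def with_expr(self, expr: np.ndarray) -> "SurvivalCohort":
        """Same follow-up data, different covariate."""
        return SurvivalCohort(self.time, self.event, expr, self.patient_ids)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "survival": self.survival.tolist(),
            "at_risk": self.at_risk.tolist(),
            "n_subjects": self.n_subjects,
        }


def km_estimate(cohort: SurvivalCohort, mask: np.ndarray | None = None) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i<=t} (1 - d_i/n_i).

    ``mask`` restricts the estimate to a subset of the cohort.  A subset with
    no events yields the flat curve S == 1 over an empty event-time grid.
    """
    if mask is None:
        mask = np.ones(cohort.n, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty subset")
    t = cohort.time[mask]
    e = cohort.event[mask]
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ut, first = np.unique(t, return_index=True)
    n_at_risk = t.size - first
    d = np.add.reduceat(e, first)
    ev = d > 0
    times = ut[ev]
    surv = np.cumprod(1.0 - d[ev] / n_at_risk[ev])
    return KMCurve(times, surv, n_at_risk[ev].astype(int), int(t.size))


def _logrank_grid(
    time: np.ndarray,
    event: np.ndarray,
    member: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-group log-rank statistics for many splits of one cohort at once.

    Parameters
    ----------
    member : bool array (n_patients, n_splits); True marks the "high" group.

    Returns
    -------
    (chi2, observed_minus_expected, variance) per split.  At each distinct
    event time the observed high-group deaths are compared with the
    hypergeometric expectation d * n1/n, with the multi-death hypergeometric
    variance d * (n1/n)(1 - n1/n)(n - d)/(n - 1).  Splits where the total
    variance is zero (the risk sets never mix) return statistic 0 because
    O - E is identically 0 there.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    g = member[order]
    n = t.size
    ut, first = np.unique(t, return_index=True)
    at_risk = (n - first).astype(float)
    d = np.add.reduceat(e.astype(float), first)
    # suffix[i] = number of high-group members with time >= t[i]
    suffix = np.cumsum(g[::-1], axis=0)[::-1].astype(float)
    n1 = suffix[first]
    d1 = np.add.reduceat(g & (e[:, None] > 0), first, axis=0).astype(float)

    ev = d > 0
    frac = n1[ev] / at_risk[ev, None]
    dd = d[ev, None]
    rr = at_risk[ev, None]
    o_minus_e = (d1[ev] - dd * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_t = dd * frac * (1.0 - frac) * (rr - dd) / (rr - 1.0)
    var_t = np.where(rr > 1.0, var_t, 0.0)
    var = var_t.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0.0, o_minus_e**2 / var, 0.0)
    return chi2, o_minus_e, var


def logrank_statistic(
    cohort: SurvivalCohort, high: np.ndarray
) -> tuple[float, float]:
    """Standard two-group log-rank test.

    ``high`` is a boolean membership vector.  Returns (chi-square statistic,
    p-value from the chi-square(1) reference distribution).  The statistic is
    invariant to exchanging the two group labels.
    """
    high = np.asarray(high, dtype=bool)
    if high.size != cohort.n:
        raise ValueError("group labels length mismatch")
    if high.all() or not high.any():
        raise DegenerateSplitError("both groups must be non-empty")
    if cohort.n_events == 0:
        raise DegenerateSplitError("no events")
    chi2, _, _ = _logrank_grid(cohort.time, cohort.event, high[:, None])
    stat = float(chi2[0])
    return stat, float(stats.chi2.sf(stat, df=1))


def stratify(cohort: SurvivalCohort, threshold: float) -> dict:
    """Split a cohort at an expression threshold: high iff expr > threshold.

    Ties at the threshold fall into the low group (strict-greater rule).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    high = cohort.expr > threshold
    labels = np.where(high, "high", "low")
    return {
        "labels": labels,
        "high": high,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "threshold": float(threshold),
    }
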