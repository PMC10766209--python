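"""Optimal-cutpoint survival stratification with a permutation-corrected p.

The procedure: every quantile level of the expression distribution (default
0.10 .. 0.90, step 0.01 -> 81 candidates) is tried as a dividing threshold;
samples with expression strictly greater than the threshold form the "high"
group; the two-group log-rank statistic is computed for each admissible
split and the threshold with the largest statistic is the optimal cutpoint.

Because the cutoff is chosen to maximize the statistic, the naive
chi-square(1) p-value of the winning split is anti-conservative.  The
permutation test therefore re-runs the *entire* scan — re-optimizing the
cutoff — on each of N permutations of the (time, event) pairs against the
fixed expression vector, and reports the fraction of permutation maxima
exceeding the observed maximum.

A joint "universal threshold" search maximizes the average log-rank
statistic of two expression variables split at the same absolute level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .cox import CoxResult, cox_univariate
from .survival import KMCurve, SurvivalCohort, _logrank_grid, km_estimate, stratify

logger = logging.getLogger(__name__)


class NoAdmissibleCutpointError(ValueError):
    pass


@dataclass(frozen=True)
class CutpointScan:
    """Per-quantile-level thresholds and log-rank statistics, plus the optimum.

    ``statistics`` holds NaN at skipped levels (a group smaller than
    ``min_group``).  ``best_*`` describe the maximal-statistic level; ties
    are broken toward the smallest quantile level.
    """

    quantile_levels: np.ndarray
    thresholds: np.ndarray
    statistics: np.ndarray
    skipped: np.ndarray
    best_level: float
    best_threshold: float
    best_statistic: float
    min_group: int

    @property
    def n_skipped(self) -> int:
        return int(self.skipped.sum())

    @property
    def naive_p(self) -> float:
        """Chi-square(1) p of the best statistic, ignoring cutoff selection."""
        return float(_sps.chi2.sf(self.best_statistic, df=1))

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "quantile_level": self.quantile_levels,
                "threshold": self.thresholds,
                "statistic": self.statistics,
                "skipped": self.skipped,
            }
        )

    def to_dict(self) -> dict:
        return {
            "quantile_levels": self.quantile_levels.tolist(),
            "thresholds": self.thresholds.tolist(),
            "statistics": [None if not np.isfinite(s) else float(s) for s in self.statistics],
            "skipped": self.skipped.tolist(),
            "best_level": self.best_level,
            "best_threshold": self.best_threshold,
            "best_statistic": self.best_statistic,
            "naive_p": self.naive_p,
            "min_group": self.min_group,
        }


@dataclass(frozen=True)
class PermutationResult:
    """Null distribution of re-optimized scan maxima and the resulting p.

    ``p_value`` follows ``exceed_rule``: "strict" is the plain fraction of
    null maxima strictly greater than the observed one (can be exactly 0);
    "add_one" is the conservative (1 + #{null >= obs}) / (N + 1) estimator.
    Both are always available via ``p_strict`` / ``p_add_one``.
    """

    observed: float
    null_stats: np.ndarray
    n_permutations: int
    p_value: float
    exceed_rule: str
    seed: int | None
    n_failed_scans: int

    @property
    def p_strict(self) -> float:
        return float(np.mean(self.null_stats > self.observed))

    @property
    def p_add_one(self) -> float:
        return float(
            (1.0 + np.sum(self.null_stats >= self.observed))
            / (self.n_permutations + 1.0)
        )

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed": self.observed,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "p_strict": self.p_strict,
            "p_add_one": self.p_add_one,
            "exceed_rule": self.exceed_rule,
            "seed": self.seed,
            "n_failed_scans": self.n_failed_scans,
        }
        if include_null:
            d["null_stats"] = self.null_stats.tolist()
        return d


@dataclass(frozen=True)
class UniversalThresholdResult:
    """Shared absolute expression threshold maximizing the mean log-rank statistic."""

    threshold: float
    avg_statistic: float
    statistic_a: float
    statistic_b: float
    per_variable_p: tuple[float, float]
    avg_p: float
    candidate_grid: np.ndarray
    avg_statistics: np.ndarray

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "avg_statistic": self.avg_statistic,
            "statistic_a": self.statistic_a,
            "statistic_b": self.statistic_b,
            "per_variable_p": list(self.per_variable_p),
            "avg_p": self.avg_p,
            "p_convention": "mean of per-variable permutation p at the fixed shared grid",
            "n_candidates": int(self.candidate_grid.size),
        }


def default_quantile_levels(
    q_lo: float = 0.10, q_hi: float = 0.90, q_step: float = 0.01
) -> np.ndarray:
    n = int(round((q_hi - q_lo) / q_step))
    return q_lo + q_step * np.arange(n + 1)


class _PermutationKernel:
    """Re-scores a fixed membership matrix against permuted (time, event).

    Jointly permuting the (time, event) pairs against the fixed expression
    vector is equivalent to permuting the rows of the membership matrix
    against the fixed, pre-sorted follow-up data, so everything that depends
    only on the time axis (risk-set sizes, death counts, variance
    coefficients) is computed once.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, member: np.ndarray):
        order = np.argsort(time, kind="stable")
        e = event[order]
        n = time.size
        _, first = np.unique(time[order], return_index=True)
        d = np.add.reduceat(e.astype(float), first)
        at_risk = (n - first).astype(float)
        ev = d > 0
        self.first = first
        self.ev = ev
        self.n = n
        self.dd = d[ev, None]
        rr = at_risk[ev, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            self.vcoef = np.where(rr > 1.0, self.dd * (rr - self.dd) / (rr - 1.0), 0.0)
        self.inv_rr = 1.0 / rr
        # membership rows aligned to the sorted time axis
        self.gf = member[order].astype(float)
        # death rows and, within them, the starts of each event-time block;
        # the event vector stays fixed to the time axis under permutation
        drows = np.flatnonzero(e > 0)
        block_of_death = np.searchsorted(first, drows, side="right") - 1
        self.drows = drows
        self.dfirst = np.flatnonzero(
            np.diff(block_of_death, prepend=block_of_death[0] - 1)
        )

    def max_statistic(self, perm: np.ndarray) -> float:
        """Maximal log-rank chi-square over the splits for one permutation."""
        gf = self.gf[perm]
        block = np.add.reduceat(gf, self.first, axis=0)
        n1 = np.cumsum(block[::-1], axis=0)[::-1][self.ev]
        d1 = np.add.reduceat(gf[self.drows], self.dfirst, axis=0)
        frac = n1 * self.inv_rr
        o_minus_e = (d1 - self.dd * frac).sum(axis=0)
        var = (self.vcoef * frac * (1.0 - frac)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(var > 0.0, o_minus_e**2 / var, 0.0)
        return float(chi2.max())


def _grid_statistics(
    time: np.ndarray,
    event: np.ndarray,
    member: np.ndarray,
    admissible: np.ndarray,
) -> np.ndarray:
    """Log-rank chi-square per split; NaN where inadmissible."""
    out = np.full(member.shape[1], np.nan)
    if admissible.any():
        chi2, _, _ = _logrank_grid(time, event, member[:, admissible])
        out[admissible] = chi2
    return out


def _admissible_columns(member: np.ndarray, min_group: int) -> np.ndarray:
    n = member.shape[0]
    n_high = member.sum(axis=0)
    return (n_high >= min_group) & (n - n_high >= min_group)


def _pick_best(levels: np.ndarray, statistics: np.ndarray) -> int:
    """Index of the maximal statistic; smallest level wins ties."""
    if not np.isfinite(statistics).any():
        raise NoAdmissibleCutpointError("no admissible cutpoint")
    best = np.nanmax(statistics)
    return int(np.flatnonzero(statistics == best)[0])


def scan_cutpoints(
    cohort: SurvivalCohort,
    q_lo: float = 0.10,
    q_hi: float = 0.90,
    q_step: float = 0.01,
    min_group: int = 2,
) -> CutpointScan:
    """Quantile-grid cutoff scan maximizing the two-group log-rank statistic.

    Thresholds are the linear-interpolation quantiles of the expression
    values; the high group is ``expr > threshold`` (strict).  Levels leaving
    either group below ``min_group`` members are skipped.
    """
    if cohort.n_events < 1:
        raise ValueError("cohort has no events")
    if cohort.n < 2 * min_group:
        raise ValueError("cohort smaller than 2 * min_group")
    levels = default_quantile_levels(q_lo, q_hi, q_step)
    thresholds = np.quantile(cohort.expr, levels)  # linear interpolation
    member = cohort.expr[:, None] > thresholds[None, :]
    admissible = _admissible_columns(member, min_group)
    statistics = _grid_statistics(cohort.time, cohort.event, member, admissible)
    best = _pick_best(levels, statistics)
    return CutpointScan(
        quantile_levels=levels,
        thresholds=thresholds,
        statistics=statistics,
        skipped=~admissible,
        best_level=float(levels[best]),
        best_threshold=float(thresholds[best]),
        best_statistic=float(statistics[best]),
        min_group=min_group,
    )


def permutation_test(
    cohort: SurvivalCohort,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    exceed_rule: str = "strict",
    q_lo: float = 0.10,
    q_hi: float = 0.90,
    q_step: float = 0.01,
    min_group: int = 2,
    observed: float | None = None,
) -> PermutationResult:
    """Cutoff-re-optimizing permutation test for the maximal log-rank statistic.

    Each permutation jointly shuffles the (time, event) pairs against the
    fixed expression vector and re-runs the full cutpoint scan; the maximal
    statistic over the grid is recorded.  Permutations where no admissible
    split exists contribute a statistic of 0 and stay in the denominator.
    """
    if exceed_rule not in ("strict", "add_one"):
        raise ValueError("exceed_rule must be 'strict' or 'add_one'")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    elif seed is None or isinstance(seed, (int, np.integer)):
        rng, seed_out = np.random.default_rng(seed), (None if seed is None else int(seed))
    else:
        raise TypeError("seed must be an int, a Generator, or None")
    if n_permutations < 100:
        logger.warning(
            "n_permutations=%d is small; p-value resolution is 1/%d",
            n_permutations,
            n_permutations,
        )

    if observed is None:
        observed = scan_cutpoints(cohort, q_lo, q_hi, q_step, min_group).best_statistic

    levels = default_quantile_levels(q_lo, q_hi, q_step)
    thresholds = np.quantile(cohort.expr, levels)
    member = cohort.expr[:, None] > thresholds[None, :]
    # the thresholds depend only on expr, which a permutation leaves fixed,
    # so re-running the scan reduces to re-scoring a fixed membership matrix
    admissible = _admissible_columns(member, min_group)
    member_adm = member[:, admissible]

    null_stats = np.empty(n_permutations)
    n_failed = 0
    if not admissible.any():
        null_stats[:] = 0.0
        n_failed = n_permutations
    else:
        kernel = _PermutationKernel(cohort.time, cohort.event, member_adm)
        for i in range(n_permutations):
            null_stats[i] = kernel.max_statistic(rng.permutation(cohort.n))
    if n_failed:
        logger.info("%d permutation scans had no admissible split", n_failed)

    p_strict = float(np.mean(null_stats > observed))
    p_add_one = float((1.0 + np.sum(null_stats >= observed)) / (n_permutations + 1.0))
    return PermutationResult(
        observed=float(observed),
        null_stats=null_stats,
        n_permutations=n_permutations,
        p_value=p_strict if exceed_rule == "strict" else p_add_one,
        exceed_rule=exceed_rule,
        seed=seed_out,
        n_failed_scans=n_failed,
    )


def _fixed_grid_permutation_p(
    cohort: SurvivalCohort,
    grid: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    min_group: int,
    exceed_rule: str,
) -> float:
    """Permutation p for the max log-rank statistic over a fixed absolute grid."""
    member = cohort.expr[:, None] > grid[None, :]
    admissible = _admissible_columns(member, min_group)
    if not admissible.any():
        raise NoAdmissibleCutpointError("no admissible candidate")
    member_adm = member[:, admissible]
    chi2, _, _ = _logrank_grid(cohort.time, cohort.event, member_adm)
    observed = chi2.max()
    null = np.empty(n_permutations)
    kernel = _PermutationKernel(cohort.time, cohort.event, member_adm)
    for i in range(n_permutations):
        null[i] = kernel.max_statistic(rng.permutation(cohort.n))
    if exceed_rule == "strict":
        return float(np.mean(null > observed))
    return float((1.0 + np.sum(null >= observed)) / (n_permutations + 1.0))


def universal_threshold(
    cohort_a: SurvivalCohort,
    cohort_b: SurvivalCohort,
    candidate_grid: np.ndarray | None = None,
    q_lo: float = 0.10,
    q_hi: float = 0.90,
    q_step: float = 0.01,
    min_group: int = 2,
    n_permutations: int = 1000,
    seed: int | None = None,
    exceed_rule: str = "strict",
) -> UniversalThresholdResult:
    """Joint threshold search: maximize the mean of two log-rank statistics.

    The two cohorts share the patient universe but carry different expression
    variables.  Each candidate absolute level splits both cohorts with the
    strict-greater rule; candidates where either split is inadmissible are
    skipped.  The per-variable p-values are permutation p-values for the
    maximal statistic over the same fixed grid, and ``avg_p`` is their mean.
    """
    if cohort_a.n != cohort_b.n or not np.array_equal(
        cohort_a.patient_ids, cohort_b.patient_ids
    ):
        raise ValueError("cohorts must share the same patients in the same order")
    if candidate_grid is None:
        levels = default_quantile_levels(q_lo, q_hi, q_step)
        grid = np.union1d(
            np.quantile(cohort_a.expr, levels), np.quantile(cohort_b.expr, levels)
        )
    else:
        grid = np.unique(np.asarray(candidate_grid, dtype=float))

    member_a = cohort_a.expr[:, None] > grid[None, :]
    member_b = cohort_b.expr[:, None] > grid[None, :]
    adm = _admissible_columns(member_a, min_group) & _admissible_columns(
        member_b, min_group
    )
    stats_a = _grid_statistics(cohort_a.time, cohort_a.event, member_a, adm)
    stats_b = _grid_statistics(cohort_b.time, cohort_b.event, member_b, adm)
    avg = 0.5 * (stats_a + stats_b)
    best = _pick_best(grid, avg)

    rng = np.random.default_rng(seed)
    grid_adm = grid[adm]
    p_a = _fixed_grid_permutation_p(
        cohort_a, grid_adm, n_permutations, rng, min_group, exceed_rule
    )
    p_b = _fixed_grid_permutation_p(
        cohort_b, grid_adm, n_permutations, rng, min_group, exceed_rule
    )
    return UniversalThresholdResult(
        threshold=float(grid[best]),
        avg_statistic=float(avg[best]),
        statistic_a=float(stats_a[best]),
        statistic_b=float(stats_b[best]),
        per_variable_p=(p_a, p_b),
        avg_p=float(0.5 * (p_a + p_b)),
        candidate_grid=grid,
        avg_statistics=avg,
    )


class CutpointSurvival:
    """Optimal-cutpoint survival model for one expression variable.

    ``fit()`` runs the quantile-grid scan, the cutoff-re-optimizing
    permutation test and (by default) the univariate Cox regression, and
    returns a :class:`CutpointSurvivalResults`.

    Examples
    --------
    >>> model = CutpointSurvival.from_dataframe(df, time="months",
    ...                                         event="death", expr="log2_fpkm")
    >>> res = model.fit(n_permutations=10_000, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, cohort: SurvivalCohort):
        self.cohort = cohort

    @classmethod
    def from_dataframe(cls, df, time="time", event="event", expr="expr",
                       patient_id=None):
        return cls(SurvivalCohort.from_dataframe(df, time, event, expr, patient_id))

    @classmethod
    def from_arrays(cls, time, event, expr, patient_ids=None):
        return cls(SurvivalCohort(time, event, expr, patient_ids))

    def scan(self, **kwargs) -> CutpointScan:
        return scan_cutpoints(self.cohort, **kwargs)

    def fit(
        self,
        q_lo: float = 0.10,
        q_hi: float = 0.90,
        q_step: float = 0.01,
        min_group: int = 2,
        n_permutations: int = 10_000,
        seed: int | None = None,
        exceed_rule: str = "strict",
        run_cox: bool = True,
        cox_ties: str = "efron",
    ) -> "CutpointSurvivalResults":
        scan = scan_cutpoints(self.cohort, q_lo, q_hi, q_step, min_group)
        perm = permutation_test(
            self.cohort,
            n_permutations=n_permutations,
            seed=seed,
            exceed_rule=exceed_rule,
            q_lo=q_lo,
            q_hi=q_hi,
            q_step=q_step,
            min_group=min_group,
            observed=scan.best_statistic,
        )
        cox = cox_univariate(self.cohort, ties=cox_ties) if run_cox else None
        return CutpointSurvivalResults(self.cohort, scan, perm, cox)


class CutpointSurvivalResults:
    """Scan + permutation inference + Cox fit for one cohort."""

    def __init__(
        self,
        cohort: SurvivalCohort,
        scan: CutpointScan,
        permutation: PermutationResult,
        cox: CoxResult | None,
    ):
        self.cohort = cohort
        self.scan = scan
        self.permutation = permutation
        self.cox = cox

    @property
    def best_threshold(self) -> float:
        return self.scan.best_threshold

    @property
    def p_value(self) -> float:
        return self.permutation.p_value

    def stratify(self) -> dict:
        return stratify(self.cohort, self.scan.best_threshold)

    def km_curves(self) -> dict[str, KMCurve]:
        high = self.stratify()["high"]
        return {
            "low": km_estimate(self.cohort, ~high),
            "high": km_estimate(self.cohort, high),
        }

    def summary(self) -> str:
        s = self.scan
        p = self.permutation
        lines = [
            "Optimal-cutpoint survival stratification",
            "----------------------------------------",
            f"n = {self.cohort.n}, events = {self.cohort.n_events}",
            f"grid: {s.quantile_levels[0]:.2f}..{s.quantile_levels[-1]:.2f} "
            f"({s.quantile_levels.size} levels, {s.n_skipped} skipped)",
            f"optimal cutpoint: level {s.best_level:.2f} "
            f"(threshold {s.best_threshold:.4f}), log-rank chi2 = "
            f"{s.best_statistic:.4f}",
            f"permutation p ({p.n_permutations} perms, {p.exceed_rule}): "
            f"{p.p_value:.4g}  [strict {p.p_strict:.4g}, add-one {p.p_add_one:.4g}]",
            f"naive chi2(1) p (no selection correction): {s.naive_p:.4g}",
        ]
        if self.cox is not None:
            lines.append(self.cox.summary())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "scan": self.scan.to_dict(),
            "permutation": self.permutation.to_dict(),
            "cox": None if self.cox is None else self.cox.to_dict(),
            "km_curves": {k: v.to_dict() for k, v in self.km_curves().items()},
            "stratification": {
                k: v
                for k, v in self.stratify().items()
                if k in ("n_high", "n_low", "threshold")
            },
        }


class UniversalThreshold:
    """Model object for the joint two-variable threshold search."""

    def __init__(self, cohort_a: SurvivalCohort, cohort_b: SurvivalCohort):
        self.cohort_a = cohort_a
        self.cohort_b = cohort_b

    def fit(self, **kwargs) -> UniversalThresholdResult:
        return universal_threshold(self.cohort_a, self.cohort_b, **kwargs)
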