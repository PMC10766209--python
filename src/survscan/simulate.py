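"""Synthetic data with known ground truth for every pipeline stage.

Three generators: right-censored survival cohorts whose hazard depends on a
continuous log2-expression covariate (through a planted step threshold, or
log-linearly for Cox recovery), paired signed DEG sets with a planted
concordant/discordant overlap composition, and negative-binomial count
matrices with per-sample depth factors and an optional asymmetric DE
fraction for normalization tests.

Every generator is deterministic under a fixed seed and returns its ground
truth next to the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .expression import CountMatrix
from .overlap import SignedGeneSet
from .survival import SurvivalCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated right-censored survival cohort.

    ``cut_quantile`` plants the threshold as a quantile of the realized
    expression values (set ``cut_level`` instead to plant an absolute log2
    level).  ``hr_high`` multiplies the exponential baseline hazard above
    the threshold when ``effect="step"``; with ``effect="loglinear"`` the
    hazard is baseline * hr_high**(expr - expr_mean), i.e. hr_high is the
    hazard ratio per one log2 unit (per 2-fold expression).  Censoring is
    exponential with ``censor_rate`` (default baseline/4, which under a null
    effect censors ~20% of patients) and/or administrative at ``admin_time``.
    """

    n: int = 300
    baseline_rate: float = 0.1
    cut_quantile: float | None = 0.5
    cut_level: float | None = None
    hr_high: float = 1.0
    expr_mean: float = 6.5
    expr_sd: float = 1.5
    censor_rate: float | None = None
    admin_time: float | None = None
    effect: str = "step"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.baseline_rate <= 0 or self.hr_high <= 0 or self.expr_sd <= 0:
            raise ValueError("rates, hazard ratios and sd must be positive")
        if self.effect not in ("step", "loglinear"):
            raise ValueError("effect must be 'step' or 'loglinear'")
        if self.effect == "step":
            if (self.cut_quantile is None) == (self.cut_level is None):
                raise ValueError("set exactly one of cut_quantile / cut_level")
            if self.cut_quantile is not None and not (0 < self.cut_quantile < 1):
                raise ValueError("cut_quantile must lie in (0, 1)")


def simulate_cohort(spec: CohortSpec) -> tuple[SurvivalCohort, dict]:
    """Draw a cohort; return (cohort, ground-truth record)."""
    rng = np.random.default_rng(spec.seed)
    expr = rng.normal(spec.expr_mean, spec.expr_sd, spec.n)

    if spec.effect == "step":
        if spec.cut_quantile is not None:
            threshold = float(np.quantile(expr, spec.cut_quantile))
        else:
            threshold = float(spec.cut_level)
        hazard = spec.baseline_rate * np.where(expr > threshold, spec.hr_high, 1.0)
        truth = {
            "effect": "step",
            "threshold": threshold,
            "cut_quantile": spec.cut_quantile,
            "hr_high": spec.hr_high,
        }
    else:
        hazard = spec.baseline_rate * spec.hr_high ** (expr - spec.expr_mean)
        truth = {
            "effect": "loglinear",
            "hr_per_log2": spec.hr_high,
            "beta": float(np.log(spec.hr_high)),
        }

    event_time = rng.exponential(1.0 / hazard)
    censor_rate = (
        spec.baseline_rate / 4.0 if spec.censor_rate is None else spec.censor_rate
    )
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, spec.n)
    else:
        censor_time = np.full(spec.n, np.inf)
    if spec.admin_time is not None:
        censor_time = np.minimum(censor_time, spec.admin_time)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    # exponential draws are continuous; clip pathological zeros
    time = np.maximum(time, np.finfo(float).tiny)
    if event.mean() < 0.05:
        warnings.warn("fewer than 5% of patients experience the event", stacklevel=2)
    truth["event_fraction"] = float(event.mean())
    cohort = SurvivalCohort(time=time, event=event, expr=expr)
    return cohort, truth


@dataclass(frozen=True)
class DEGPairSpec:
    """Planted composition of two signed DEG sets over a universe of size G."""

    universe_size: int
    n_a: int
    n_b: int
    n_concordant: int = 0
    n_discordant: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        shared = self.n_concordant + self.n_discordant
        if shared > min(self.n_a, self.n_b):
            raise ValueError("planted overlap exceeds the smaller set")
        if max(self.n_a, self.n_b) > self.universe_size:
            raise ValueError("set size exceeds the universe")
        if self.n_a + self.n_b - shared > self.universe_size:
            raise ValueError("sets cannot fit in the universe with this overlap")


def simulate_deg_pair(spec: DEGPairSpec) -> tuple[SignedGeneSet, SignedGeneSet, dict]:
    """Two signed sets with exactly the planted overlap composition."""
    rng = np.random.default_rng(spec.seed)
    shared = spec.n_concordant + spec.n_discordant
    n_needed = spec.n_a + spec.n_b - shared
    pool = rng.permutation(spec.universe_size)[:n_needed]
    conc = pool[: spec.n_concordant]
    disc = pool[spec.n_concordant : shared]
    only_a = pool[shared : shared + (spec.n_a - shared)]
    only_b = pool[shared + (spec.n_a - shared) :]

    members_a: dict = {}
    members_b: dict = {}
    for gidx in conc:
        s = int(rng.integers(0, 2)) * 2 - 1
        members_a[f"g{gidx}"] = s
        members_b[f"g{gidx}"] = s
    for gidx in disc:
        s = int(rng.integers(0, 2)) * 2 - 1
        members_a[f"g{gidx}"] = s
        members_b[f"g{gidx}"] = -s
    for gidx in only_a:
        members_a[f"g{gidx}"] = int(rng.integers(0, 2)) * 2 - 1
    for gidx in only_b:
        members_b[f"g{gidx}"] = int(rng.integers(0, 2)) * 2 - 1

    truth = {
        "n_concordant": spec.n_concordant,
        "n_discordant": spec.n_discordant,
        "n_shared": shared,
    }
    return (
        SignedGeneSet(spec.universe_size, members_a),
        SignedGeneSet(spec.universe_size, members_b),
        truth,
    )


@dataclass(frozen=True)
class CountSpec:
    """Negative-binomial count matrix with per-sample depth factors.

    Gene-level base means are log-normal (``mean_log_mu``, ``sd_log_mu`` on
    the natural-log scale); the NB variance is mu + dispersion * mu^2
    (dispersion 0 = Poisson).  A ``de_fraction`` of genes receives a
    ``de_fold`` change in the samples listed in ``de_samples``.
    """

    n_genes: int = 2000
    n_samples: int = 4
    mean_log_mu: float = 4.0
    sd_log_mu: float = 1.5
    dispersion: float = 0.1
    depth_factors: tuple = None  # type: ignore[assignment]
    de_fraction: float = 0.0
    de_fold: float = 4.0
    de_samples: tuple = None  # type: ignore[assignment]
    gene_length_range: tuple = (300, 10_000)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        depth = self.depth_factors
        if depth is None:
            depth = tuple(1.0 for _ in range(self.n_samples))
        depth = tuple(float(d) for d in depth)
        if len(depth) != self.n_samples or any(d <= 0 for d in depth):
            raise ValueError("depth_factors must be positive, one per sample")
        object.__setattr__(self, "depth_factors", depth)
        de_samples = self.de_samples
        if de_samples is None:
            de_samples = (self.n_samples - 1,)
        object.__setattr__(self, "de_samples", tuple(int(j) for j in de_samples))
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")


def simulate_counts(spec: CountSpec) -> tuple[CountMatrix, dict]:
    """Draw a count matrix; return (matrix, ground-truth record)."""
    rng = np.random.default_rng(spec.seed)
    base_mu = np.exp(rng.normal(spec.mean_log_mu, spec.sd_log_mu, spec.n_genes))
    mu = base_mu[:, None] * np.asarray(spec.depth_factors)[None, :]

    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_genes = rng.permutation(spec.n_genes)[:n_de]
    for j in spec.de_samples:
        mu[de_genes, j] *= spec.de_fold

    if spec.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        # NB with var = mu + dispersion * mu^2: shape r = 1/dispersion
        r = 1.0 / spec.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    lengths = rng.integers(
        spec.gene_length_range[0], spec.gene_length_range[1] + 1, spec.n_genes
    )
    cm = CountMatrix(
        gene_ids=[f"g{i}" for i in range(spec.n_genes)],
        gene_lengths_bp=lengths,
        sample_ids=[f"s{j}" for j in range(spec.n_samples)],
        counts=counts,
    )
    truth = {
        "depth_factors": list(spec.depth_factors),
        "de_genes": [f"g{i}" for i in sorted(de_genes)],
        "de_samples": list(spec.de_samples),
        "de_fold": spec.de_fold,
    }
    return cm, truth
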