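"""Directional overlap of differentially-expressed gene sets.

A DEG set is "signed": each member carries the direction of its expression
change (+1 up, -1 down), derived from a DE table by the FDR < 0.05 and
|fold change| >= 1.5 thresholds.  The Monte-Carlo test draws, in each
iteration, two random gene sets of the observed cardinalities from the
universe of protein-coding genes, assigns each drawn gene an independent
fair-coin sign, and compares the intersection cardinality (concordant,
discordant, or total shared, selectable) with the observed one; the p-value
is the fraction of iterations whose statistic exceeds the observed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_MODES = ("concordant", "discordant", "shared")


@dataclass(frozen=True)
class DETable:
    """Differential-expression results: gene, log2 FC, p, FDR."""

    gene_ids: list
    log2_fc: np.ndarray
    p_value: np.ndarray
    fdr: np.ndarray | None = None

    def __post_init__(self) -> None:
        fc = np.asarray(self.log2_fc, dtype=float)
        p = np.asarray(self.p_value, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if fc.size != len(self.gene_ids) or p.size != len(self.gene_ids):
            raise ValueError("columns must align with gene_ids")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        fdr = self.fdr
        if fdr is None:
            fdr = bh_adjust(p)
        else:
            fdr = np.asarray(fdr, dtype=float)
            if np.any((fdr < 0) | (fdr > 1)):
                raise ValueError("FDR values must lie in [0, 1]")
        object.__setattr__(self, "log2_fc", fc)
        object.__setattr__(self, "p_value", p)
        object.__setattr__(self, "fdr", fdr)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        gene: str = "gene",
        log2_fc: str = "log2fc",
        p_value: str = "pvalue",
        fdr: str | None = "padj",
    ) -> "DETable":
        return cls(
            gene_ids=list(df[gene]),
            log2_fc=df[log2_fc].to_numpy(float),
            p_value=df[p_value].to_numpy(float),
            fdr=df[fdr].to_numpy(float) if fdr and fdr in df.columns else None,
        )


@dataclass(frozen=True)
class SignedGeneSet:
    """Genes with a direction sign (+1 / -1) within a universe of size G."""

    universe_size: int
    members: dict

    def __post_init__(self) -> None:
        if len(self.members) > self.universe_size:
            raise ValueError("more members than the universe allows")
        if any(s not in (1, -1) for s in self.members.values()):
            raise ValueError("signs must be +1 or -1")

    def __len__(self) -> int:
        return len(self.members)

    def flipped(self) -> "SignedGeneSet":
        """Same genes with all directions reversed (contrast reorientation)."""
        return SignedGeneSet(self.universe_size,
                             {g: -s for g, s in self.members.items()})


@dataclass(frozen=True)
class OverlapResult:
    n_shared: int
    n_concordant: int
    n_discordant: int
    statistic_mode: str
    observed_statistic: int
    n_iterations: int
    p_value: float
    p_strict: float
    p_add_one: float
    exceed_rule: str
    seed: int | None
    p_by_mode: dict

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "statistic_mode": self.statistic_mode,
            "observed_statistic": self.observed_statistic,
            "n_iterations": self.n_iterations,
            "p_value": self.p_value,
            "p_strict": self.p_strict,
            "p_add_one": self.p_add_one,
            "exceed_rule": self.exceed_rule,
            "seed": self.seed,
            "p_by_mode": self.p_by_mode,
        }

    def summary(self) -> str:
        return (
            f"signed overlap: shared={self.n_shared} "
            f"(concordant={self.n_concordant}, discordant={self.n_discordant}); "
            f"MC p[{self.statistic_mode}]={self.p_value:.4g} "
            f"(N={self.n_iterations}, {self.exceed_rule})"
        )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def make_signed_set(
    det: DETable,
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
    universe_size: int | None = None,
) -> SignedGeneSet:
    """Signed DEG set: fdr < fdr_max and |fold change| >= fc_min.

    The fold-change threshold is applied as |log2 FC| >= log2(fc_min); the
    sign of the retained gene is the sign of its log2 FC.  Genes with a
    log2 FC of exactly 0 cannot carry a direction and are excluded with a
    logged note.
    """
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1")
    if universe_size is None:
        universe_size = len(det.gene_ids)
    if universe_size < len(det.gene_ids):
        raise ValueError("universe_size smaller than the DE table")
    lfc_min = np.log2(fc_min)
    members = {}
    n_zero = 0
    for g, lfc, q in zip(det.gene_ids, det.log2_fc, det.fdr):
        if q < fdr_max and abs(lfc) >= lfc_min:
            if lfc == 0:
                n_zero += 1
                continue
            members[g] = 1 if lfc > 0 else -1
    if n_zero:
        logger.info("%d significant genes had log2FC == 0 and were excluded", n_zero)
    return SignedGeneSet(universe_size=universe_size, members=members)


def concordant_overlap(a: SignedGeneSet, b: SignedGeneSet) -> tuple[int, int, int]:
    """(n_shared, n_concordant, n_discordant) of two signed sets."""
    if a.universe_size != b.universe_size:
        raise ValueError("sets must share the same universe size")
    shared = a.members.keys() & b.members.keys()
    conc = sum(1 for g in shared if a.members[g] == b.members[g])
    return len(shared), conc, len(shared) - conc


def mc_overlap_test(
    a: SignedGeneSet,
    b: SignedGeneSet,
    n_iterations: int = 10_000,
    statistic_mode: str = "concordant",
    seed: int | np.random.Generator | None = None,
    exceed_rule: str = "strict",
) -> OverlapResult:
    """Monte-Carlo test for the directional overlap of two signed gene sets.

    Each iteration draws two uniform random subsets of the universe without
    replacement, with the observed cardinalities, assigns independent +/-1
    signs, and records the intersection statistics in all three modes.  The
    p-value (per ``exceed_rule``) compares the observed statistic of the
    selected mode with its null draws.
    """
    if statistic_mode not in _MODES:
        raise ValueError(f"statistic_mode must be one of {_MODES}")
    if exceed_rule not in ("strict", "add_one"):
        raise ValueError("exceed_rule must be 'strict' or 'add_one'")
    g = a.universe_size
    if b.universe_size != g:
        raise ValueError("sets must share the same universe size")
    n_a, n_b = len(a), len(b)
    if n_a > g or n_b > g:
        raise ValueError("set larger than universe")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed

    n_shared, n_conc, n_disc = concordant_overlap(a, b)
    observed = {"concordant": n_conc, "discordant": n_disc, "shared": n_shared}

    null = {m: np.empty(n_iterations, dtype=np.int64) for m in _MODES}
    # draw the smaller set first so the result is exactly symmetric in (a, b)
    n1, n2 = sorted((n_a, n_b))
    sign_a = np.empty(g, dtype=np.int8)
    sign_b = np.empty(g, dtype=np.int8)
    for i in range(n_iterations):
        idx_a = rng.permutation(g)[:n1]
        idx_b = rng.permutation(g)[:n2]
        sign_a[:] = 0
        sign_b[:] = 0
        sign_a[idx_a] = rng.integers(0, 2, n1) * 2 - 1
        sign_b[idx_b] = rng.integers(0, 2, n2) * 2 - 1
        both = (sign_a != 0) & (sign_b != 0)
        k = int(both.sum())
        c = int((sign_a[both] == sign_b[both]).sum())
        null["shared"][i] = k
        null["concordant"][i] = c
        null["discordant"][i] = k - c

    p_by_mode = {}
    for m in _MODES:
        obs_m = observed[m]
        p_by_mode[m] = {
            "strict": float(np.mean(null[m] > obs_m)),
            "add_one": float(
                (1.0 + np.sum(null[m] >= obs_m)) / (n_iterations + 1.0)
            ),
        }
    p_strict = p_by_mode[statistic_mode]["strict"]
    p_add_one = p_by_mode[statistic_mode]["add_one"]
    return OverlapResult(
        n_shared=n_shared,
        n_concordant=n_conc,
        n_discordant=n_disc,
        statistic_mode=statistic_mode,
        observed_statistic=observed[statistic_mode],
        n_iterations=n_iterations,
        p_value=p_strict if exceed_rule == "strict" else p_add_one,
        p_strict=p_strict,
        p_add_one=p_add_one,
        exceed_rule=exceed_rule,
        seed=None if seed_out is None else int(seed_out),
        p_by_mode=p_by_mode,
    )


def hypergeom_overlap_test(n_a: int, n_b: int, g: int, k_observed: int) -> float:
    """Upper-tail hypergeometric overlap p-value: P(K >= k_observed).

    K is the overlap of two fixed-size subsets drawn uniformly from a
    universe of g genes, i.e. K ~ Hypergeometric(g, n_a, n_b).
    """
    if not (0 <= k_observed <= min(n_a, n_b) <= g) or max(n_a, n_b) > g:
        raise ValueError("infeasible counts for a hypergeometric overlap")
    return float(stats.hypergeom.sf(k_observed - 1, g, n_a, n_b))


def spearman_fc_concordance(
    fc_a, fc_b, r_min: float = 0.3, fdr_max: float = 0.05, fdr: float | None = None
) -> dict:
    """Spearman rank correlation of paired fold changes.

    Returns rho, the t-approximation p-value, n, and a significance label
    following the |r| > r_min and FDR < fdr_max rule (the raw p is used when
    no multiplicity-adjusted value is supplied).
    """
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank-degenerate input: constant vector")
    rho, p = stats.spearmanr(a, b)
    q = p if fdr is None else fdr
    return {
        "rho": float(rho),
        "p": float(p),
        "n": int(a.size),
        "significant": bool(abs(rho) > r_min and q < fdr_max),
    }
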