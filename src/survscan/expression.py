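"""Count-matrix preparation: TMM normalization, log2(FPKM+1), filtering.

TMM (trimmed mean of M-values) estimates relative RNA-composition factors
between samples from doubly trimmed log count ratios against a reference
sample; FPKM then uses the TMM-scaled effective library sizes.  The
background-noise filter is a filterByExpr-style rule: a gene is kept when
its count clears a library-size-rescaled minimum in enough samples and its
total count clears a floor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountMatrix:
    """Raw read counts (genes x samples) with per-gene lengths."""

    gene_ids: list
    gene_lengths_bp: np.ndarray
    sample_ids: list
    counts: np.ndarray
    group_labels: list | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        lengths = np.asarray(self.gene_lengths_bp)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_genes, n_samples)")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        if lengths.shape != (len(self.gene_ids),) or np.any(lengths <= 0):
            raise ValueError("gene_lengths_bp must be positive, one per gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.group_labels is not None and len(self.group_labels) != len(
            self.sample_ids
        ):
            raise ValueError("group_labels length mismatch")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "gene_lengths_bp", lengths.astype(np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, lengths: pd.Series,
                       group_labels=None) -> "CountMatrix":
        """Counts indexed by gene id, columns = samples; lengths aligned by id."""
        lengths = lengths.reindex(df.index)
        if lengths.isna().any():
            missing = list(lengths.index[lengths.isna()])[:5]
            raise ValueError(f"missing gene lengths, e.g. {missing}")
        return cls(
            gene_ids=list(df.index),
            gene_lengths_bp=lengths.to_numpy(),
            sample_ids=list(df.columns),
            counts=df.to_numpy(),
            group_labels=list(group_labels) if group_labels is not None else None,
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CountMatrix(
            gene_ids=[g for g, m in zip(self.gene_ids, mask) if m],
            gene_lengths_bp=self.gene_lengths_bp[mask],
            sample_ids=self.sample_ids,
            counts=self.counts[mask],
            group_labels=self.group_labels,
        )


@dataclass(frozen=True)
class NormalizationFactors:
    sample_ids: list
    factors: np.ndarray
    reference_sample: str
    trim_m: float
    trim_a: float

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if np.any(f <= 0):
            raise ValueError("factors must be positive")
        object.__setattr__(self, "factors", f)

    def factor_for(self, sample_id) -> float:
        return float(self.factors[self.sample_ids.index(sample_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "factor": self.factors})


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression values, by default on the log2(FPKM+1) scale."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    scale_tag: str = "log2_fpkm_plus1"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape must be (n_genes, n_samples)")
        if self.scale_tag == "log2_fpkm_plus1" and np.any(v < 0):
            raise ValueError("log2(FPKM+1) values cannot be negative")
        object.__setattr__(self, "values", v)

    def row(self, gene_id) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _choose_reference(counts: np.ndarray) -> int:
    """Sample whose upper-quartile count fraction is closest to the mean fraction."""
    lib = counts.sum(axis=0).astype(float)
    q75 = np.array([np.quantile(counts[:, j], 0.75) for j in range(counts.shape[1])])
    frac = q75 / lib
    return int(np.argmin(np.abs(frac - frac.mean())))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Raw (un-centered) TMM factor of one sample against the reference.

    Genes with a zero count in either sample are excluded; the remaining
    M-values (log2 ratio of library-size-scaled counts) are doubly trimmed —
    the top/bottom trim_m by M and trim_a by A (average log abundance) — and
    averaged with inverse-variance weights from the delta method.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("no co-expressed genes with the reference sample")
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    p_o = o / lib_obs
    p_r = r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # delta-method variance of M; weight = 1/variance
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    mean_m = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(mean_m):
        return 1.0
    return float(2.0**mean_m)


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormalizationFactors:
    """TMM normalization factors, centered to geometric mean 1.

    ``reference=None`` picks the sample whose 75th-percentile count fraction
    is closest to the mean of those fractions.  The reference's raw
    (pre-centering) factor is 1 by construction.
    """
    if cm.n_samples < 2:
        raise ValueError("need >=2 samples")
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    lib = cm.library_sizes.astype(float)
    if np.any(lib <= 0):
        bad = [s for s, l in zip(cm.sample_ids, lib) if l <= 0]
        raise ValueError(f"samples with zero library size: {bad}")
    if reference is None:
        ref_idx = _choose_reference(cm.counts)
    else:
        ref_idx = cm.sample_ids.index(reference)
    ref_col = cm.counts[:, ref_idx]

    raw = np.ones(cm.n_samples)
    for j in range(cm.n_samples):
        if j == ref_idx:
            continue
        try:
            raw[j] = _tmm_pair_factor(
                cm.counts[:, j], ref_col, lib[j], lib[ref_idx], trim_m, trim_a
            )
        except ValueError as exc:
            raise ValueError(f"sample {cm.sample_ids[j]!r}: {exc}") from None
    centered = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(
        sample_ids=list(cm.sample_ids),
        factors=centered,
        reference_sample=cm.sample_ids[ref_idx],
        trim_m=trim_m,
        trim_a=trim_a,
    )


def fpkm_log2(cm: CountMatrix, nf: NormalizationFactors) -> ExpressionMatrix:
    """TMM-normalized log2(FPKM + 1) matrix.

    FPKM(g, s) = count / (length_kb(g) * effective_library_millions(s)),
    with the effective library size = raw library size * TMM factor.
    """
    if list(nf.sample_ids) != list(cm.sample_ids):
        # allow reordering by id
        try:
            perm = [nf.sample_ids.index(s) for s in cm.sample_ids]
        except ValueError:
            raise ValueError("normalization factors do not cover all samples")
        factors = nf.factors[perm]
    else:
        factors = nf.factors
    eff_lib = cm.library_sizes.astype(float) * factors
    if np.any(eff_lib <= 0):
        raise ValueError("zero effective library size")
    length_kb = cm.gene_lengths_bp.astype(float) / 1000.0
    fpkm = cm.counts / (length_kb[:, None] * (eff_lib / 1e6)[None, :])
    return ExpressionMatrix(
        gene_ids=list(cm.gene_ids),
        sample_ids=list(cm.sample_ids),
        values=np.log2(fpkm + 1.0),
        scale_tag="log2_fpkm_plus1",
    )


def filter_low_expression(
    cm: CountMatrix, min_count: int = 10, min_total: int = 15
) -> np.ndarray:
    """Boolean keep-mask for background-noise removal.

    A gene is kept iff its count reaches a library-size-rescaled
    ``min_count`` in at least ``n_min`` samples (the smallest group size
    when group labels are present, otherwise half the samples rounded up)
    and its total count across samples reaches ``min_total``.
    """
    lib = cm.library_sizes.astype(float)
    if cm.group_labels is not None:
        _, counts_per_group = np.unique(np.asarray(cm.group_labels), return_counts=True)
        n_min = int(counts_per_group.min())
    else:
        n_min = int(np.ceil(cm.n_samples * 0.5))
    median_lib = float(np.median(lib))
    # rescale min_count by each sample's library relative to the median
    scaled_min = min_count * lib / median_lib
    enough = (cm.counts >= scaled_min[None, :]).sum(axis=1) >= n_min
    total_ok = cm.counts.sum(axis=1) >= min_total
    keep = enough & total_ok
    if not keep.any():
        logger.warning("low-expression filter removed every gene")
    return keep


@dataclass(frozen=True)
class IsoformRatio:
    """Ratio of cohort-mean linear FPKM of one isoform over another."""

    iso_num: str
    iso_den: str
    cohort_ratio: float
    per_sample_ratios: np.ndarray
    sample_ids: list = field(default_factory=list)


def isoform_ratio(em: ExpressionMatrix, iso_num, iso_den) -> IsoformRatio:
    """Mean-linear-FPKM ratio of two isoforms across a cohort.

    Linear values are recovered as 2**value - 1 from the log2(FPKM+1)
    matrix; the cohort ratio is mean(numerator) / mean(denominator), and
    per-sample ratios are reported where the denominator is positive.
    """
    if em.scale_tag != "log2_fpkm_plus1":
        raise ValueError("isoform_ratio expects a log2(FPKM+1) matrix")
    num = 2.0 ** em.row(iso_num) - 1.0
    den = 2.0 ** em.row(iso_den) - 1.0
    if den.mean() <= 0:
        raise ValueError("ratio undefined: denominator mean expression is 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_sample = np.where(den > 0, num / den, np.nan)
    return IsoformRatio(
        iso_num=str(iso_num),
        iso_den=str(iso_den),
        cohort_ratio=float(num.mean() / den.mean()),
        per_sample_ratios=per_sample,
        sample_ids=list(em.sample_ids),
    )
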