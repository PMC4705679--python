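"""Between-sample scaling and log-CPM transformation.

Scaling factors follow the trimmed-mean-of-M-values scheme: per sample, a
doubly trimmed, precision-weighted mean of gene-wise log2 count-ratio
M-values against a reference sample, rescaled so the factors have geometric
mean one.  The transform is a log2 counts-per-million with a pseudo-count,
computed against effective (factor-adjusted) library sizes; no per-observation
precision weights are produced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io_counts import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormFactors",
    "ExpressionMatrix",
    "tmm_reference",
    "tmm_factors",
    "unit_factors",
    "logcpm_transform",
    "drop_zero_genes",
]


@dataclass
class NormFactors:
    """Per-sample scaling factors with the raw library sizes they adjust."""

    sample_ids: list[str]
    factors: np.ndarray  # positive reals, geometric mean 1
    lib_sizes: np.ndarray  # positive integer column sums

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=np.float64)
        self.lib_sizes = np.asarray(self.lib_sizes)
        if (self.factors <= 0).any():
            raise ValueError("all scaling factors must be positive")
        if abs(np.log(self.factors).mean()) > 1e-9:
            raise ValueError("scaling factors must have geometric mean 1")


@dataclass
class ExpressionMatrix:
    """Normalized log2-scale expression values (same shape/ids as source)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (G, N) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")


def _upper_quartile_fractions(values: np.ndarray) -> np.ndarray:
    lib = values.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    return np.quantile(values / lib, 0.75, axis=0)


def tmm_reference(counts: CountMatrix) -> int:
    """Choose the reference sample for scaling-factor computation.

    Returns the index of the sample whose 75th-percentile count fraction is
    closest to the mean of that quantity across samples (first index on
    ties).
    """
    if counts.values.sum() == 0:
        raise ValueError("all-zero count matrix")
    f75 = _upper_quartile_fractions(counts.values)
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_log2_factor(
    y_k: np.ndarray,
    y_r: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """Doubly trimmed, precision-weighted mean of M-values (log2 scale)."""
    n_k = y_k.sum()
    n_r = y_r.sum()
    both = (y_k > 0) & (y_r > 0)
    yk = y_k[both].astype(np.float64)
    yr = y_r[both].astype(np.float64)
    if yk.size == 0:
        warnings.warn("no genes shared with reference; factor set to 1")
        return 0.0
    m = np.log2((yk / n_k) / (yr / n_r))
    a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("no genes survive trimming; factor set to 1")
        return 0.0
    # Inverse-asymptotic-variance weights computed on within-sample count
    # proportions, so the whole procedure is exactly invariant to rescaling
    # any single column: w = [(1-p_k)/p_k + (1-p_r)/p_r]^-1 with p = y/N.
    p_k = yk / n_k
    p_r = yr / n_r
    w = 1.0 / ((1.0 - p_k) / p_k + (1.0 - p_r) / p_r)
    return float((w[keep] * m[keep]).sum() / w[keep].sum())


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: int | None = None,
) -> NormFactors:
    """Compute per-sample scaling factors.

    Per sample *k* versus the reference *r*, over genes with nonzero counts
    in both, M-values ``log2((y_gk/N_k)/(y_gr/N_r))`` are trimmed by
    ``trim_m`` (top and bottom, by M) and ``trim_a`` (by the average log
    abundance A) and averaged with inverse-asymptotic-variance weights
    computed on count proportions.  The resulting factors are rescaled to
    geometric mean 1.  Every quantity involved depends only on within-sample
    proportions, so the factors are invariant to rescaling any column.
    """
    lib = counts.values.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, z in zip(counts.sample_ids, lib == 0) if z]
        raise ValueError(f"sample(s) with zero library size: {bad}")
    if reference is None:
        reference = tmm_reference(counts)
    log2f = np.zeros(counts.n_samples)
    for k in range(counts.n_samples):
        if k == reference:
            continue
        log2f[k] = _tmm_log2_factor(
            counts.values[:, k], counts.values[:, reference], trim_m, trim_a
        )
    factors = 2.0 ** (log2f - log2f.mean())
    return NormFactors(list(counts.sample_ids), factors, lib)


def unit_factors(counts: CountMatrix) -> NormFactors:
    """Factors of 1 for every sample (bypass for pre-normalized input)."""
    lib = counts.values.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    return NormFactors(
        list(counts.sample_ids), np.ones(counts.n_samples), lib
    )


def logcpm_transform(
    counts: CountMatrix, factors: NormFactors, prior: float = 0.5
) -> ExpressionMatrix:
    """Log2 counts-per-million against effective library sizes.

    ``value(g, i) = log2((count(g, i) + prior) / (lib(i) * factor(i) + 1) * 1e6)``
    """
    if prior <= 0:
        raise ValueError("prior count must be positive")
    if factors.sample_ids != counts.sample_ids:
        raise ValueError("factors computed on a different sample set")
    eff = factors.lib_sizes * factors.factors
    values = np.log2((counts.values + prior) / (eff + 1.0) * 1e6)
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids), values)


def drop_zero_genes(counts: CountMatrix) -> tuple[CountMatrix, list[str]]:
    """Remove genes with zero counts in every sample.

    Returns the filtered matrix and the ids of the dropped genes.  Such rows
    carry no ranking information and break M-value computation.
    """
    keep = counts.values.sum(axis=1) > 0
    dropped = [g for g, k in zip(counts.gene_ids, keep) if not k]
    if dropped:
        logger.info("dropped %d all-zero gene(s)", len(dropped))
    kept = CountMatrix(
        [g for g, k in zip(counts.gene_ids, keep) if k],
        list(counts.sample_ids),
        counts.values[keep],
    )
    return kept, dropped
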