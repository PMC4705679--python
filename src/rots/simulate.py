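"""Negative-binomial count simulator with known differential-expression truth.

Emulates a spike-in benchmark: a small set of control genes at fixed
between-group fold changes (0.5, 0.67, 1, 4) embedded in a null background,
with NB noise (variance mu + phi * mu^2) and unequal library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_counts import CountMatrix, GroupDesign

__all__ = [
    "SimParams",
    "SimTruth",
    "spikein_preset",
    "simulate_counts",
    "design_for",
    "write_truth",
    "read_truth",
]


@dataclass
class SimParams:
    """Configuration of a two-group count simulation.

    ``controls`` lists (count, fold_change) classes; all remaining genes form
    a fold-change-1 background.  Baseline means are drawn log-uniform over
    ``baseline_mean_range``; library-size factors are drawn log-uniform over
    ``libsize_factor_range`` unless given explicitly (length 2n).
    """

    genes: int
    samples_per_group: int
    controls: list[tuple[int, float]] = field(default_factory=list)
    baseline_mean_range: tuple[float, float] = (10.0, 1e4)
    dispersion: float = 0.1
    libsize_factors: np.ndarray | None = None
    libsize_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(c <= 0 or fc <= 0 for c, fc in self.controls):
            raise ValueError("control counts and fold changes must be positive")
        total_controls = sum(c for c, _ in self.controls)
        if self.genes < total_controls:
            raise ValueError(
                f"{self.genes} genes cannot hold {total_controls} controls"
            )
        lo, hi = self.baseline_mean_range
        if not 0 < lo <= hi:
            raise ValueError("invalid baseline mean range")
        if self.libsize_factors is not None:
            self.libsize_factors = np.asarray(self.libsize_factors, dtype=np.float64)
            if self.libsize_factors.size != 2 * self.samples_per_group:
                raise ValueError("libsize_factors must have length 2n")
            if (self.libsize_factors <= 0).any():
                raise ValueError("libsize_factors must be positive")


@dataclass
class SimTruth:
    """Assigned fold change and DE flag per simulated gene."""

    gene_ids: list[str]
    fold_change: np.ndarray
    is_de: np.ndarray

    def __post_init__(self) -> None:
        self.fold_change = np.asarray(self.fold_change, dtype=np.float64)
        self.is_de = np.asarray(self.is_de, dtype=bool)
        if not np.array_equal(self.is_de, self.fold_change != 1.0):
            raise ValueError("is_de flags inconsistent with fold changes")


def spikein_preset(
    genes: int = 1000, samples_per_group: int = 5, seed: int = 0
) -> SimParams:
    """Spike-in-style preset: 92 controls at fold changes {0.5, 0.67, 1, 4}.

    23 controls are at fold change 1; the remaining 69 are split evenly
    across the other three classes.  Five replicates per group by default and
    low dispersion (0.01), mimicking technical replicates.
    """
    return SimParams(
        genes=genes,
        samples_per_group=samples_per_group,
        controls=[(23, 0.5), (23, 0.67), (23, 1.0), (23, 4.0)],
        dispersion=0.01,
        seed=seed,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mu)
    size = 1.0 / phi  # var = mu + phi * mu^2
    return rng.negative_binomial(size, size / (size + mu))


def simulate_counts(params: SimParams) -> tuple[CountMatrix, SimTruth]:
    """Draw a count matrix and its truth labels, reproducibly from the seed.

    Group 1 samples use the baseline mean; group 2 multiplies it by the
    gene's assigned fold change.  Counts are NB with variance mu + phi*mu^2.
    """
    rng = np.random.default_rng(params.seed)
    G = params.genes
    n = params.samples_per_group
    fc = np.ones(G)
    row = 0
    for count, f in params.controls:
        fc[row : row + count] = f
        row += count
    lo, hi = params.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    if params.libsize_factors is None:
        flo, fhi = params.libsize_factor_range
        libfac = np.exp(rng.uniform(np.log(flo), np.log(fhi), size=2 * n))
    else:
        libfac = params.libsize_factors
    group2 = np.r_[np.zeros(n), np.ones(n)]  # 0/1 exponent on the fold change
    mu = baseline[:, None] * fc[:, None] ** group2[None, :] * libfac[None, :]
    values = _nb_draw(rng, mu, params.dispersion)
    width = len(str(G))
    gene_ids = [f"gene_{i + 1:0{width}d}" for i in range(G)]
    sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    counts = CountMatrix(gene_ids, sample_ids, values.astype(np.int64))
    truth = SimTruth(gene_ids, fc, fc != 1.0)
    return counts, truth


def design_for(counts: CountMatrix) -> GroupDesign:
    """Two-group design matching a simulated matrix (half A, half B)."""
    n = counts.n_samples // 2
    groups = np.r_[np.ones(n, dtype=np.int64), np.full(n, 2, dtype=np.int64)]
    return GroupDesign(list(counts.sample_ids), groups, {1: "A", 2: "B"})


def write_truth(truth: SimTruth, path) -> None:
    """Write truth labels as tab-delimited text."""
    pd.DataFrame(
        {
            "gene_id": truth.gene_ids,
            "fold_change": truth.fold_change,
            "is_de": truth.is_de.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> SimTruth:
    """Read truth labels written by :func:`write_truth`."""
    df = pd.read_csv(path, sep="\t")
    return SimTruth(
        [str(g) for g in df["gene_id"]],
        df["fold_change"].to_numpy(),
        df["is_de"].to_numpy().astype(bool),
    )
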