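"""Reading and writing count matrices, group designs, and result tables.

Count matrices are plain delimited text with genes in rows: the first row is
a header of sample identifiers, the first column holds gene identifiers, and
the body is non-negative integers.  Designs are two-column files (sample id,
group label) without a header.  Tab and comma delimiters are auto-detected on
read; tab is always used on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:
    from .rots_core import RotsFit

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GroupDesign",
    "CountsParseError",
    "DesignError",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "write_results",
    "read_results",
    "read_summary",
]


class CountsParseError(ValueError):
    """A count matrix file violates the expected layout or cell format."""


class DesignError(ValueError):
    """A sample-to-group design is malformed or incompatible with the data."""


@dataclass
class CountMatrix:
    """Raw integer read counts with gene and sample identifiers.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers, in file order.
    sample_ids : list of str
        Unique column identifiers, in file order.
    values : ndarray of shape (G, N)
        Non-negative integer counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.issubdtype(self.values.dtype, np.floating) and np.all(
                self.values == np.floor(self.values)
            ):
                self.values = self.values.astype(np.int64)
            else:
                raise CountsParseError("count values must be integers")
        if self.values.ndim != 2:
            raise CountsParseError("count matrix must be two-dimensional")
        g, n = self.values.shape
        if len(self.gene_ids) != g:
            raise CountsParseError(
                f"{len(self.gene_ids)} gene ids for {g} rows"
            )
        if len(self.sample_ids) != n:
            raise CountsParseError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        if len(set(self.gene_ids)) != g:
            dupes = _duplicates(self.gene_ids)
            raise CountsParseError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise CountsParseError(f"duplicate sample ids: {dupes}")
        if (self.values < 0).any():
            g_bad, s_bad = np.argwhere(self.values < 0)[0]
            raise CountsParseError(
                f"negative count at gene {self.gene_ids[g_bad]!r}, "
                f"sample {self.sample_ids[s_bad]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupDesign:
    """Assignment of each sample to condition 1 or 2.

    Group labels in design files are arbitrary strings; they are mapped to
    the numeric conditions 1 and 2 in order of first appearance.
    """

    sample_ids: list[str]
    groups: np.ndarray  # int array of 1s and 2s aligned with sample_ids
    label_of_group: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=np.int64)
        if len(self.sample_ids) != self.groups.size:
            raise DesignError("sample_ids and groups differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DesignError(
                f"duplicate sample ids: {_duplicates(self.sample_ids)}"
            )
        present = set(self.groups.tolist())
        if present != {1, 2}:
            raise DesignError(
                f"exactly two groups required, found {sorted(present)}"
            )
        for j in (1, 2):
            n_j = int((self.groups == j).sum())
            if n_j < 2:
                label = self.label_of_group.get(j, str(j))
                raise DesignError(
                    f"group {label!r} has {n_j} sample(s); at least 2 required"
                )

    @property
    def n1(self) -> int:
        return int((self.groups == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.groups == 2).sum())

    @property
    def group_of_sample(self) -> dict[str, int]:
        return dict(zip(self.sample_ids, self.groups.tolist()))

    def reordered(self, sample_ids: list[str]) -> "GroupDesign":
        """Return an equivalent design whose samples follow ``sample_ids``."""
        mapping = self.group_of_sample
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise DesignError(f"samples not covered by design: {missing}")
        extra = set(mapping) - set(sample_ids)
        if extra:
            raise DesignError(f"design samples absent from matrix: {sorted(extra)}")
        groups = np.array([mapping[s] for s in sample_ids], dtype=np.int64)
        return GroupDesign(list(sample_ids), groups, dict(self.label_of_group))


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_counts(path: str | Path, delimiter: str | None = None) -> CountMatrix:
    """Read a delimited count matrix (genes in rows, header of sample ids).

    Parameters
    ----------
    path : path-like
        File to read.
    delimiter : str, optional
        Field delimiter.  Auto-detected (tab vs comma) when omitted.

    Raises
    ------
    CountsParseError
        On non-integer or negative cells (naming the offending gene and
        sample) and on duplicate identifiers.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    # Header parsed by hand: pandas silently renames duplicate column names,
    # which would defeat the duplicate-sample-id check.
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    sample_ids = [h.strip() for h in header[1:]]
    df = pd.read_csv(path, sep=delimiter, header=None, skiprows=1, dtype=str)
    if df.shape[1] != len(sample_ids) + 1:
        raise CountsParseError(
            f"header has {len(sample_ids)} sample(s) but body rows have "
            f"{df.shape[1] - 1} value column(s)"
        )
    gene_ids = [str(g) for g in df.iloc[:, 0]]
    values = np.empty((df.shape[0], len(sample_ids)), dtype=np.int64)
    for j in range(len(sample_ids)):
        cells = df.iloc[:, j + 1].to_numpy()
        try:
            values[:, j] = np.asarray(cells, dtype=np.int64)
        except (ValueError, TypeError):
            for i, cell in enumerate(cells):
                try:
                    int(cell)
                except (ValueError, TypeError):
                    raise CountsParseError(
                        f"non-integer count {cell!r} at gene {gene_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}"
                    ) from None
            raise
    return CountMatrix(gene_ids, sample_ids, values)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as tab-delimited text."""
    df = pd.DataFrame(counts.values, index=counts.gene_ids, columns=counts.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path: str | Path, delimiter: str | None = None) -> GroupDesign:
    """Read a two-column design file (sample id, group label; no header).

    Labels are mapped to conditions 1/2 by first appearance; the mapping is
    logged.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if df.shape[1] != 2:
        raise DesignError(
            f"design file must have exactly 2 columns, found {df.shape[1]}"
        )
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    labels = [str(x) for x in df.iloc[:, 1]]
    order: list[str] = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    if len(order) != 2:
        raise DesignError(
            f"exactly two groups required, found {len(order)}: {order}"
        )
    label_to_num = {order[0]: 1, order[1]: 2}
    groups = np.array([label_to_num[lab] for lab in labels], dtype=np.int64)
    logger.info("group mapping: %r -> 1, %r -> 2", order[0], order[1])
    return GroupDesign(sample_ids, groups, {1: order[0], 2: order[1]})


def write_design(design: GroupDesign, path: str | Path) -> None:
    """Write a design as two tab-separated columns without a header."""
    labels = [design.label_of_group.get(g, str(g)) for g in design.groups.tolist()]
    with open(path, "w") as fh:
        for sid, lab in zip(design.sample_ids, labels):
            fh.write(f"{sid}\t{lab}\n")


def write_results(
    fit: "RotsFit", path: str | Path, summary_path: str | Path | None = None
) -> None:
    """Write a per-gene result table and a key/value run summary.

    The table is tab-delimited with columns ``gene_id``, ``statistic``,
    ``logfc``, ``fdr``.  The summary records the optimized parameters
    (``alpha1``, ``alpha2``, ``k_opt``, ``R_opt``, ``Z_opt``) and run
    metadata (``B``, ``P``, ``seed``, gene counts).
    """
    path = Path(path)
    if summary_path is None:
        summary_path = path.with_name(path.name + ".summary")
    df = pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "statistic": fit.statistic,
            "logfc": fit.logfc,
            "fdr": fit.fdr,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    summary = {
        "alpha1": fit.alpha.a1,
        "alpha2": fit.alpha.a2,
        "k_opt": fit.k_opt,
        "R_opt": fit.R_opt,
        "Z_opt": fit.Z_opt,
        "B": fit.B,
        "P": fit.P,
        "seed": fit.seed,
        "n_genes": len(fit.gene_ids),
        "n_dropped": len(fit.dropped_gene_ids),
    }
    with open(summary_path, "w") as fh:
        for key, val in summary.items():
            fh.write(f"{key}\t{val!r}\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def read_summary(path: str | Path) -> dict:
    """Read a run summary back into a dict of python values."""
    import ast

    out: dict = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.rstrip("\n").partition("\t")
            out[key] = ast.literal_eval(val)
    return out
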