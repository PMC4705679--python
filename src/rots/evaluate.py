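"""Scoring a gene ranking / FDR vector against simulation truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .simulate import SimTruth

__all__ = ["EvalReport", "roc_auc", "confusion_at_fdr", "evaluate_run"]


@dataclass
class EvalReport:
    """ROC AUC plus the confusion table at an FDR cutoff."""

    auc: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float

    @property
    def n_genes(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _truth_flags(truth: SimTruth | np.ndarray) -> np.ndarray:
    if isinstance(truth, SimTruth):
        return truth.is_de
    return np.asarray(truth, dtype=bool)


def roc_auc(scores: np.ndarray, truth: SimTruth | np.ndarray) -> float:
    """ROC AUC of scores against DE flags (rank formulation; ties count 1/2).

    Scores are rank-transformed first so that +inf entries (ranked above all
    finite values) are handled exactly.
    """
    y = _truth_flags(truth)
    scores = np.asarray(scores, dtype=np.float64)
    if y.all() or not y.any():
        raise ValueError("both DE and non-DE genes required for ROC analysis")
    return float(roc_auc_score(y, rankdata(scores)))


def confusion_at_fdr(
    fdr: np.ndarray, truth: SimTruth | np.ndarray, cutoff: float = 0.05
) -> EvalReport:
    """Confusion counts for calls defined by strict ``fdr < cutoff``."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    y = _truth_flags(truth)
    fdr = np.asarray(fdr, dtype=np.float64)
    if fdr.shape != y.shape:
        raise ValueError("fdr and truth differ in length")
    if (fdr < 0).any() or (fdr > 1).any():
        raise ValueError("fdr values must lie in [0, 1]")
    called = fdr < cutoff
    return EvalReport(
        auc=None,
        tp=int((called & y).sum()),
        fp=int((called & ~y).sum()),
        tn=int((~called & ~y).sum()),
        fn=int((~called & y).sum()),
        cutoff=cutoff,
    )


def evaluate_run(
    scores: np.ndarray,
    fdr: np.ndarray,
    truth: SimTruth | np.ndarray,
    cutoff: float = 0.05,
) -> EvalReport:
    """Full report: AUC of the scores and confusion at the FDR cutoff."""
    report = confusion_at_fdr(fdr, truth, cutoff)
    report.auc = roc_auc(scores, truth)
    return report
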