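"""Edge-level accuracy of candidate networks against a gold standard.

Matching is directed and sign-blind on non-self-loop edges: an inferred
edge (regulator, target) is a true positive when the gold standard has a
nonzero entry at the same off-diagonal position, regardless of weight
sign. Self-loops are excluded from both edge sets so accuracy reflects
regulatory links only. F1 at tp = 0 is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grnic import GrnicResult
from .inference import SparsitySweep
from .netsim import GeneNetwork

__all__ = ["EvaluationReport", "confusion", "f1_score", "evaluate_sweep"]


def _support(net: GeneNetwork) -> np.ndarray:
    """Boolean off-diagonal support (self-loops masked out)."""
    s = net.weights != 0
    np.fill_diagonal(s, False)
    return s


def confusion(estimate: GeneNetwork, truth: GeneNetwork) -> tuple[int, int, int]:
    """Directed, sign-blind edge confusion counts (tp, fp, fn)."""
    if estimate.genes != truth.genes:
        raise ValueError("estimate and truth gene sets differ")
    est, tru = _support(estimate), _support(truth)
    tp = int(np.count_nonzero(est & tru))
    fp = int(np.count_nonzero(est & ~tru))
    fn = int(np.count_nonzero(~est & tru))
    return tp, fp, fn


def f1_score(tp: int, fp: int, fn: int) -> float:
    """2tp / (2tp + fp + fn); 0 by convention when tp = 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


@dataclass
class EvaluationReport:
    """Per-candidate confusion/F1 plus sparsity summaries (links per gene)."""

    link_counts: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    max_f1_index: int
    selected_index: int | None
    sparsity_true: float
    n_genes: int

    @property
    def selected_f1(self) -> float | None:
        if self.selected_index is None:
            return None
        return float(self.f1[self.selected_index])

    @property
    def max_f1(self) -> float:
        return float(self.f1[self.max_f1_index])

    @property
    def sparsity_max_f1(self) -> float:
        return float(self.link_counts[self.max_f1_index]) / self.n_genes

    @property
    def sparsity_selected(self) -> float | None:
        if self.selected_index is None:
            return None
        return float(self.link_counts[self.selected_index]) / self.n_genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "link_count": self.link_counts,
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            }
        )


def evaluate_sweep(
    sweep: SparsitySweep,
    truth: GeneNetwork,
    result: GrnicResult | None = None,
) -> EvaluationReport:
    """Score every candidate against the gold standard.

    Reports per-candidate (tp, fp, fn, precision, recall, F1), the
    max-F1 candidate, and - when a :class:`GrnicResult` is supplied -
    the selected candidate's accuracy and sparsity for comparison with
    the best achievable and the true sparsity.
    """
    if sweep.genes != truth.genes:
        raise ValueError("sweep and truth gene sets differ")
    tru = _support(truth)
    n_true = int(np.count_nonzero(tru))

    tps, fps, fns = [], [], []
    for cand in sweep:
        est = _support(cand)
        tp = int(np.count_nonzero(est & tru))
        tps.append(tp)
        fps.append(int(np.count_nonzero(est)) - tp)
        fns.append(n_true - tp)
    tp_a, fp_a, fn_a = (np.asarray(a) for a in (tps, fps, fns))

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp_a + fp_a > 0, tp_a / np.maximum(tp_a + fp_a, 1), 0.0)
        recall = np.where(tp_a + fn_a > 0, tp_a / np.maximum(tp_a + fn_a, 1), 0.0)
    f1 = np.array([f1_score(t, f, n) for t, f, n in zip(tps, fps, fns)])

    return EvaluationReport(
        link_counts=np.asarray(sweep.link_counts),
        tp=tp_a,
        fp=fp_a,
        fn=fn_a,
        precision=precision,
        recall=recall,
        f1=f1,
        max_f1_index=int(np.argmax(f1)),
        selected_index=None if result is None else result.selected_index,
        sparsity_true=truth.sparsity,
        n_genes=len(sweep.genes),
    )
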