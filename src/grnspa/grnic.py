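"""The sparsity-selection core: the GRN Information Criterion (GRNIC).

For every candidate network ``A_i`` in a sparsity sweep, two terms are
computed and summed,

    GRNIC_i = K_i + L_i,

where ``K`` is a normalized penalty (the number of genes that regulate
at least one *other* gene - the model's regulator count) and ``L`` is a
normalized badness of fit of the expression predicted from the candidate,
``Yhat_i = -A_i^dagger P``, against the measured expression. Both terms
are min-max normalized across the sweep so they span [0, 1] and are
commensurate regardless of network size or error scale; the candidate
minimizing GRNIC is selected. The construction mirrors AIC/BIC: a
complexity penalty plus a (transformed) lack-of-fit term, with ``exp``
of the scaled badness of fit standing in for the negative log-likelihood.

The pseudoinverse is computed by singular value decomposition with a
safeguard that zeroes singular values below ``1 / max(Y)`` before
inversion, protecting against unstable inversions of near-singular
candidates; the safeguard is almost never active in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import SparsitySweep
from .netsim import ExpressionData, GeneNetwork, PerturbationDesign

__all__ = [
    "GrnicResult",
    "predict_expression",
    "penalty_K",
    "badness_of_fit",
    "combine_penalty_and_fit",
    "grnic_scores",
    "shuffle_control",
]


@dataclass
class GrnicResult:
    """Per-candidate GRNIC table and the selected sweep position.

    All arrays are aligned with the sweep order. ``k_norm`` and
    ``l_norm`` lie in [0, 1] and ``grnic = k_norm + l_norm`` exactly;
    ties at the minimum resolve toward the smaller link count.
    """

    link_counts: np.ndarray
    k_raw: np.ndarray
    k_norm: np.ndarray
    fit_error_raw: np.ndarray
    l_norm: np.ndarray
    grnic: np.ndarray
    selected_index: int
    n_genes: int

    @property
    def selected_sparsity(self) -> float:
        """Links per gene of the selected candidate."""
        return float(self.link_counts[self.selected_index]) / self.n_genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "link_count": self.link_counts,
                "k_raw": self.k_raw,
                "k_norm": self.k_norm,
                "fit_error_raw": self.fit_error_raw,
                "l_norm": self.l_norm,
                "grnic": self.grnic,
            }
        )


def _safeguard_threshold(measured: ExpressionData, signed: bool) -> float:
    y = measured.values
    top = float(np.max(y)) if signed else float(np.max(np.abs(y)))
    if top <= 0:
        return np.inf
    return 1.0 / top


def predict_expression(
    candidate: GeneNetwork,
    design: PerturbationDesign,
    measured: ExpressionData,
    signed_threshold: bool = False,
) -> ExpressionData:
    """Predict expression from a candidate network: ``Yhat = -A^dagger P``.

    The pseudoinverse of the candidate's weight matrix is formed by SVD
    after zeroing singular values below ``1 / max|Y|`` of the measured
    expression (``signed_threshold=True`` uses the signed maximum
    instead). If every singular value falls below the threshold the
    candidate cannot predict anything: a zero matrix is returned with
    its ``degenerate`` flag set.
    """
    if candidate.genes != design.genes:
        raise ValueError("candidate and design gene sets differ")
    thr = _safeguard_threshold(measured, signed_threshold)
    u, s, vt = np.linalg.svd(candidate.weights)
    keep = s >= thr
    if not keep.any():
        return ExpressionData(
            list(candidate.genes),
            list(design.experiments),
            np.zeros_like(design.values),
            degenerate=True,
        )
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    pinv = (vt.T * s_inv) @ u.T
    return ExpressionData(
        list(candidate.genes), list(design.experiments), -pinv @ design.values
    )


def penalty_K(candidate: GeneNetwork) -> int:
    """Number of genes that regulate at least one other gene.

    Counts columns with a nonzero off-diagonal entry; a gene whose only
    target is itself (self-loop) is not a regulator in this sense.
    """
    off = candidate.weights.copy()
    np.fill_diagonal(off, 0.0)
    return int(np.count_nonzero(np.any(off != 0, axis=0)))


def badness_of_fit(predicted: ExpressionData, measured: ExpressionData) -> float:
    """Scale-free prediction error between predicted and measured expression.

    Each matrix is first divided by its own maximum absolute entry (a
    zero matrix is left as is), putting both on a common [-1, 1] range;
    the result is the root-mean-square elementwise difference. The value
    is transformed and normalized across the sweep by
    :func:`grnic_scores`.
    """
    p, m = predicted.values, measured.values
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: predicted {p.shape} vs measured {m.shape}")

    def scaled(x: np.ndarray) -> np.ndarray:
        top = np.max(np.abs(x))
        return x / top if top > 0 else x

    return float(np.sqrt(np.mean((scaled(p) - scaled(m)) ** 2)))


def _minmax(x: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; a constant vector maps to all-zeros."""
    x = np.asarray(x, dtype=float)
    span = np.ptp(x)
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def combine_penalty_and_fit(
    k_raw: np.ndarray, e_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalization chain turning raw (K, badness) into GRNIC terms.

    ``l_norm = minmax(exp(minmax(e_raw)))`` and ``k_norm = minmax(k_raw)``;
    returns ``(k_norm, l_norm, k_norm + l_norm)``. A term constant across
    the sweep normalizes to all-zeros.
    """
    l_norm = _minmax(np.exp(_minmax(np.asarray(e_raw, dtype=float))))
    k_norm = _minmax(np.asarray(k_raw, dtype=float))
    return k_norm, l_norm, k_norm + l_norm


def grnic_scores(
    sweep: SparsitySweep,
    design: PerturbationDesign,
    measured: ExpressionData,
    signed_threshold: bool = False,
) -> GrnicResult:
    """Score every candidate in a sweep and select the GRNIC minimizer.

    Per candidate i: ``k_raw[i]`` is the regulator count and
    ``e_raw[i]`` the badness of fit of its predicted expression. The
    badness-of-fit chain is: min-max scale ``e_raw`` across the sweep,
    apply ``exp``, min-max normalize again, giving ``l_norm``;
    ``k_raw`` is min-max normalized to ``k_norm``; and
    ``grnic = k_norm + l_norm``. A term that is constant across the
    sweep normalizes to all-zeros, so a single-candidate sweep scores
    ``grnic = [0]``. Ties at the minimum go to the smaller link count.
    """
    if len(sweep) == 0:
        raise ValueError("empty sweep")
    if sweep.genes != measured.genes:
        raise ValueError("sweep and expression gene sets differ")

    k_raw = np.array([penalty_K(c) for c in sweep], dtype=float)
    e_raw = np.array(
        [
            badness_of_fit(
                predict_expression(c, design, measured, signed_threshold), measured
            )
            for c in sweep
        ]
    )

    k_norm, l_norm, grnic = combine_penalty_and_fit(k_raw, e_raw)
    # link_counts are strictly increasing, so argmin's first hit is the
    # smallest-link-count tie winner.
    selected = int(np.argmin(grnic))
    return GrnicResult(
        link_counts=np.asarray(sweep.link_counts),
        k_raw=k_raw,
        k_norm=k_norm,
        fit_error_raw=e_raw,
        l_norm=l_norm,
        grnic=grnic,
        selected_index=selected,
        n_genes=len(sweep.genes),
    )


def shuffle_control(predicted: ExpressionData, seed: int = 0) -> ExpressionData:
    """Experiment-wise random shuffle: permute genes within each column.

    Destroys the gene-to-gene structure of a predicted expression matrix
    while preserving each experiment's value multiset - the null against
    which the badness-of-fit trend across a sweep is compared.
    """
    rng = np.random.default_rng(seed)
    shuffled = predicted.values.copy()
    for j in range(shuffled.shape[1]):
        shuffled[:, j] = shuffled[rng.permutation(shuffled.shape[0]), j]
    return ExpressionData(list(predicted.genes), list(predicted.experiments), shuffled)
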