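"""Synthetic gene regulatory networks and steady-state perturbation data.

The benchmark this module emulates is a single-gene-knockdown screen: a
stable linear regulatory system ``A`` is perturbed one gene at a time
(design matrix ``P`` with -1 on the diagonal of each replicate block) and
the steady-state response in log2 fold change is ``Y = -A^{-1} P``, to
which Gaussian noise at a controlled signal-to-noise ratio is added.

Conventions
-----------
* ``A[i, j]`` is the regulatory effect of gene ``j`` (regulator, column)
  on gene ``i`` (target, row).
* Sparsity of a network is the number of non-self-loop links divided by
  the number of genes ("links per gene").
* Self-loops (negative diagonal, self-decay) exist for dynamic stability
  and are never counted as regulatory links.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "GeneNetwork",
    "PerturbationDesign",
    "ExpressionData",
    "NoiseSpec",
    "NOISE_PRESETS",
    "generate_true_network",
    "make_design",
    "simulate_expression",
    "add_noise",
    "realized_snr",
]

#: Named noise presets (signal-to-noise ratios). "low" noise means a high
#: SNR. These are documented stand-ins calibrated to produce clearly
#: separated easy/hard regimes; see docs/methods.md.
NOISE_PRESETS: dict[str, float] = {"low": 10.0, "high": 0.1}


def default_gene_names(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


@dataclass
class GeneNetwork:
    """Signed weighted adjacency matrix of a gene regulatory network.

    Parameters
    ----------
    genes
        Ordered gene identifiers; length N.
    weights
        N x N real matrix ``A``; ``A[i, j] != 0`` means gene ``j``
        regulates gene ``i``.
    """

    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError(f"weights must be square, got shape {self.weights.shape}")
        if len(self.genes) != self.weights.shape[0]:
            raise ValueError(
                f"{len(self.genes)} gene names for a {self.weights.shape[0]}-gene matrix"
            )
        self.genes = list(self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def link_count(self) -> int:
        """Number of nonzero off-diagonal entries (self-loops excluded)."""
        off = self.weights.copy()
        np.fill_diagonal(off, 0.0)
        return int(np.count_nonzero(off))

    @property
    def sparsity(self) -> float:
        """Links per gene, excluding self-loops."""
        return self.link_count / self.n_genes

    def edges(self) -> list[tuple[str, str, float]]:
        """Non-self-loop edges as (regulator, target, weight) tuples."""
        tgt, reg = np.nonzero(self.weights)
        out = []
        for i, j in zip(tgt, reg):
            if i != j:
                out.append((self.genes[j], self.genes[i], float(self.weights[i, j])))
        return out

    def is_stable(self) -> bool:
        """True when all eigenvalues of A have negative real part."""
        return bool(np.max(np.linalg.eigvals(self.weights).real) < 0)

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(list(self.genes), self.weights.copy())


@dataclass
class PerturbationDesign:
    """Gene x experiment design matrix P; -1 marks the perturbed gene."""

    genes: list[str]
    experiments: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.experiments)):
            raise ValueError(
                f"design shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.experiments)} experiments"
            )
        if not np.isin(self.values, (-1.0, 0.0)).all():
            raise ValueError("design entries must be -1 or 0")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)


@dataclass
class ExpressionData:
    """Gene x experiment matrix of log2 fold changes (measured or predicted)."""

    genes: list[str]
    experiments: list[str]
    values: np.ndarray
    #: Set when a prediction came from a candidate whose singular values
    #: were all below the safeguard threshold (zero prediction).
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.experiments)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.experiments)} experiments"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    def copy(self) -> "ExpressionData":
        return dataclasses.replace(self, values=self.values.copy())


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise at a target signal-to-noise ratio.

    ``snr`` is defined as sigma_min(Y) / sigma_max(E): the weakest signal
    direction relative to the strongest noise direction.
    """

    snr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError(f"snr must be > 0, got {self.snr}")


def generate_true_network(
    n_genes: int,
    sparsity: float = 1.75,
    tf_fraction: float = 0.53,
    seed: int = 0,
    cond_max: float = 8.0,
) -> GeneNetwork:
    """Generate a stable gold-standard network.

    Off-diagonal links originate from a designated transcription-factor
    (TF) subset; regulators are drawn with preferential attachment so a
    few hubs carry many targets, mimicking bacterial regulon topology.
    Every diagonal entry is -1 (self-decay) before a rescaling step that
    shrinks off-diagonal weights until all eigenvalue real parts are
    below -0.01 and the condition number is at most ``cond_max``, so the
    returned network is simulation-ready and its steady-state responses
    are not dominated by a single near-critical direction.

    Parameters
    ----------
    n_genes
        Number of genes N.
    sparsity
        Target non-self-loop links per gene; the network carries
        ``round(sparsity * n_genes)`` links.
    tf_fraction
        Fraction of genes allowed to act as regulators.
    seed
        Seed for the network topology and weights.
    cond_max
        Upper bound on the condition number of the weight matrix;
        bounds how strongly knockdown responses are amplified.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    n_links = int(round(sparsity * n_genes))
    n_tf = int(round(tf_fraction * n_genes))
    if n_tf < 1:
        raise ValueError(f"tf_fraction={tf_fraction} yields no regulators for N={n_genes}")
    if n_links > n_tf * (n_genes - 1):
        raise ValueError(
            f"{n_links} links infeasible with {n_tf} regulators over {n_genes} genes"
        )

    rng = np.random.default_rng(seed)
    tfs = rng.choice(n_genes, size=n_tf, replace=False)
    weights = np.zeros((n_genes, n_genes))

    out_degree = np.zeros(n_tf)
    taken: set[tuple[int, int]] = set()
    while len(taken) < n_links:
        # preferential attachment on current out-degree (+1 smoothing)
        p = (out_degree + 1.0) / (out_degree + 1.0).sum()
        reg = int(tfs[rng.choice(n_tf, p=p)])
        tgt = int(rng.integers(n_genes))
        if tgt == reg or (tgt, reg) in taken:
            continue
        taken.add((tgt, reg))
        out_degree[np.nonzero(tfs == reg)[0][0]] += 1
        sign = 1.0 if rng.random() < 0.5 else -1.0
        weights[tgt, reg] = sign * rng.uniform(0.5, 1.5)

    np.fill_diagonal(weights, -1.0)

    # Shrink off-diagonal weights until the spectral abscissa clears
    # -0.01 and conditioning is bounded; off -> 0 forces both.
    diag = np.diag(np.diag(weights))
    off = weights - diag
    for _ in range(200):
        a = diag + off
        if np.max(np.linalg.eigvals(a).real) < -0.01 and np.linalg.cond(a) <= cond_max:
            break
        off *= 0.8
    else:  # pragma: no cover
        raise RuntimeError("stability rescaling failed to converge")

    return GeneNetwork(default_gene_names(n_genes), diag + off)


def make_design(n_genes: int, replicates: int = 1) -> PerturbationDesign:
    """Single-knockdown design: ``replicates`` copies of -I, concatenated.

    Column ``k*N + i`` has -1 in row ``i`` and 0 elsewhere, so an N-gene
    design with r replicates is an N x rN matrix.
    """
    if n_genes < 1 or replicates < 1:
        raise ValueError("n_genes and replicates must be positive")
    block = -np.eye(n_genes)
    values = np.tile(block, replicates)
    genes = default_gene_names(n_genes)
    experiments = [
        f"{g}_kd_r{k + 1}" for k in range(replicates) for g in genes
    ]
    return PerturbationDesign(genes, experiments, values)


def simulate_expression(
    net: GeneNetwork,
    design: PerturbationDesign,
    perturbation_strength: float = 1.0,
) -> ExpressionData:
    """Noise-free steady-state log2 fold changes, ``Y = -A^{-1} (s P)``.

    ``perturbation_strength`` (s) is the actual size of each knockdown
    in the units of the linear system, while the design matrix keeps its
    -1 indicator convention: in a real screen the analyst knows *which*
    gene was knocked down, not by *how much*. With the default s = 1 the
    relation reduces to the plain ``Y = -A^{-1} P``.

    Raises if the network matrix is singular; stability-flagged networks
    from :func:`generate_true_network` are always invertible.
    """
    if net.genes != design.genes:
        raise ValueError("network and design gene sets differ")
    if not perturbation_strength > 0:
        raise ValueError("perturbation_strength must be positive")
    a = net.weights
    if abs(np.linalg.det(a)) < 1e-300 or np.linalg.cond(a) > 1e12:
        raise np.linalg.LinAlgError(
            "network matrix is singular; regenerate the network or use the "
            "pseudoinverse prediction path"
        )
    y = -scipy.linalg.solve(a, perturbation_strength * design.values)
    return ExpressionData(list(net.genes), list(design.experiments), y)


def _noise_sigma(y: np.ndarray, snr: float) -> float:
    """Std dev so that sigma_min(Y)/E[sigma_max(E)] equals ``snr``.

    For an N x M matrix of i.i.d. N(0, sigma^2) entries the largest
    singular value concentrates at sigma * (sqrt(N) + sqrt(M)).
    """
    n, m = y.shape
    s_min = np.linalg.svd(y, compute_uv=False)[-1]
    return float(s_min / (snr * (np.sqrt(n) + np.sqrt(m))))


def add_noise(y: ExpressionData, spec: NoiseSpec) -> ExpressionData:
    """Add i.i.d. Gaussian noise calibrated to the target SNR.

    Deterministic given ``spec.seed``; the realized SNR fluctuates around
    ``spec.snr`` with the sampling variation of the extreme singular
    value of a Gaussian matrix.
    """
    sigma = _noise_sigma(y.values, spec.snr)
    rng = np.random.default_rng(spec.seed)
    noise = sigma * rng.standard_normal(y.values.shape)
    return ExpressionData(list(y.genes), list(y.experiments), y.values + noise)


def realized_snr(clean: ExpressionData, noisy: ExpressionData) -> float:
    """sigma_min(signal) / sigma_max(noise) for a (clean, noisy) pair."""
    e = noisy.values - clean.values
    s_min = np.linalg.svd(clean.values, compute_uv=False)[-1]
    s_max = np.linalg.svd(e, compute_uv=False)[0]
    return float(s_min / s_max)
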