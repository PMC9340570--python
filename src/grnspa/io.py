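"""TSV readers/writers and the end-to-end pipeline runner.

Canonical formats (tab-delimited, UTF-8, '.' decimal):

* matrix TSV - header row of experiment labels, first column of gene
  IDs, numeric body (expression and design matrices);
* dense network TSV - square matrix with gene IDs as both header and
  first column;
* edge-list TSV - three headerless columns (regulator, target, weight).

Sweeps are serialized as a directory of edge-list TSVs plus a JSON
manifest listing link counts in order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import evaluate_sweep
from .grnic import grnic_scores
from .inference import (
    SparsitySweep,
    infer_lasso_sweep,
    infer_ridge_sweep,
    infer_tree_sweep,
)
from .netsim import (
    NOISE_PRESETS,
    ExpressionData,
    GeneNetwork,
    NoiseSpec,
    PerturbationDesign,
    add_noise,
    generate_true_network,
    make_design,
    simulate_expression,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_expression",
    "read_design",
    "read_network",
    "write_network",
    "write_edge_list",
    "read_sweep",
    "write_sweep",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("grnspa")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled matrix TSV; validates labels and numeric entries."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    for axis, labels in (("gene", df.index), ("experiment", df.columns)):
        dup = labels[labels.duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicate {axis} label {dup[0]!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value at gene {df.index[bad[0]]!r}, "
            f"experiment {df.columns[bad[1]]!r}"
        )
    return df.astype(float)


def write_matrix(values: np.ndarray, genes: list[str], experiments: list[str],
                 path: str | Path) -> None:
    pd.DataFrame(values, index=list(genes), columns=list(experiments)).to_csv(
        Path(path), sep="\t", index_label="gene"
    )


def read_expression(path: str | Path) -> ExpressionData:
    df = read_matrix(path)
    return ExpressionData(list(df.index), list(df.columns), df.to_numpy())


def read_design(path: str | Path) -> PerturbationDesign:
    df = read_matrix(path)
    return PerturbationDesign(list(df.index), list(df.columns), df.to_numpy())


def _read_edge_list(path: Path, genes: list[str]) -> GeneNetwork:
    idx = {g: i for i, g in enumerate(genes)}
    weights = np.zeros((len(genes), len(genes)))
    seen: dict[tuple[int, int], float] = {}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["regulator", "target", "weight"], dtype=str)
    for line, row in enumerate(df.itertuples(index=False), start=1):
        for g in (row.regulator, row.target):
            if g not in idx:
                raise ValueError(f"{path}:{line}: unknown gene {g!r}")
        try:
            w = float(row.weight)
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{line}: non-numeric weight {row.weight!r}")
        key = (idx[row.target], idx[row.regulator])
        if key in seen and seen[key] != w:
            raise ValueError(
                f"{path}:{line}: duplicate edge {row.regulator}->{row.target} "
                f"with conflicting weights {seen[key]} and {w}"
            )
        seen[key] = w
        weights[key] = w
    return GeneNetwork(list(genes), weights)


def read_network(path: str | Path, genes: list[str] | None = None) -> GeneNetwork:
    """Read a network from dense-matrix or 3-column edge-list TSV.

    Edge lists are headerless (regulator, target, weight) and need the
    gene universe; dense files carry their own gene labels.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    is_edge_list = False
    if len(first) == 3:
        try:
            float(first[2])
            is_edge_list = True
        except ValueError:
            pass
    if not first or (len(first) == 1 and not first[0]):  # empty file
        is_edge_list = True
    if is_edge_list or (path.stat().st_size == 0):
        if genes is None:
            raise ValueError(f"{path}: edge-list format needs the gene universe")
        if path.stat().st_size == 0:
            return GeneNetwork(list(genes), np.zeros((len(genes), len(genes))))
        return _read_edge_list(path, list(genes))
    df = read_matrix(path)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: dense network rows and columns must match")
    return GeneNetwork(list(df.index), df.to_numpy())


def write_network(net: GeneNetwork, path: str | Path) -> None:
    """Write a network as a dense square TSV (genes x genes)."""
    write_matrix(net.weights, net.genes, net.genes, path)


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write non-self-loop edges as headerless (regulator, target, weight)."""
    with open(path, "w") as fh:
        for reg, tgt, w in net.edges():
            fh.write(f"{reg}\t{tgt}\t{w:.12g}\n")


def write_sweep(sweep: SparsitySweep, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (cand, k) in enumerate(zip(sweep.candidates, sweep.link_counts)):
        name = f"candidate_{i:04d}_links{k}.tsv"
        write_edge_list(cand, outdir / name)
        files.append(name)
    manifest = {
        "genes": sweep.genes,
        "link_counts": list(map(int, sweep.link_counts)),
        "files": files,
    }
    manifest_path = outdir / "sweep_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_sweep(sweep_dir: str | Path) -> SparsitySweep:
    sweep_dir = Path(sweep_dir)
    manifest = json.loads((sweep_dir / "sweep_manifest.json").read_text())
    genes = manifest["genes"]
    candidates = [
        read_network(sweep_dir / name, genes) for name in manifest["files"]
    ]
    return SparsitySweep(candidates, manifest["link_counts"])


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either set ``expression``/``design`` paths to existing TSVs, or set
    ``simulate=True`` to generate them. ``noise`` is a preset name
    ("low"/"high") or an explicit SNR value.
    """

    outdir: str = "spa_run"
    method: str = "lasso"  # lasso | ridge | tree
    min_lpg: float = 1.0
    max_lpg: float = 5.0
    seed: int = 0
    expression: str | None = None
    design: str | None = None
    truth: str | None = None
    simulate: bool = False
    n_genes: int = 50
    sparsity: float = 1.75
    tf_fraction: float = 0.53
    replicates: int = 3
    noise: str | float = "low"
    perturbation_strength: float = 3.0
    n_trees: int = 1000
    ridge_alpha: float = 1.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_lpg > self.max_lpg:
            raise ValueError("min_lpg must not exceed max_lpg")
        if self.method not in ("lasso", "ridge", "tree"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def snr(self) -> float:
        if isinstance(self.noise, str):
            try:
                return NOISE_PRESETS[self.noise]
            except KeyError:
                raise ValueError(
                    f"unknown noise preset {self.noise!r}; "
                    f"choose from {sorted(NOISE_PRESETS)} or give a number"
                )
        return float(self.noise)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        kwargs.setdefault("extras", {}).update(extras)
        return cls(**kwargs)


def _stage(name: str, **info) -> None:
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: RunConfig) -> dict:
    """simulate (optional) -> infer -> select -> evaluate (optional).

    Writes all intermediate artifacts under ``config.outdir`` and a
    ``manifest.json`` echoing the config, the seed, the selected
    sparsity, and (when a gold standard is available) the selected and
    maximum F1. Idempotent given the seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: GeneNetwork | None = None

    if config.simulate:
        truth = generate_true_network(
            config.n_genes, config.sparsity, config.tf_fraction, config.seed
        )
        design = make_design(config.n_genes, config.replicates)
        clean = simulate_expression(truth, design, config.perturbation_strength)
        expr = add_noise(clean, NoiseSpec(snr=config.snr, seed=config.seed))
        write_network(truth, outdir / "truth.tsv")
        write_edge_list(truth, outdir / "truth_edges.tsv")
        write_matrix(design.values, design.genes, design.experiments,
                     outdir / "design.tsv")
        write_matrix(expr.values, expr.genes, expr.experiments,
                     outdir / "expression.tsv")
        _stage("simulate", genes=config.n_genes, replicates=config.replicates,
               snr=config.snr)
    else:
        if not config.expression or not config.design:
            raise ValueError("expression and design paths required unless simulate=True")
        expr = read_expression(config.expression)
        design = read_design(config.design)
        if config.truth:
            truth = read_network(config.truth, expr.genes)
        _stage("load", expression=config.expression, design=config.design)

    if config.method == "lasso":
        sweep = infer_lasso_sweep(expr, design, config.min_lpg, config.max_lpg)
    elif config.method == "ridge":
        sweep = infer_ridge_sweep(expr, design, config.min_lpg, config.max_lpg,
                                  alpha=config.ridge_alpha)
    else:
        sweep = infer_tree_sweep(expr, n_trees=config.n_trees,
                                 min_lpg=config.min_lpg, max_lpg=config.max_lpg,
                                 seed=config.seed)
    write_sweep(sweep, outdir / "sweep")
    _stage("infer", method=config.method, candidates=len(sweep))

    result = grnic_scores(sweep, design, expr)
    result.to_frame().to_csv(outdir / "grnic_curves.tsv", sep="\t", index=False)
    _stage("select", selected_index=result.selected_index,
           selected_sparsity=result.selected_sparsity)

    manifest: dict = {
        "grnspa_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "extras"},
        "n_candidates": len(sweep),
        "selected_index": result.selected_index,
        "selected_link_count": int(result.link_counts[result.selected_index]),
        "selected_sparsity": result.selected_sparsity,
    }

    if truth is not None:
        report = evaluate_sweep(sweep, truth, result)
        report.to_frame().to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
        manifest.update(
            selected_f1=report.selected_f1,
            max_f1=report.max_f1,
            sparsity_true=report.sparsity_true,
            sparsity_max_f1=report.sparsity_max_f1,
        )
        _stage("evaluate", selected_f1=report.selected_f1, max_f1=report.max_f1)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
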