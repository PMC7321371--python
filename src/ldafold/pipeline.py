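"""End-to-end prediction: select → superpose → partition → reduce → sample → refine.

The run follows the stage order of the method:

1.  score every template with the configured energy model;
2.  keep the templates at or below the energy-percentile cutoff (default
    30th percentile);
3.  superpose the survivors onto the best (lowest-energy) decoy;
4.  partition them into ``n_classes`` energy classes (1-D k-means);
5.  build the shrinkage-regularized discriminant basis (``lda_dim``
    directions, default 4) and append the HF residual of the best decoy —
    5 reduced-basis terms under the defaults;
6.  derive the prismatic search bounds from the template projections and
    sample the reduced space with the swarm optimizer (40 × 50 default);
7.  if the sampled optimum does not beat the best decoy's energy, fall
    back to the best decoy;
8.  refine over the three SVD coordinates (accept-if-better);
9.  optionally evaluate against a native structure.

Every stage logs one structured line; with an ``output_dir`` the predicted
structure (PDB), a JSON report, the optimizer trace (TSV) and the echoed
configuration are written for provenance.  Runs are bit-reproducible from
(inputs, seed).
"""

from __future__ import annotations

import glob
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import lda, swarm
from .energy import (
    GoEnergy,
    SelectionResult,
    SurrogateEnergy,
    TableEnergy,
    load_energy_table,
    select_templates,
)
from .lda import ClassPartition, ReducedBasis, SearchSpace, TemplateEnsemble
from .structures import CaTrace, CorrespondenceError, flatten, read_ca_trace, superpose, unflatten, write_ca_trace, rmsd
from .svdrefine import RefineConfig, RefineReport, refine
from .swarm import OptimizationResult, SwarmConfig, optimize, write_trace

__all__ = [
    "RunConfig",
    "PredictionResult",
    "ConfigurationError",
    "run_prediction",
    "evaluate_vs_native",
    "build_energy_model",
    "load_templates",
]

logger = logging.getLogger("ldafold")


class ConfigurationError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything a prediction run needs; defaults follow the method's setup."""

    template_dir: str = ""
    native_path: str | None = None
    energy_model: str = "surrogate"
    energy_params: dict = field(default_factory=dict)
    percentile: float = 30.0
    n_classes: int = 4
    lda_dim: int = 4
    margin: float = 0.1
    energy_tolerance: float | None = None
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.n_classes <= lda.MAX_CLASSES:
            raise ConfigurationError(
                f"n_classes must be in [2, {lda.MAX_CLASSES}], got {self.n_classes}"
            )
        if self.lda_dim < 1 or self.lda_dim > self.n_classes:
            raise ConfigurationError(
                f"lda_dim must be in [1, n_classes={self.n_classes}], got {self.lda_dim}"
            )
        if self.lda_dim > self.n_classes - 1:
            logger.warning(
                "lda_dim=%d exceeds the between-class scatter rank bound "
                "(n_classes-1=%d); the extra direction is regularization-dominated",
                self.lda_dim, self.n_classes - 1,
            )
        if not 0.0 < self.percentile < 100.0:
            raise ConfigurationError("percentile must be in (0, 100)")
        if self.margin < 0:
            raise ConfigurationError("margin must be non-negative")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "swarm" in payload and isinstance(payload["swarm"], dict):
            payload["swarm"] = SwarmConfig(**payload["swarm"])
        if "refine" in payload and isinstance(payload["refine"], dict):
            ref = dict(payload["refine"])
            if "swarm" in ref and isinstance(ref["swarm"], dict):
                ref["swarm"] = SwarmConfig(**ref["swarm"])
            payload["refine"] = RefineConfig(**ref)
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PredictionResult:
    """Everything a run produced, mirroring the per-stage artifacts."""

    predicted: CaTrace
    predicted_energy: float
    best_template_energy: float
    rmsd_to_native: float | None
    optimizer_result: OptimizationResult
    refine_report: RefineReport
    selection: SelectionResult
    partition: ClassPartition
    basis: ReducedBasis
    space: SearchSpace
    n_models_within_tolerance: int | None


def build_energy_model(config: RunConfig):
    """Instantiate the configured energy model by name."""
    name = config.energy_model
    params = dict(config.energy_params)
    if name == "surrogate":
        return SurrogateEnergy(**params)
    if name == "go":
        ref_path = params.pop("reference_path", None)
        if ref_path is None:
            raise ConfigurationError("go energy model requires energy_params.reference_path")
        reference = read_ca_trace(ref_path)
        return GoEnergy(reference=reference, **params)
    if name == "table":
        table_path = params.pop("table_path", None)
        if table_path is None:
            raise ConfigurationError("table energy model requires energy_params.table_path")
        return TableEnergy(table=load_energy_table(table_path))
    raise ConfigurationError(f"unknown energy model {name!r}")


def load_templates(template_dir: str) -> list[CaTrace]:
    """Read all ``*.pdb`` files of a directory (sorted by name) as Cα traces."""
    paths = sorted(glob.glob(os.path.join(template_dir, "*.pdb")))
    if len(paths) < 5:
        raise ConfigurationError(
            f"need at least 5 template PDB files in {template_dir!r}, found {len(paths)}"
        )
    traces = [read_ca_trace(p) for p in paths]
    counts = {t.residue_count for t in traces}
    if len(counts) != 1:
        raise ConfigurationError(
            f"templates must share a residue count; found {sorted(counts)}"
        )
    return traces


def _stage(name: str, started: float, **stats) -> None:
    extra = " ".join(f"{k}={v}" for k, v in stats.items())
    logger.info("stage=%s elapsed=%.3fs %s", name, time.perf_counter() - started, extra)


def run_prediction(config: RunConfig, templates: list[CaTrace] | None = None,
                   energy_model=None) -> PredictionResult:
    """Execute the full prediction pipeline.

    ``templates`` and ``energy_model`` may be passed directly (library use);
    otherwise they are loaded/built from the configuration.
    """
    t0 = time.perf_counter()
    if templates is None:
        templates = load_templates(config.template_dir)
    if len(templates) < 5:
        raise ConfigurationError(f"need at least 5 templates, got {len(templates)}")
    counts = {t.residue_count for t in templates}
    if len(counts) != 1:
        raise ConfigurationError(f"templates must share a residue count; found {sorted(counts)}")
    if energy_model is None:
        energy_model = build_energy_model(config)
    _stage("load", t0, n_templates=len(templates), residues=templates[0].residue_count)

    # 1-2: score and select
    t = time.perf_counter()
    energies = np.array([float(energy_model(tr)) for tr in templates])
    selection = select_templates(energies, config.percentile)
    kept = selection.kept_indices
    if kept.size < config.n_classes:
        raise ConfigurationError(
            f"only {kept.size} templates survive the {config.percentile}th percentile; "
            f"need at least n_classes={config.n_classes}"
        )
    _stage("select", t, kept=kept.size, cutoff=f"{selection.cutoff_energy:.4g}")

    # 3: superpose survivors onto the best decoy (ties by label order)
    t = time.perf_counter()
    kept_energies = energies[kept]
    best_order = sorted(range(kept.size), key=lambda i: (kept_energies[i], templates[kept[i]].label))
    best_local = best_order[0]
    best_trace = templates[kept[best_local]]
    superposed = []
    for i in kept:
        _, moved = superpose(templates[i], best_trace)
        superposed.append(moved)
    ensemble = TemplateEnsemble.from_traces(superposed, kept_energies)
    m_best = ensemble.X[:, best_local]
    best_template_energy = float(kept_energies[best_local])
    _stage("superpose", t, reference=best_trace.label)

    # 4: energy partition
    t = time.perf_counter()
    partition = lda.kmeans_energy_partition(kept_energies, config.n_classes, seed=config.seed)
    _stage("partition", t, sizes=partition.class_sizes.tolist())

    # 5: regularized discriminant basis + HF term
    t = time.perf_counter()
    scatter = lda.compute_scatter(ensemble, partition)
    b_rows, w_rows = lda.scatter_samples(ensemble, partition)
    sb_reg = lda.shrink_scatter(scatter.SB, b_rows)
    sw_reg = lda.shrink_scatter(scatter.SW, w_rows)
    Vd = lda.lda_basis(sb_reg, sw_reg, config.lda_dim)
    basis = lda.append_hf_term(Vd, scatter.mu, m_best)
    _stage("reduce", t, lambda_B=f"{sb_reg.lambda_:.3g}", lambda_W=f"{sw_reg.lambda_:.3g}",
           columns=basis.n_columns, hf_degenerate=basis.hf_degenerate)

    # 6: bounded swarm sampling of the reduced space
    t = time.perf_counter()
    space = lda.search_bounds(basis, ensemble, config.margin)

    def objective(a: np.ndarray) -> float:
        return float(energy_model(unflatten(lda.reconstruct(basis, a), label="sample")))

    swarm_config = SwarmConfig(
        swarm_size=config.swarm.swarm_size,
        iterations=config.swarm.iterations,
        seed=config.seed if config.swarm.seed == 0 else config.swarm.seed,
        collapse_threshold=config.swarm.collapse_threshold,
        variant=config.swarm.variant,
    )
    opt = optimize(objective, space, swarm_config)
    _stage("sample", t, best=f"{opt.best_value:.6g}", collapsed_at=opt.collapsed_at)

    # 7: fall back to the best decoy if sampling found nothing better
    if opt.best_value <= best_template_energy:
        candidate_vec = lda.reconstruct(basis, opt.best_position)
        candidate_energy = opt.best_value
    else:
        candidate_vec = m_best
        candidate_energy = best_template_energy
        logger.info("stage=fallback reason=sampled_optimum_worse_than_best_decoy")
    candidate = unflatten(candidate_vec, label="predicted")

    # 8: SVD-coordinate refinement (accept-if-better)
    t = time.perf_counter()
    refine_config = RefineConfig(
        delta=config.refine.delta,
        swarm=SwarmConfig(
            swarm_size=config.refine.swarm.swarm_size,
            iterations=config.refine.swarm.iterations,
            seed=config.seed + 1 if config.refine.swarm.seed == 0 else config.refine.swarm.seed,
            collapse_threshold=config.refine.swarm.collapse_threshold,
            variant=config.refine.swarm.variant,
        ),
    )
    predicted, refine_report = refine(candidate, energy_model, refine_config)
    predicted = predicted.copy(label="predicted")
    predicted_energy = min(refine_report.refined_energy, candidate_energy)
    _stage("refine", t, accepted=refine_report.accepted,
           energy=f"{predicted_energy:.6g}")

    # 9: optional evaluation against the native structure
    rmsd_to_native = None
    if config.native_path:
        native = read_ca_trace(config.native_path)
        rmsd_to_native = evaluate_vs_native(predicted, native)["rmsd"]
        _stage("evaluate", time.perf_counter(), rmsd_to_native=f"{rmsd_to_native:.4f}")

    n_within = None
    if config.energy_tolerance is not None:
        n_within = int(np.sum(opt.sampled_values <= config.energy_tolerance))

    result = PredictionResult(
        predicted=predicted,
        predicted_energy=float(predicted_energy),
        best_template_energy=best_template_energy,
        rmsd_to_native=rmsd_to_native,
        optimizer_result=opt,
        refine_report=refine_report,
        selection=selection,
        partition=partition,
        basis=basis,
        space=space,
        n_models_within_tolerance=n_within,
    )
    if config.output_dir:
        _write_outputs(config, result)
    _stage("done", t0, energy=f"{result.predicted_energy:.6g}")
    return result


def evaluate_vs_native(predicted: CaTrace, native: CaTrace) -> dict:
    """Superposed Cα RMSD plus the per-residue deviation profile."""
    if predicted.residue_count != native.residue_count:
        raise CorrespondenceError(
            f"residue counts differ: {predicted.residue_count} vs {native.residue_count}"
        )
    result, moved = superpose(predicted, native)
    per_residue = np.linalg.norm(moved.coords - native.coords, axis=1)
    return {"rmsd": result.rmsd, "per_residue_deviation": per_residue}


def _write_outputs(config: RunConfig, result: PredictionResult) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    write_ca_trace(result.predicted, os.path.join(out, "predicted.pdb"))
    write_trace(result.optimizer_result, os.path.join(out, "optimizer_trace.tsv"))
    result.basis.to_json(os.path.join(out, "reduced_basis.json"))
    report = {
        "predicted_energy": result.predicted_energy,
        "best_template_energy": result.best_template_energy,
        "energy_model": config.energy_model,
        "rmsd_to_native": result.rmsd_to_native,
        "selection": {
            "percentile": result.selection.percentile,
            "cutoff_energy": result.selection.cutoff_energy,
            "n_kept": int(result.selection.kept_indices.size),
        },
        "partition_sizes": result.partition.class_sizes.tolist(),
        "basis_columns": result.basis.n_columns,
        "collapsed_at": result.optimizer_result.collapsed_at,
        "n_sampled_models": int(result.optimizer_result.sampled_values.size),
        "n_models_within_tolerance": result.n_models_within_tolerance,
        "refine": {
            "input_energy": result.refine_report.input_energy,
            "refined_energy": result.refine_report.refined_energy,
            "accepted": result.refine_report.accepted,
            "betas": result.refine_report.betas.tolist(),
            "alphas": result.refine_report.alphas.tolist(),
        },
        "search_space": {
            "lower": result.space.lower.tolist(),
            "upper": result.space.upper.tolist(),
        },
    }
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)
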