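"""End-to-end orchestration with seeded reproducibility and JSON reports.

The pipeline runs: informative-gene filter -> PCA permutation validation ->
covariance PCA -> K selection (elbow, unless fixed) -> simplex fit ->
t-ratio randomization test -> bootstrap -> defining-gene selection ->
overlap summary -> gene-set enrichment -> attribute tests.  Every stochastic
stage derives its seed deterministically from the master seed and the stage
name, so identical configs and inputs give identical reports (wall times
excepted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enrichment import hypergeometric_enrichment, test_attributes
from .genes import archetype_gene_coefficients, overlap_summary, select_defining_genes
from .io import (
    AttributeTable,
    ExpressionMatrix,
    GeneSetCollection,
    filter_informative_genes,
    read_attributes,
    read_expression_matrix,
    read_gmt,
)
from .pca import fit_pca, pca_permutation_test
from .simplex import bootstrap_archetypes, fit_simplex, select_k_elbow
from .tratio import t_ratio_test

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


@dataclass
class RunConfig:
    matrix: str | None = None
    gmt: str | None = None
    attributes: str | None = None
    outdir: str | None = None
    orientation: str = "samples_by_genes"
    sd_min: float = 1.0
    var_min: float = 1.0
    dims: int = 8
    k: int | str = "auto"
    k_min: int = 2
    k_max: int = 8
    n_restarts: int = 10
    n_rand: int = 1000
    n_perm: int = 100
    n_boot: int = 1000
    bin_fraction: float = 0.1
    alpha: float = 0.05
    scheme: str = "shuffle_genes_then_pca"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.partial = partial


def run_pipeline(
    config: RunConfig,
    expression: ExpressionMatrix | None = None,
    gene_sets: GeneSetCollection | None = None,
    attributes: AttributeTable | None = None,
) -> dict:
    """Execute the full analysis; returns a JSON-serializable report.

    Inputs may be passed in memory or read from the paths in ``config``.
    On stage failure a :class:`PipelineError` carries the partial report.
    """
    report: dict = {
        "version": __version__,
        "config": _jsonify(dataclasses.asdict(config)),
        "stages": {},
        "wall_time_s": {},
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        if expression is None:
            if config.matrix is None:
                raise ValueError("no expression matrix provided")
            expression = read_expression_matrix(config.matrix, config.orientation)
        if gene_sets is None and config.gmt:
            gene_sets = read_gmt(config.gmt)
        if attributes is None and config.attributes:
            attributes = read_attributes(config.attributes, known_samples=expression.sample_ids)
        report["wall_time_s"][stage] = time.perf_counter() - t0

        stage = "filter"
        t0 = time.perf_counter()
        filtered = filter_informative_genes(expression, config.sd_min, config.var_min)
        report["stages"]["filter"] = {
            "n_genes_in": expression.n_genes,
            "n_genes_kept": filtered.n_genes,
            "n_samples": filtered.n_samples,
        }
        report["wall_time_s"][stage] = time.perf_counter() - t0

        stage = "pca_validation"
        t0 = time.perf_counter()
        val = pca_permutation_test(
            filtered, config.n_perm, seed=stage_seed(config.seed, stage), alpha=config.alpha,
            max_pcs=config.dims,
        )
        report["stages"][stage] = {
            "psi_observed": val.psi_observed,
            "phi_observed": val.phi_observed,
            "p_psi": val.p_psi,
            "p_phi": val.p_phi,
            "p_psi_uncorrected": val.p_psi_uncorrected,
            "n_significant_pcs": val.n_significant_pcs,
            "genes_significant_per_pc": _jsonify(val.genes_significant_per_pc),
            "n_permutations": val.n_permutations,
        }
        report["wall_time_s"][stage] = time.perf_counter() - t0

        stage = "pca"
        t0 = time.perf_counter()
        dims = min(config.dims, filtered.n_samples - 1, filtered.n_genes)
        pca = fit_pca(filtered, dims)
        report["stages"][stage] = {
            "dims": dims,
            "explained_fraction": _jsonify(pca.explained_fraction),
            "total_explained": float(pca.explained_fraction.sum()),
        }
        report["wall_time_s"][stage] = time.perf_counter() - t0

        stage = "select_k"
        t0 = time.perf_counter()
        if config.k == "auto":
            k, curve = select_k_elbow(
                pca.scores,
                k_min=config.k_min,
                k_max=config.k_max,
                seed=stage_seed(config.seed, stage),
                n_restarts=config.n_restarts,
                return_curve=True,
            )
            report["stages"][stage] = {"k": k, "esv_curve": curve}
        else:
            k = int(config.k)
            report["stages"][stage] = {"k": k, "esv_curve": None}
        report["wall_time_s"][stage] = time.perf_counter() - t0

        stage = "fit"
        t0 = time.perf_counter()
        fit = fit_simplex(
            pca.scores, k, n_restarts=config.n_restarts, seed=stage_seed(config.seed, stage)
        )
        report["stages"][stage] = {
            "k": fit.k,
            "esv": fit.esv,
            "algorithm": fit.algorithm,
            "vertex_sample_ids": [filtered.sample_ids[i] for i in fit.vertex_sample_indices],
            "archetypes_pc": _jsonify(fit.archetypes_pc),
        }
        report["wall_time_s"][stage] = time.perf_counter() - t0

        stage = "t_ratio"
        t0 = time.perf_counter()
        tres = t_ratio_test(
            filtered if config.scheme == "shuffle_genes_then_pca" else pca.scores,
            k=k,
            n_rand=config.n_rand,
            scheme=config.scheme,
            seed=stage_seed(config.seed, stage),
            n_restarts=config.n_restarts,
        )
        report["stages"][stage] = {
            "t_observed": tres.t_observed,
            "p_value": tres.p_value,
            "p_uncorrected": tres.p_uncorrected,
            "n_randomizations": tres.n_randomizations,
            "scheme": tres.randomization_scheme,
        }
        report["wall_time_s"][stage] = time.perf_counter() - t0

        stage = "bootstrap"
        t0 = time.perf_counter()
        boot = bootstrap_archetypes(
            pca.scores,
            k,
            n_boot=config.n_boot,
            seed=stage_seed(config.seed, stage),
            n_restarts=config.n_restarts,
            reference=fit,
        )
        report["stages"][stage] = {
            "n_boot": boot.n_boot,
            "n_dropped": boot.n_dropped,
            "ellipse_areas": {f"PC{a + 1}-PC{b + 1}": _jsonify(v) for (a, b), v in boot.ellipse_areas.items()},
        }
        report["wall_time_s"][stage] = time.perf_counter() - t0

        stage = "genes"
        t0 = time.perf_counter()
        profiles = archetype_gene_coefficients(fit, pca)
        lists = select_defining_genes(profiles)
        overlap = overlap_summary(lists)
        report["stages"][stage] = {
            "positive_genes": lists.positive_genes,
            "negative_genes": lists.negative_genes,
            "positive_cutoffs": lists.positive_cutoffs,
            "negative_cutoffs": lists.negative_cutoffs,
            "n_unique_genes": overlap.n_unique_genes,
            "n_shared_genes": overlap.n_shared_genes,
            "shared_fraction": overlap.shared_fraction,
            "pairwise_counts": _jsonify(overlap.pairwise_counts),
            "ribbon_table": _jsonify(overlap.ribbon_table),
        }
        report["wall_time_s"][stage] = time.perf_counter() - t0

        if gene_sets is not None:
            stage = "enrichment"
            t0 = time.perf_counter()
            enr = {}
            for a in range(k):
                for sign, genes in (("positive", lists.positive_genes[a]),
                                    ("negative", lists.negative_genes[a])):
                    res = hypergeometric_enrichment(genes, gene_sets, filtered.gene_ids)
                    enr[f"archetype{a + 1}_{sign}"] = _jsonify(res)
            report["stages"][stage] = enr
            report["wall_time_s"][stage] = time.perf_counter() - t0

        if attributes is not None:
            stage = "attributes"
            t0 = time.perf_counter()
            assoc = test_attributes(fit, attributes, filtered.sample_ids, config.bin_fraction)
            report["stages"][stage] = _jsonify(assoc)
            report["wall_time_s"][stage] = time.perf_counter() - t0
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc, report) from exc

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
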