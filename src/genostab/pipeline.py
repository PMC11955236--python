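"""End-to-end stability analysis: bootstrap, PS, PCS and per-row PSVs.

`run_analysis` ties the pieces together: generate bootstrap-replicate
embeddings of one genotype dataset, score the overall stability (PS), the
k-means cluster stability (PCS) and the per-row support values (PSVs), and
return them in a single report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import BootstrapRun, run_bootstrap
from .clustering import pandora_cluster_stability
from .io import GenotypeDataset
from .procrustes import pandora_stability
from .support import SupportVector, align_to_reference, pandora_support_values

REPORT_SCHEMA_VERSION = 1


@dataclass
class StabilityReport:
    """Everything one stability run produced."""

    ps: float
    pcs: float
    k: int
    psv: SupportVector
    n_replicates: int
    converged: bool
    seed: int
    config: dict = field(default_factory=dict)
    run: BootstrapRun | None = None

    def to_json_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "ps": round(float(self.ps), 12),
            "pcs": round(float(self.pcs), 12),
            "k": int(self.k),
            "n_replicates": int(self.n_replicates),
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "psv_mean": round(float(self.psv.values.mean()), 12),
            "psv_min": round(float(self.psv.values.min()), 12),
            "config": self.config,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_analysis(
    dataset: GenotypeDataset,
    analysis: str = "pca",
    n_components: int | None = None,
    distance_metric: str = "euclidean",
    distance_level: str = "individual",
    project_ids: tuple[str, ...] = (),
    n_max: int = 100,
    tolerance: float = 0.05,
    disable_convergence: bool = False,
    threads: int = 1,
    seed: int = 0,
    k: int | None = None,
    fix_bootstrap_identity: bool = False,
) -> StabilityReport:
    """Bootstrap the embedding of ``dataset`` and score PS, PCS and PSVs.

    ``analysis`` is "pca" (10 components by default, optional least-squares
    projection of ``project_ids``) or "mds" (2 components by default, on the
    chosen distance metric and level). ``k`` overrides the BIC grid search
    for the number of k-means clusters. ``fix_bootstrap_identity`` replaces
    every replicate's resampled SNP indices by the identity (test hook).
    """
    if analysis not in ("pca", "mds"):
        raise ValueError(f"analysis must be 'pca' or 'mds', got {analysis!r}")
    if n_components is None:
        n_components = 10 if analysis == "pca" else 2
    method_params: dict = {"n_components": n_components}
    if analysis == "pca":
        method_params["project_ids"] = tuple(project_ids)
    else:
        method_params["metric"] = distance_metric
        method_params["level"] = distance_level

    run = run_bootstrap(
        dataset,
        method=analysis,
        method_params=method_params,
        n_max=n_max,
        tolerance=tolerance,
        threads=threads,
        master_seed=seed,
        disable_convergence=disable_convergence,
        fixed_indices=np.arange(dataset.n_snps) if fix_bootstrap_identity else None,
    )
    ps = pandora_stability(run.embeddings)
    populations = (
        list(dataset.populations)
        if run.embeddings[0].level == "individual"
        else list(run.embeddings[0].row_labels)
    )
    pcs, used_k = pandora_cluster_stability(
        run.embeddings, k=k, seed=seed, populations=populations
    )
    psv = pandora_support_values(align_to_reference(run.embeddings))
    config = {
        "analysis": analysis,
        "n_components": int(n_components),
        "distance_metric": distance_metric if analysis == "mds" else None,
        "distance_level": distance_level if analysis == "mds" else None,
        "project_ids": list(project_ids),
        "n_max": int(n_max),
        "tolerance": float(tolerance),
        "disable_convergence": bool(disable_convergence),
        "k": None if k is None else int(k),
    }
    return StabilityReport(
        ps=ps,
        pcs=pcs,
        k=used_k,
        psv=psv,
        n_replicates=run.n_computed,
        converged=run.converged,
        seed=seed,
        config=config,
        run=run,
    )


def write_outputs(report: StabilityReport, outdir, save_replicates: bool = False) -> Path:
    """Write report.json, psv.tsv and (optionally) per-replicate embeddings."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.write_json(outdir / "report.json")
    report.psv.write_tsv(outdir / "psv.tsv")
    if save_replicates and report.run is not None:
        repdir = outdir / "replicates"
        repdir.mkdir(exist_ok=True)
        for i, emb in enumerate(report.run.embeddings):
            emb.write_tsv(repdir / f"replicate_{i}.tsv")
    return outdir / "report.json"
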