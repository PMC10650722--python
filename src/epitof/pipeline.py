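"""Orchestrated end-to-end runs with a single config and a run manifest.

``run_epitof_pipeline`` executes simulate/load -> normalize -> subsample
-> embed -> cluster -> statistics and writes every stage table plus a
manifest (parameters, seeds, library versions, sha256 digests of the
outputs) so that a run can be reproduced exactly. ``run_atac_pipeline``
does the same for the region-count differential stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .atac import DifferentialAccessibility, read_region_counts, write_region_counts
from .embedding import SubsampleSpec
from .model import EpiTofModel
from .normalize import TransformSpec, ValidationError
from .panels import MarkerPanel
from .simulate import (EpiTofSimConfig, simulate_epitof, simulate_region_counts,
                       write_ground_truth)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One config for a full run; every study parameter has its value here."""

    output_dir: str = "epitof_run"
    seed: int = 0
    # EpiTOF stage ------------------------------------------------------
    cells_path: Optional[str] = None       # TSV; None -> simulate
    panel_path: Optional[str] = None       # JSON sidecar, required with cells_path
    simulation: Optional[dict] = None      # EpiTofSimConfig overrides
    transform: str = "scale"
    cofactor: float = 50.0
    subsample_target: int = 10_000
    n_neighbors: int = 15
    min_dist: float = 0.1
    k: int = 1000
    alpha: float = 0.05
    signature_family: str = "global"
    # ATAC stage --------------------------------------------------------
    counts_path: Optional[str] = None      # BED-like TSV; None -> simulate
    groups_path: Optional[str] = None      # sample\tgroup TSV with counts_path
    atac_simulation: Optional[dict] = None
    min_fc: float = 2.0
    normalization: str = "median_of_ratios"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_fc < 1:
            raise ValidationError("min_fc must be >= 1")
        if self.subsample_target < 1:
            raise ValidationError("subsample_target must be >= 1")
        for path in (self.cells_path, self.panel_path, self.counts_path,
                     self.groups_path):
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input path does not exist: {path}")
        if self.cells_path is not None and self.panel_path is None:
            raise ValidationError("cells_path requires panel_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest_base(config: RunConfig) -> dict:
    import scipy
    import sklearn

    return {
        "epitof_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "scipy": scipy.__version__, "scikit_learn": sklearn.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {},
    }


def _write_manifest(manifest: dict, outdir: Path) -> Path:
    for name in sorted(manifest["outputs"]):
        manifest["outputs"][name] = _sha256(outdir / name)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_epitof_pipeline(config: RunConfig) -> dict:
    """Run the single-cell stage end to end; returns the manifest dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_base(config)

    if config.cells_path is not None:
        panel = MarkerPanel.from_json(config.panel_path)
        cells = io.read_cell_matrix(config.cells_path, panel)
        truth = None
    else:
        sim_kwargs = dict(config.simulation or {})
        sim_kwargs.setdefault("seed", config.seed)
        if "subpop_effects" in sim_kwargs:
            sim_kwargs["subpop_effects"] = {
                (int(k.split("|")[0]), k.split("|")[1]): v
                for k, v in sim_kwargs["subpop_effects"].items()}
        sim = EpiTofSimConfig(**sim_kwargs)
        cells, truth = simulate_epitof(sim)
        io.write_cell_matrix(cells, outdir / "cells.tsv")
        cells.panel.to_json(outdir / "panel.json")
        write_ground_truth(truth, outdir / "ground_truth.json")
        manifest["outputs"].update(
            {"cells.tsv": "", "panel.json": "", "ground_truth.json": ""})

    model = EpiTofModel(
        cells,
        transform=TransformSpec(kind=config.transform, cofactor=config.cofactor),
        subsample=SubsampleSpec(target=config.subsample_target),
        n_neighbors=config.n_neighbors, min_dist=config.min_dist,
        k=config.k, alpha=config.alpha,
        signature_family=config.signature_family)
    results = model.fit(seed=config.seed)

    io.write_normalized_matrix(results.normalization.normalized,
                               outdir / "normalized.tsv")
    emb = pd.DataFrame(results.embedding.coords, columns=["UMAP1", "UMAP2"])
    emb.insert(0, "sample_id", results.subset.sample_id.to_numpy())
    emb.insert(1, "group", results.subset.group.to_numpy())
    emb["cluster"] = results.clusters.labels
    emb.to_csv(outdir / "embedding.tsv", sep="\t", index=False,
               float_format="%.17g")
    emb[["sample_id", "group", "cluster"]].to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)
    results.composition.proportions.to_csv(outdir / "composition.tsv", sep="\t",
                                           float_format="%.17g")
    results.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                              float_format="%.17g")
    results.signatures.to_csv(outdir / "signatures.tsv", sep="\t", index=False,
                              float_format="%.17g")
    results.heatmap.medians.to_csv(outdir / "heatmap.tsv", sep="\t",
                                   float_format="%.17g")
    (outdir / "heatmap_orders.json").write_text(json.dumps({
        "row_order": [int(c) for c in results.heatmap.row_order],
        "col_order": list(results.heatmap.col_order),
        "fold_change": {int(c): (None if not np.isfinite(v) else v)
                        for c, v in results.heatmap.fold_change.items()},
        "category": {int(c): v for c, v in results.heatmap.category.items()},
    }, indent=2) + "\n")
    manifest["outputs"].update({name: "" for name in (
        "normalized.tsv", "embedding.tsv", "clusters.tsv", "composition.tsv",
        "enrichment.tsv", "signatures.tsv", "heatmap.tsv",
        "heatmap_orders.json")})
    manifest["summary"] = {
        "n_cells": int(results.subset.n_cells),
        "n_clusters": int(results.n_clusters),
        "n_enriched_clusters":
            int((results.enrichment["direction"] != "ns").sum()),
        "n_significant_marks": int(results.signatures["significant"].sum()),
    }
    _write_manifest(manifest, outdir)
    log.info("EpiTOF pipeline complete: %s", outdir / "manifest.json")
    return manifest


def run_atac_pipeline(config: RunConfig) -> dict:
    """Run the differential-accessibility stage; returns the manifest dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_base(config)

    if config.counts_path is not None:
        groups = pd.read_csv(config.groups_path, sep="\t",
                             index_col=0).iloc[:, 0]
        matrix = read_region_counts(config.counts_path, groups)
    else:
        sim_kwargs = dict(config.atac_simulation or {})
        sim_kwargs.setdefault("seed", config.seed)
        sim_kwargs.setdefault("n_regions", 1000)
        sim_kwargs.setdefault("n_per_group", 5)
        sim_kwargs.setdefault("frac_diff", 0.1)
        sim_kwargs.setdefault("log2fc", 3.0)
        sim_kwargs.setdefault("dispersion", 0.05)
        matrix, truth = simulate_region_counts(**sim_kwargs)
        write_region_counts(matrix, outdir / "counts.tsv")
        write_ground_truth(truth, outdir / "atac_ground_truth.json")
        manifest["outputs"].update(
            {"counts.tsv": "", "atac_ground_truth.json": ""})

    results = DifferentialAccessibility(
        matrix, alpha=config.alpha, min_fc=config.min_fc,
        normalization=config.normalization).fit()
    results.table.to_csv(outdir / "differential.tsv", sep="\t", index=False,
                         float_format="%.17g")
    results.volcano_table().to_csv(outdir / "volcano.tsv", sep="\t",
                                   index=False, float_format="%.17g")
    (outdir / "summary.json").write_text(json.dumps(
        {"n_regions": len(results.table),
         "n_up": results.n_up, "n_down": results.n_down}, indent=2) + "\n")
    manifest["outputs"].update({name: "" for name in (
        "differential.tsv", "volcano.tsv", "summary.json")})
    manifest["summary"] = {"n_up": results.n_up, "n_down": results.n_down}
    _write_manifest(manifest, outdir)
    log.info("ATAC pipeline complete: %s", outdir / "manifest.json")
    return manifest
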