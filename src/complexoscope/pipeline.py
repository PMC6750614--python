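"""End-to-end orchestration: assemble -> filter -> score -> cluster -> report.

``run_pipeline`` executes the full analysis from one configuration:
quantifiability filtering, median normalization, ortholog collapse,
complex coverage filtering and scoring (curated-database branch and
PPI-clique branch), Ward clustering of relative score profiles, the
low-variance (conserved-complex) subset, shared-protein k-means, and the
species-level overview (PCA, Pearson). Every stage's record count lands
in a machine-readable manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clustering, complexes, io as cio
from .assembly import collapse_to_reference, median_normalize, quantifiability_filter
from .datatypes import DataModelError, FilterPolicy


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """One-file configuration for a full run."""

    quant_tables: dict[str, str]  # species id -> TSV path
    ortholog_map: str
    complex_db: str
    ppi_edges: str | None = None
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    k_complex_clusters: int = 6
    k_ppi_clusters: int = 8
    k_protein_clusters: int = 6
    k_subset_clusters: int = 4
    variance_threshold: float = 0.20
    fold_change_threshold: float = 1.5
    seed: int = 0

    def validate_paths(self) -> None:
        paths = dict(self.quant_tables)
        paths["ortholog_map"] = self.ortholog_map
        paths["complex_db"] = self.complex_db
        if self.ppi_edges is not None:
            paths["ppi_edges"] = self.ppi_edges
        for name, p in paths.items():
            if not Path(p).exists():
                raise PipelineError(f"config: missing input for {name!r}: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        policy = FilterPolicy(**raw.pop("filter_policy", {}))
        return cls(filter_policy=policy, **raw)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write all outputs plus a run manifest."""
    config.validate_paths()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except DataModelError as err:
            raise PipelineError(f"stage {name!r}: {err}") from err

    tables = {
        sp: stage("read_quant_table", cio.read_quant_table, path, sp)
        for sp, path in config.quant_tables.items()
    }
    counts["proteins_identified"] = sum(len(t) for t in tables.values())

    filtered = {sp: stage("quantifiability_filter", quantifiability_filter, t)
                for sp, t in tables.items()}
    counts["proteins_quantifiable"] = sum(len(t) for t in filtered.values())

    normalized = stage("median_normalize", median_normalize, list(filtered.values()))
    omap = stage("read_ortholog_map", cio.read_ortholog_map, config.ortholog_map)
    matrix = stage("collapse_to_reference", collapse_to_reference, normalized, omap)
    counts["reference_proteins"] = len(matrix.values)
    counts["reference_proteins_multi_entry"] = int(
        (matrix.n_contributors > 1).any(axis=1).sum())
    cio.write_reference_matrix(matrix.values, outdir / "reference_matrix.tsv")

    detected = matrix.detected_sets()

    def complex_branch(db, tag: str, k: int):
        passing, report = stage("filter_complexes", complexes.filter_complexes,
                                db, detected, config.filter_policy)
        counts[f"{tag}_complexes_parsed"] = len(db)
        counts[f"{tag}_complexes_passing"] = len(passing)
        complexes.filter_report_frame(report).to_csv(
            outdir / f"{tag}_filter_report.tsv", sep="\t", index=False)
        if not passing:
            return None, None
        scores = stage("build_score_matrix", complexes.build_score_matrix, passing, matrix)
        cio.write_score_matrix(scores, outdir / f"{tag}_scores.tsv")
        k_eff = min(k, len(scores.scores))
        profile = clustering.relative_profile(scores.scores)
        assign = stage("ward_cut", clustering.ward_cut, profile, k_eff)
        cio.write_cluster_assignment(assign, outdir / f"{tag}_clusters.tsv")
        return scores, assign

    db = stage("read_complex_db", cio.read_complex_db, config.complex_db)
    scores, _ = complex_branch(db, "corum", config.k_complex_clusters)
    if scores is not None:
        conserved = complexes.low_variance_complexes(scores, config.variance_threshold)
        counts["complexes_low_variance"] = len(conserved)
        pd.Series(conserved, name="complex_id").to_csv(
            outdir / "low_variance_complexes.tsv", sep="\t", index=False)

    if config.ppi_edges is not None:
        graph = stage("read_ppi_edges", cio.read_ppi_edges, config.ppi_edges)
        counts["ppi_nodes"] = graph.number_of_nodes()
        counts["ppi_edges"] = graph.number_of_edges()
        ppi_db = complexes.expand_ppi_to_complexes(graph)
        complex_branch(ppi_db, "ppi", config.k_ppi_clusters)

    shared = matrix.values.dropna()
    counts["proteins_shared_all_species"] = len(shared)
    if len(shared) >= config.k_protein_clusters:
        profiles = clustering.relative_profile(shared)
        assign = clustering.kmeans_profiles(
            profiles, config.k_protein_clusters, seed=config.seed)
        cio.write_cluster_assignment(assign, outdir / "protein_kmeans.tsv")

    corr = clustering.pearson_matrix(matrix.values)
    corr.to_csv(outdir / "pearson_matrix.tsv", sep="\t", float_format="%.17g")
    if len(shared) >= 2:
        _, var_explained = clustering.pca_overview(clustering.relative_profile(shared))
        pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(var_explained))],
                      "variance_explained": var_explained}).to_csv(
            outdir / "pca_variance.tsv", sep="\t", index=False, float_format="%.17g")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "filter_policy": {
                "min_members": config.filter_policy.min_members,
                "small_max_size": config.filter_policy.small_max_size,
                "small_min_coverage": config.filter_policy.small_min_coverage,
                "large_min_coverage": config.filter_policy.large_min_coverage,
            },
            "k_complex_clusters": config.k_complex_clusters,
            "k_ppi_clusters": config.k_ppi_clusters,
            "k_protein_clusters": config.k_protein_clusters,
            "variance_threshold": config.variance_threshold,
            "fold_change_threshold": config.fold_change_threshold,
        },
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
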