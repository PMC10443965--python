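"""End-to-end orchestration: preprocess → DE → cluster → enrich → screen.

``run_pipeline`` is the in-memory engine used by the CLI, the examples and
the acceptance machinery; ``run_all`` wraps it with file I/O, a summary
JSON and per-stage TSV outputs so a whole analysis is one call (or one
shell command) from count matrices to candidate regulators.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .cluster import ClusterParams, ClusterResult, cluster_profiles, label_clusters
from .diffexp import DEConfig, DEResult, call_degs
from .enrich import enrich_clusters
from .preprocess import (
    MIRNA_DETECTION,
    MRNA_DETECTION,
    ConditionProfile,
    cpm_transform,
    condition_profiles,
    detection_filter,
    pca_qc,
)
from .screen import ScreenParams, screen_regulators

logger = logging.getLogger("mirscreen")


@dataclass
class RunConfig:
    """All stage thresholds plus the master seed; serializable for the sidecar."""

    mrna_detection: dict = field(default_factory=lambda: dict(MRNA_DETECTION))
    mirna_detection: dict = field(default_factory=lambda: dict(MIRNA_DETECTION))
    mrna_de: DEConfig = field(default_factory=lambda: DEConfig.for_kind("mRNA"))
    mirna_de: DEConfig = field(default_factory=lambda: DEConfig.for_kind("miRNA"))
    cluster: ClusterParams = field(default_factory=ClusterParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    detected_mrna: pd.Index
    detected_mirna: pd.Index
    mrna_profiles: ConditionProfile
    mirna_profiles: ConditionProfile
    mrna_de: DEResult
    mirna_de: DEResult
    clusters: ClusterResult
    set_enrichment: pd.DataFrame
    candidates: pd.DataFrame
    pca: dict

    def summary(self) -> dict:
        calls = self.mrna_de.feature_calls
        passing = (
            sorted(self.candidates.loc[self.candidates["passes"], "mirna"].unique())
            if not self.candidates.empty
            else []
        )
        return {
            "n_detected_genes": int(len(self.detected_mrna)),
            "n_detected_mirnas": int(len(self.detected_mirna)),
            "n_deg_down": int((calls["direction"] == "down").sum()),
            "n_deg_up": int((calls["direction"] == "up").sum()),
            "n_de_mirnas": int(self.mirna_de.feature_calls["is_de"].sum()),
            "n_clusters": int(self.clusters.n_clusters),
            "cluster_labels": dict(self.clusters.labels),
            "n_candidate_mirnas": len(passing),
            "candidate_mirnas": passing,
        }


def run_pipeline(
    mrna: mio.CountMatrix,
    mirna: mio.CountMatrix,
    targets: mio.TargetMap,
    gene_sets: mio.GeneSetCollection | None = None,
    config: RunConfig | None = None,
    skip_screen: bool = False,
) -> PipelineResult:
    """Run every stage in memory and return all intermediate results."""
    config = config or RunConfig()

    mrna_cpm = cpm_transform(mrna)
    mirna_cpm = cpm_transform(mirna)
    detected_mrna = detection_filter(mrna_cpm, **config.mrna_detection)
    detected_mirna = detection_filter(mirna_cpm, **config.mirna_detection)
    logger.info("detected %d genes, %d miRNAs", len(detected_mrna), len(detected_mirna))

    mrna_profiles = condition_profiles(mrna_cpm, detected_mrna)
    mirna_profiles = condition_profiles(mirna_cpm, detected_mirna)
    pca_fracs, pca_scores = pca_qc(mrna_cpm)

    mrna_de = call_degs(mrna, mrna_cpm, config.mrna_de, features=detected_mrna)
    mirna_de = call_degs(mirna, mirna_cpm, config.mirna_de, features=detected_mirna)

    cluster_params = dataclasses.replace(config.cluster, seed=config.seed)
    partitions = []
    for direction in ("down", "up"):
        degs = set(mrna_de.de_features(direction))
        part = cluster_profiles(mrna_profiles, degs, direction, cluster_params)
        partitions.append(part)
    assignments = pd.concat([p.assignments for p in partitions])
    cluster_means = pd.concat([p.cluster_means for p in partitions])
    clusters = ClusterResult(assignments, cluster_means)
    clusters = label_clusters(clusters, mrna_profiles)

    universe = set(detected_mrna)
    if gene_sets is not None and len(gene_sets):
        set_enrichment = enrich_clusters(clusters.cluster_sets(), gene_sets, universe)
    else:
        set_enrichment = pd.DataFrame()

    if skip_screen:
        candidates = pd.DataFrame()
    else:
        candidates = screen_regulators(
            mirna_de.de_features(),
            clusters,
            targets,
            mrna_profiles,
            mirna_profiles,
            universe,
            config.screen,
        )
    return PipelineResult(
        detected_mrna, detected_mirna, mrna_profiles, mirna_profiles,
        mrna_de, mirna_de, clusters, set_enrichment, candidates,
        {"variance_fractions": pca_fracs.tolist(), "scores": pca_scores},
    )


def run_all(
    mrna_counts: str | Path,
    mirna_counts: str | Path,
    sample_sheet: str | Path,
    target_map: str | Path,
    outdir: str | Path,
    gene_sets: str | Path | None = None,
    config: RunConfig | None = None,
    skip_screen: bool = False,
) -> PipelineResult:
    """File-based end-to-end run: read inputs, run the pipeline, write outputs."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in (mrna_counts, mirna_counts, sample_sheet):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    if not skip_screen and not Path(target_map).exists():
        raise FileNotFoundError(f"target map not found (required for screen): {target_map}")

    mrna = mio.read_counts(mrna_counts, sample_sheet, "mRNA")
    mirna = mio.read_counts(mirna_counts, sample_sheet, "miRNA")
    targets = (
        mio.read_target_map(target_map)
        if Path(target_map).exists()
        else mio.TargetMap(pd.DataFrame(columns=["mirna_id", "gene_id"]))
    )
    gsc = mio.read_gmt(gene_sets) if gene_sets else None

    result = run_pipeline(mrna, mirna, targets, gsc, config, skip_screen=skip_screen)

    mrna_cpm = cpm_transform(mrna)
    mrna_cpm.values.rename_axis("feature_id").to_csv(outdir / "cpm.tsv", sep="\t")
    pd.Series(result.detected_mrna).to_csv(
        outdir / "detected_genes.txt", index=False, header=False
    )
    pd.Series(result.detected_mirna).to_csv(
        outdir / "detected_mirnas.txt", index=False, header=False
    )
    result.mrna_profiles.mean_cpm.rename_axis("feature_id").to_csv(
        outdir / "profiles_mean.tsv", sep="\t"
    )
    result.mrna_profiles.standardized.rename_axis("feature_id").to_csv(
        outdir / "profiles_standardized.tsv", sep="\t"
    )
    result.pca["scores"].rename_axis("sample_id").to_csv(
        outdir / "pca_scores.tsv", sep="\t"
    )
    result.mrna_de.table.to_csv(outdir / "de_results_mrna.tsv", sep="\t", index=False)
    result.mirna_de.table.to_csv(outdir / "de_results_mirna.tsv", sep="\t", index=False)
    clusters_df = result.clusters.assignments.rename("cluster").rename_axis("feature_id").reset_index()
    clusters_df["label"] = clusters_df["cluster"].map(result.clusters.labels).fillna("")
    clusters_df.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    result.clusters.cluster_means.rename_axis("cluster").to_csv(
        outdir / "cluster_means.tsv", sep="\t"
    )
    if not result.set_enrichment.empty:
        result.set_enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    if not skip_screen:
        result.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    mio.write_run_metadata(
        outdir / "run_metadata.json",
        config=config.to_dict(),
        inputs={
            "mrna_counts": str(mrna_counts),
            "mirna_counts": str(mirna_counts),
            "sample_sheet": str(sample_sheet),
            "target_map": str(target_map),
            "gene_sets": str(gene_sets) if gene_sets else None,
        },
        pca_variance_fractions=result.pca["variance_fractions"],
    )
    return result
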