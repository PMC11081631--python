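"""End-to-end study execution: images → color → brightness → clustering →
gene–color correlation → preranked enrichment → cross-lineage intersection.

`run_study` drives a simulated multi-lineage study. Images are streamed
(generate → measure → discard) to keep memory flat; pass ``save_images``
to materialize per-cell multi-page TIFFs. All stage outputs are written
as plain-text tables under ``out_dir``:

    colors_<lineage>.csv           per-cell ΔR/ΔG/ΔB with across-plane SD
    brightness_<lineage>.csv       corrected RGB, Y, Ynorm, clamp flag
    qc_channel_correlation.csv     3×3 inter-channel Pearson per lineage
    counts_<lineage>/              MTX + features/barcodes sidecars
    metadata.csv                   cell_id, lineage, pigment, image_path
    clusters.csv                   pooled SNN-Louvain assignment
    cluster_summary.csv            per-cluster brightness distribution
    correlations_<lineage>.csv     per-gene r, abs_r, rank
    ranking_<lineage>.rnk          preranked input (gene TAB |r|)
    gene_sets.gmt                  the collection that was tested
    gsea_<lineage>.tsv             ES, NES, pval, padj, leading edge
    intersection.tsv               pathways enriched in every lineage
    truth_<lineage>.csv            planted slopes (simulation ground truth)
    run_info.json                  config echo, seed, package version
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .brightness import brightness_table
from .correlation import gene_brightness_correlation, rank_genes, write_rnk
from .enrichment import (
    LineageEnrichmentSummary,
    intersect_lineages,
    partition_by_nes,
    run_gsea,
    write_gmt,
)
from .expression import (
    ClusteringParams,
    CountMatrix,
    cluster_color_summary,
    log_normalize,
    pca,
    scale_genes,
    snn_cluster,
    write_counts,
)
from .image_color import channel_correlation, color_table, measure_cell, write_zstack_tiff
from .simulate import StudyBundle, StudyConfig, generate_study

log = logging.getLogger("pigcorr")

__all__ = ["StudyResult", "run_study", "measure_lineage_colors"]


@dataclass
class StudyResult:
    bundle: StudyBundle
    colors: dict[str, pd.DataFrame]
    brightness: dict[str, pd.DataFrame]
    channel_qc: pd.DataFrame
    clusters: pd.DataFrame
    cluster_summary: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    gsea: dict[str, pd.DataFrame]
    summary: LineageEnrichmentSummary


def measure_lineage_colors(lineage_data, roi=None, image_dir: str | None = None):
    """Stream the lineage's images through the color-measurement stage."""
    records = []
    paths = []
    roi = roi or lineage_data.image_params[0].roi
    for stack in lineage_data.iter_images():
        if image_dir is not None:
            path = os.path.join(image_dir, f"{stack.cell_id}.tiff")
            write_zstack_tiff(stack, path)
            paths.append(path)
        records.append(measure_cell(stack, roi=roi))
    return records, paths


def _detection_filter(counts: CountMatrix, min_cells: int = 3) -> np.ndarray:
    """Genes detected (count > 0) in at least ``min_cells`` cells."""
    return (counts.counts > 0).sum(axis=1) >= min_cells


def run_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    out_dir: str = "pigcorr_run",
    n_perm: int = 1000,
    fdr: float = 0.05,
    min_detected_cells: int = 3,
    clustering: ClusteringParams | None = None,
    save_images: bool = False,
    proxy: str = "luma",
) -> StudyResult:
    """Execute the full simulated study and write all stage outputs."""
    config = config or StudyConfig()
    if not config.with_images:
        config = dataclasses.replace(config, with_images=True)
    clustering = clustering or ClusteringParams()
    os.makedirs(out_dir, exist_ok=True)

    log.info("simulating study: %d lineages x %d cells, %d genes, seed=%d",
             len(config.lineages), config.cells_per_lineage, config.n_genes, seed)
    bundle = generate_study(config, seed=seed)

    image_dir = None
    if save_images:
        image_dir = os.path.join(out_dir, "images")
        os.makedirs(image_dir, exist_ok=True)

    colors, bright, qc_rows = {}, {}, []
    for lineage, ld in bundle.lineages.items():
        log.info("measuring colors: %s", lineage)
        records, paths = measure_lineage_colors(ld, image_dir=image_dir)
        if paths:
            ld.metadata["image_path"] = paths
        ctab = color_table(records)
        colors[lineage] = ctab
        ctab.to_csv(os.path.join(out_dir, f"colors_{_safe(lineage)}.csv"), index=False)

        btab = brightness_table(ctab, proxy=proxy)
        bright[lineage] = btab
        btab.to_csv(
            os.path.join(out_dir, f"brightness_{_safe(lineage)}.csv"), index=False
        )

        cc = channel_correlation(records)
        qc_rows.append(
            {
                "lineage": lineage,
                "r_RG": cc.loc["R", "G"],
                "r_RB": cc.loc["R", "B"],
                "r_GB": cc.loc["G", "B"],
            }
        )
        write_counts(
            ld.counts, os.path.join(out_dir, f"counts_{_safe(lineage)}"), fmt="mtx"
        )
        ld.truth.to_csv(
            os.path.join(out_dir, f"truth_{_safe(lineage)}.csv"), index=False
        )
    channel_qc = pd.DataFrame(qc_rows)
    channel_qc.to_csv(os.path.join(out_dir, "qc_channel_correlation.csv"), index=False)

    pd.concat([ld.metadata for ld in bundle.lineages.values()]).to_csv(
        os.path.join(out_dir, "metadata.csv"), index=False
    )

    # pooled clustering across lineages
    log.info("clustering pooled cells")
    all_genes = bundle.lineages[config.lineages[0]].counts.genes
    pooled = CountMatrix(
        genes=list(all_genes),
        cells=[c for ld in bundle.lineages.values() for c in ld.counts.cells],
        counts=np.hstack([ld.counts.counts for ld in bundle.lineages.values()]),
    )
    scaled_pooled = scale_genes(log_normalize(pooled, config.scale_factor))
    comps = pca(scaled_pooled, n_components=clustering.n_components)
    assignment = snn_cluster(comps.scores, scaled_pooled.cells, clustering, seed=seed)
    assignment.to_frame().to_csv(os.path.join(out_dir, "clusters.csv"), index=False)

    pooled_brightness = pd.concat(bright.values(), ignore_index=True)
    summary_tab = cluster_color_summary(assignment, pooled_brightness)
    summary_tab.to_csv(os.path.join(out_dir, "cluster_summary.csv"), index=False)

    # per-lineage correlation + enrichment
    write_gmt(bundle.gene_sets, os.path.join(out_dir, "gene_sets.gmt"))
    correlations, gsea_tabs, partitions = {}, {}, {}
    for lineage, ld in bundle.lineages.items():
        log.info("correlating and testing enrichment: %s", lineage)
        keep = _detection_filter(ld.counts, min_detected_cells)
        filtered = CountMatrix(
            genes=[g for g, k in zip(ld.counts.genes, keep) if k],
            cells=list(ld.counts.cells),
            counts=ld.counts.counts[keep],
        )
        scaled = scale_genes(log_normalize(filtered, config.scale_factor))
        ynorm = bright[lineage].set_index("cell_id")["Ynorm"]
        corr = gene_brightness_correlation(scaled, ynorm, lineage=lineage)
        ranked = rank_genes(corr)
        corr_out = corr.assign(abs_r=corr["r"].abs()).sort_values(
            ["abs_r", "gene_id"], ascending=[False, True]
        )
        corr_out["rank"] = np.arange(1, len(corr_out) + 1)
        corr_out.to_csv(
            os.path.join(out_dir, f"correlations_{_safe(lineage)}.csv"), index=False
        )
        correlations[lineage] = corr_out
        write_rnk(ranked, os.path.join(out_dir, f"ranking_{_safe(lineage)}.rnk"))

        tab = run_gsea(ranked, bundle.gene_sets, n_perm=n_perm, seed=seed)
        gsea_tabs[lineage] = tab
        out = tab.copy()
        out["leading_edge"] = out["leading_edge"].map(",".join)
        out.to_csv(
            os.path.join(out_dir, f"gsea_{_safe(lineage)}.tsv"), sep="\t", index=False
        )
        partitions[lineage] = partition_by_nes(tab, alpha=fdr)

    if len(partitions) >= 2:
        summary = intersect_lineages(partitions)
    else:  # single-lineage study: the "intersection" is that lineage's lists
        (only,) = partitions.values()
        summary = LineageEnrichmentSummary(
            per_lineage=partitions,
            intersection_positive=sorted(only[0]),
            intersection_negative=sorted(only[1]),
        )
    _write_intersection(summary, os.path.join(out_dir, "intersection.tsv"))

    with open(os.path.join(out_dir, "run_info.json"), "w") as fh:
        json.dump(
            {
                "pigcorr_version": __version__,
                "seed": seed,
                "n_perm": n_perm,
                "fdr": fdr,
                "config": _config_dict(config),
            },
            fh,
            indent=2,
        )
    log.info(
        "done: %d common positive, %d common negative pathways",
        len(summary.intersection_positive),
        len(summary.intersection_negative),
    )
    return StudyResult(
        bundle=bundle,
        colors=colors,
        brightness=bright,
        channel_qc=channel_qc,
        clusters=assignment.to_frame(),
        cluster_summary=summary_tab,
        correlations=correlations,
        gsea=gsea_tabs,
        summary=summary,
    )


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in name)


def _write_intersection(summary: LineageEnrichmentSummary, path: str) -> None:
    rows = []
    for lineage, (pos, neg) in summary.per_lineage.items():
        for s in pos:
            rows.append({"scope": lineage, "direction": "positive", "set_name": s})
        for s in neg:
            rows.append({"scope": lineage, "direction": "negative", "set_name": s})
    for s in summary.intersection_positive:
        rows.append({"scope": "intersection", "direction": "positive", "set_name": s})
    for s in summary.intersection_negative:
        rows.append({"scope": "intersection", "direction": "negative", "set_name": s})
    pd.DataFrame(rows, columns=["scope", "direction", "set_name"]).to_csv(
        path, sep="\t", index=False
    )


def _config_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return clean(d)
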