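"""Dual-level pipeline orchestration.

Level 0 (broad triage): descriptors -> validity -> normalization -> BDF ->
AEC-DBSCAN -> APT-OCSVM with negatives removed.  Level 1 (refinement):
the same chain recomputed on the level-0 survivors — dataset statistics
(normalization scales, block means) are refit on the subset — with the
sigma-emphasizing BDF rule and OCSVM in label-only mode.  Survivors are
then projected per phospho-arm pairing (IPCA axes from the per-arm Tier-2
descriptor blocks), the comparison indicator and conditional sums are
computed over paired replicates, and candidates are similarity-ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from delhit import descriptors as desc
from delhit.classify_ocsvm import (
    APTConfig,
    OCSVM_FEATURES,
    apply_level_policy,
    classify,
    tune_nu,
)
from delhit.io_manifest import CountMatrix, FilterReport, SelectionManifest, read_count_tables, read_manifest, write_results
from delhit.outlier_dbscan import filter_outliers
from delhit.prefilter import BDFRule, apply_bdf, fit_normalizer
from delhit.project_rank import (
    assign_clusters,
    comparison_indicator,
    conditional_sums,
    ipca_axes,
    similarity_rank,
)

__all__ = ["PipelineConfig", "run_level", "run_pipeline", "run_pipeline_from_matrix"]


@dataclass
class PipelineConfig:
    manifest: str | None = None
    out_dir: str | None = None
    seed: int = 0
    levels: tuple[int, ...] = (0, 1)
    # descriptor scope for the filtering stages: the phospho arm's replicates
    # carry the agonist signal; the total arm enters at ranking time
    filter_scope: str = "phospho"  # phospho | total | pooled
    normalize_mode: str = "maxabs"
    bdf_comparison: str = "strictly_above_mean"
    bdf_block_aggregation: str = "all"
    bdf_level1_stability_mode: str = "sigma_above_mean"
    bdf_level1_stability_quantile: float = 0.5
    dbscan_min_pts: int | None = None
    dbscan_knee_method: str = "max_curvature"
    ocsvm: APTConfig = field(default_factory=APTConfig)
    ipca_batch_size: int | None = None
    # log1p-compress the heavy-tailed arm descriptors before scaling so the
    # projection axis tracks the strength continuum instead of being
    # dominated by the bounded replicate-detection counts
    ipca_log_features: bool = True
    score_use_enhancement: bool = True
    score_use_centroid: bool = False

    def __post_init__(self) -> None:
        self.ocsvm.seed = self.seed

    def echo(self) -> dict:
        d = asdict(self)
        d["levels"] = list(self.levels)
        d["ocsvm"]["negative_band"] = list(self.ocsvm.negative_band)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "ocsvm" in raw and isinstance(raw["ocsvm"], dict):
            oc = dict(raw["ocsvm"])
            if "negative_band" in oc:
                oc["negative_band"] = tuple(oc["negative_band"])
            raw["ocsvm"] = APTConfig(**oc)
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)


def run_level(
    matrix: CountMatrix,
    manifest: SelectionManifest,
    config: PipelineConfig,
    level: int,
    report: FilterReport,
):
    """Execute one level's stage chain; returns (survivor index, result dict).

    ``matrix`` must already be restricted to the level's input compounds
    (for level 1: the level-0 survivors).
    """
    if level not in (0, 1):
        raise ValueError("level must be 0 or 1")
    info: dict = {"level": level}
    if config.filter_scope == "pooled":
        scope = desc.pooled_scope(manifest)
    else:
        arm = "phospho" if config.filter_scope == "phospho" else "total"
        scope = desc.arm_scope(manifest, arm)
    table = desc.compute_descriptors(matrix, scope)
    n_in = len(table)

    valid, removed = desc.apply_validity_filter(table)
    report.add_stage("validity", level, n_in, removed)

    model = fit_normalizer(valid, mode=config.normalize_mode)
    norm = model.transform(valid)

    rule = BDFRule(
        level=level,
        comparison=config.bdf_comparison,
        block_aggregation=config.bdf_block_aggregation,
        level1_stability_mode=config.bdf_level1_stability_mode,
        level1_stability_quantile=config.bdf_level1_stability_quantile,
    )
    kept, removed = apply_bdf(norm, rule)
    report.add_stage("bdf", level, len(norm), removed)

    kept, removed, layer_results = filter_outliers(
        kept, min_pts=config.dbscan_min_pts, knee_method=config.dbscan_knee_method
    )
    report.add_stage("dbscan", level, len(kept) + len(removed), removed)
    info["dbscan_eps"] = {name: res.eps for name, res in layer_results.items()}

    feats = kept[OCSVM_FEATURES]
    nu, diagnostics = tune_nu(feats, config.ocsvm)
    result = classify(feats, nu, config.ocsvm, diagnostics)
    survivors, removed = apply_level_policy(result, level)
    report.add_stage("ocsvm", level, len(kept), removed)
    info["nu"] = result.nu
    info["negative_fraction"] = result.negative_fraction
    info["nu_in_band"] = result.in_band
    info["labels"] = result.labels
    info["classification"] = result
    return survivors, info


def _arm_feature_block(matrix: CountMatrix, manifest: SelectionManifest, arm: str,
                       arm_label: str | None, mode: str, log_features: bool = True) -> pd.DataFrame:
    scope = desc.arm_scope(manifest, arm, arm_label)
    table = desc.compute_descriptors(matrix, scope)
    block = table[desc.TIER2_COLUMNS].fillna(0.0)
    if log_features:
        # log then z-score: a depth rescaling of any file shifts the log
        # columns by constants, which centering removes exactly
        block = np.log(block.astype(float).clip(lower=1e-12))
        model = fit_normalizer(block, mode="zscore", columns=desc.TIER2_COLUMNS)
    else:
        model = fit_normalizer(block, mode=mode, columns=desc.TIER2_COLUMNS)
    return model.transform(block)


def _rank_pairing(matrix: CountMatrix, manifest: SelectionManifest, config: PipelineConfig,
                  phospho_label: str) -> pd.DataFrame:
    total_block = _arm_feature_block(matrix, manifest, "total", None, config.normalize_mode,
                                     config.ipca_log_features)
    phospho_block = _arm_feature_block(matrix, manifest, "phospho", phospho_label,
                                       config.normalize_mode, config.ipca_log_features)
    xy = ipca_axes(total_block, phospho_block, batch_size=config.ipca_batch_size)
    sides = assign_clusters(xy)

    pairs = manifest.paired_replicates(phospho_label)
    rich = desc.richness_table(matrix)
    rich_p = rich[[p.key for p, _ in pairs]]
    rich_t = rich[[t.key for _, t in pairs]]
    ind = comparison_indicator(rich_p, rich_t)
    if matrix.counts is not None:
        cnt_p = matrix.counts.loc[rich.index, [p.key for p, _ in pairs]]
        cnt_t = matrix.counts.loc[rich.index, [t.key for _, t in pairs]]
    else:
        cnt_p = cnt_t = None
    cond = conditional_sums(rich_p, rich_t, ind, cnt_p, cnt_t)
    hits = similarity_rank(
        xy, sides, ind, cond,
        use_enhancement=config.score_use_enhancement,
        use_centroid=config.score_use_centroid,
    )
    hits.insert(0, "arm_label", phospho_label)
    # keep the full projection for overlap flagging
    hits.attrs["positive_side"] = set(map(str, sides.index[sides == "positive"]))
    return hits


def run_pipeline_from_matrix(
    matrix: CountMatrix, manifest: SelectionManifest, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    """Full dual-level run on an in-memory CountMatrix.

    Returns (hit table, run report dict).  The hit table has one row per
    (candidate, phospho pairing); ``overlap_flag`` marks compounds on the
    positive side in every phospho pairing.
    """
    report = FilterReport()
    run_info: dict = {"config": config.echo(), "levels": {}, "warnings": []}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        current = matrix
        survivors = current.compounds
        level1_info = None
        for level in config.levels:
            survivors, info = run_level(current, manifest, config, level, report)
            run_info["levels"][str(level)] = {
                k: v for k, v in info.items() if k not in ("labels", "classification")
            }
            if level == 1:
                level1_info = info
            current = current.subset(survivors)

        hits_frames = []
        positive_sets = []
        if len(survivors) >= 2:
            for label in manifest.phospho_labels:
                h = _rank_pairing(current, manifest, config, label)
                positive_sets.append(h.attrs.get("positive_side", set()))
                hits_frames.append(h)
        else:
            warnings.warn("fewer than 2 survivors: skipping projection and ranking")
        run_info["warnings"] = [str(w.message) for w in caught]

    if hits_frames:
        overlap = set.intersection(*positive_sets) if positive_sets else set()
        hits = pd.concat(hits_frames)
        hits["overlap_flag"] = [str(c) in overlap for c in hits.index]
        hits = hits.reset_index().rename(columns={"index": "compound", "compound": "compound"})
    else:
        hits = pd.DataFrame(columns=["compound", "arm_label", "x", "y", "cluster_side",
                                     "indicator", "score", "rank", "overlap_flag"])
    run_info["report"] = report.to_dict()
    run_info["n_hits"] = int(len(hits))
    if level1_info is not None:
        run_info["level1_classification"] = level1_info.get("classification")

    if config.out_dir is not None:
        write_results(hits, report, config.out_dir)
        import json
        clean = {k: v for k, v in run_info.items() if k != "level1_classification"}
        with open(Path(config.out_dir) / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(clean, fh, indent=2, sort_keys=True, default=str)
    return hits, run_info


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Read the manifest, load count tables, and run the dual-level workflow."""
    if config.manifest is None:
        raise ValueError("config.manifest is required")
    manifest = read_manifest(config.manifest)
    matrix = read_count_tables(manifest)
    return run_pipeline_from_matrix(matrix, manifest, config)
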