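"""Normalization to [-1, 1] and Block of Descriptors Filtering (BDF).

Normalization is max-absolute scaling per descriptor: it preserves sign and
zero and bounds the transformed data to [-1, 1], matching the requirement
that every feature contribute comparably to downstream distance-based
methods (DBSCAN, OCSVM, IPCA).  A z-score mode is available for sensitivity
analysis but does not bound the range.

BDF groups the six Tier-2/Tier-3 filtering criteria into blocks —
effectiveness {SR, SC}, reproducibility {SnR, SnC}, balance {kappaR,
kappaC} — and keeps a compound only if, in every block, all member
descriptors strictly exceed the dataset mean of that descriptor
("outperform the average").  The level-1 rule additionally emphasizes
stability by introducing a fourth block {sigmaR, sigmaC} under the same
above-average comparison: among already-elite survivors, above-average
standard deviation tracks sustained high signal across replicates, whereas
a relative-spread (CV) cut would penalize compounds whose phospho/total
arm contrast — the very signature of an agonist — inflates their pooled
spread.  The CV-at-most-median alternative is available via
``level1_stability_mode="cv_below_median"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NormalizationModel", "BDFRule", "fit_normalizer", "apply_bdf"]

DEFAULT_BLOCKS = {
    "effectiveness": ["SR", "SC"],
    "reproducibility": ["SnR", "SnC"],
    "balance": ["kappaR", "kappaC"],
}


@dataclass
class NormalizationModel:
    """Per-descriptor max-abs (or z-score) scaling fitted on one dataset."""

    mode: str = "maxabs"  # maxabs | zscore
    scales: pd.Series | None = None
    centers: pd.Series | None = None
    fitted: bool = False

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("normalizer not fitted")
        cols = self.scales.index
        out = table.copy()
        if self.mode == "zscore":
            out[cols] = (table[cols] - self.centers) / self.scales
        else:
            out[cols] = table[cols] / self.scales
        return out


@dataclass
class BDFRule:
    """Block filtering rule at a given level."""

    level: int = 0
    blocks: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_BLOCKS))
    comparison: str = "strictly_above_mean"  # or strictly_above_median
    block_aggregation: str = "all"  # all | any
    level1_stability_mode: str = "sigma_above_mean"  # or cv_below_median
    level1_stability_quantile: float = 0.5

    def __post_init__(self) -> None:
        if self.level not in (0, 1):
            raise ValueError("level must be 0 or 1")
        if self.block_aggregation not in ("all", "any"):
            raise ValueError("block_aggregation must be 'all' or 'any'")
        if self.level1_stability_mode not in ("sigma_above_mean", "cv_below_median"):
            raise ValueError("unknown level1_stability_mode")


def fit_normalizer(table: pd.DataFrame, mode: str = "maxabs", columns: list[str] | None = None) -> NormalizationModel:
    """Fit per-descriptor scales on numeric descriptor columns.

    Constant-zero descriptors get scale 1 (identity transform, no division
    error).  NaN or infinite input raises, naming the first offending cell.
    """
    if columns is None:
        columns = [c for c in table.columns if c != "valid_tier3" and pd.api.types.is_numeric_dtype(table[c])]
    sub = table[columns]
    bad = ~np.isfinite(sub.to_numpy(dtype=float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite descriptor value: compound {sub.index[i]!r}, descriptor {columns[j]!r}"
        )
    if mode == "zscore":
        centers = sub.mean(axis=0)
        scales = sub.std(axis=0, ddof=0)
        scales[scales == 0] = 1.0
        return NormalizationModel(mode=mode, scales=scales, centers=centers, fitted=True)
    scales = sub.abs().max(axis=0)
    scales[scales == 0] = 1.0
    return NormalizationModel(mode="maxabs", scales=scales, centers=None, fitted=True)


def apply_bdf(
    table: pd.DataFrame, rule: BDFRule
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Keep compounds that beat the dataset average in every descriptor block.

    ``table`` must already be normalized with the model fitted on the same
    rows (under max-abs scaling the pass/fail decision is identical on raw
    values, since the scaling is a positive linear map).

    Returns (kept rows, removal log).  Removal reasons name the first
    failing block.  Level 1 appends the CV-at-most-median stability cut.
    """
    if len(table) == 0:
        warnings.warn("BDF applied to empty table", stacklevel=2)
        return table, []
    crit = pd.DataFrame(index=table.index)
    fail_reason = pd.Series("", index=table.index, dtype=object)
    keep = np.ones(len(table), dtype=bool)
    block_pass: dict[str, np.ndarray] = {}
    for bname, cols in rule.blocks.items():
        vals = table[cols].to_numpy(dtype=float)
        if rule.comparison == "strictly_above_median":
            ref = np.median(vals, axis=0)
        else:
            ref = vals.mean(axis=0)
        above = vals > ref
        agg = above.all(axis=1) if rule.block_aggregation == "all" else above.any(axis=1)
        block_pass[bname] = agg
    passed = np.ones(len(table), dtype=bool)
    for bname, agg in block_pass.items():
        newly_failed = passed & ~agg & (fail_reason == "")
        fail_reason[newly_failed] = f"bdf_block:{bname}"
        passed &= agg
    keep = passed

    if rule.level == 1:
        if rule.level1_stability_mode == "cv_below_median":
            with np.errstate(divide="ignore"):
                cv_r = 1.0 / table["kappaR"].to_numpy(dtype=float)
                cv_c = 1.0 / table["kappaC"].to_numpy(dtype=float)
            q = rule.level1_stability_quantile
            stab = (cv_r <= np.quantile(cv_r, q)) & (cv_c <= np.quantile(cv_c, q))
        else:
            sig = table[["sigmaR", "sigmaC"]].to_numpy(dtype=float)
            if rule.comparison == "strictly_above_median":
                ref = np.median(sig, axis=0)
            else:
                ref = sig.mean(axis=0)
            above = sig > ref
            stab = above.all(axis=1) if rule.block_aggregation == "all" else above.any(axis=1)
        newly_failed = keep & ~stab
        fail_reason[newly_failed] = "bdf_block:stability"
        keep &= stab

    removed = [(str(c), fail_reason[c]) for c in table.index[~keep]]
    if not keep.any():
        warnings.warn("BDF removed every compound (degenerate dataset)", stacklevel=2)
    return table.loc[keep], removed
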