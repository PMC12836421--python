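"""Selection Performance Descriptors.

Per compound, over a *scope* of replicate selection files:

==========  ====================================================================
Tier 0      C_i   abundance count in replicate i (raw barcode count)
Tier 1      R_i   richness in replicate i = (post-selection %) / (pre-selection %)
Tier 2      SR, SC      sums of richness / counts over the scope
            SnR, SnC    reproducibility: number of replicates with non-zero value
            sigmaR, sigmaC  standard deviation over the scope (sample, ddof=1)
Tier 3      phi_eff   mean over replicates (with C_i > 0) of R_i / C_i
            kappaR    mean(R) / sigmaR   (richness stability)
            kappaC    mean(C) / sigmaC   (count stability)
            phi_bal   |log2(kappaR / kappaC)|   (richness/count balance)
==========  ====================================================================

Tier-3 descriptors are only *valid* for compounds with non-zero SR, SC,
sigmaR and sigmaC; invalid compounds carry NaN in the Tier-3 columns and are
dropped by :func:`apply_validity_filter` before any Tier-3-dependent stage.

Compounds absent from the pre-selection reference have undefined richness
(no frequency to divide by); their richness is NaN and they fail validity.
No pseudocounts are applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from delhit.io_manifest import CountMatrix, SelectionManifest

__all__ = [
    "DescriptorScope",
    "DESCRIPTOR_COLUMNS",
    "TIER2_COLUMNS",
    "compute_richness",
    "compute_descriptors",
    "apply_validity_filter",
]

TIER2_COLUMNS = ["SR", "SC", "SnR", "SnC", "sigmaR", "sigmaC"]
TIER3_COLUMNS = ["phi_eff", "kappaR", "kappaC", "phi_bal"]
DESCRIPTOR_COLUMNS = TIER2_COLUMNS + TIER3_COLUMNS + ["valid_tier3"]


@dataclass
class DescriptorScope:
    """A named subset of manifest files over which descriptors are aggregated."""

    name: str
    members: list[str]  # manifest entry keys (column names)
    intent: str = "pooled"  # pooled | phospho_arm | total_arm

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"scope {self.name!r} needs >= 2 member files (sigma undefined)")


def pooled_scope(manifest: SelectionManifest) -> DescriptorScope:
    return DescriptorScope("pooled", [e.key for e in manifest.files], "pooled")


def arm_scope(manifest: SelectionManifest, arm: str, arm_label: str | None = None) -> DescriptorScope:
    members = [e.key for e in manifest.arm_files(arm, arm_label)]
    name = arm if arm_label is None else f"{arm}:{arm_label}"
    return DescriptorScope(name, members, f"{arm}_arm")


def compute_richness(
    post_counts: pd.DataFrame,
    pre_counts: pd.Series,
    file_totals: pd.Series | None = None,
    pre_total: float | None = None,
) -> pd.DataFrame:
    """Richness per compound per file: (C_f / total_f) / (C_pre / total_pre).

    ``file_totals`` / ``pre_total`` override the column sums — required when
    ``post_counts`` is a subset of the full selection files, so frequencies
    still refer to the complete sequencing output.  Compounds with zero
    pre-selection count get NaN richness (undefined); they are excluded
    from richness-based descriptors downstream.
    """
    totals = post_counts.sum(axis=0) if file_totals is None else file_totals[post_counts.columns]
    if (totals <= 0).any():
        empty = totals.index[totals <= 0][0]
        raise ValueError(f"empty selection file: {empty!r} has zero total count")
    if pre_total is None:
        pre_total = float(pre_counts.sum())
    if pre_total <= 0:
        raise ValueError("pre-selection reference has zero total count")
    pre_freq = pre_counts.astype(float) / pre_total
    post_freq = post_counts.astype(float).div(totals, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rich = post_freq.div(pre_freq, axis=0)
    rich[pre_freq == 0] = np.nan
    return rich


def richness_table(matrix: CountMatrix) -> pd.DataFrame:
    """Richness for every manifest file, using precomputed values where given."""
    man = matrix.manifest
    derived = None
    need_derive = [e for e in man.files if e.value_kind == "count"]
    if need_derive:
        if matrix.pre_counts is None:
            raise ValueError("count-valued files present but no pre-selection reference")
        derived = compute_richness(
            matrix.counts[[e.key for e in man.files if e.value_kind != "richness"]],
            matrix.pre_counts,
            file_totals=matrix.file_totals,
            pre_total=matrix.pre_total,
        )
    cols = {}
    for e in man.files:
        if e.value_kind in ("richness", "both"):
            cols[e.key] = matrix.richness[e.key]
        else:
            cols[e.key] = derived[e.key]
    return pd.DataFrame(cols)


def compute_descriptors(matrix: CountMatrix, scope: DescriptorScope) -> pd.DataFrame:
    """Tier 2 + Tier 3 Selection Performance Descriptors over one scope.

    Returns one row per compound with columns ``DESCRIPTOR_COLUMNS``.
    NaN richness (compound absent from pre-selection) propagates to SR and
    sigmaR, so such compounds fail the Tier-3 validity rule.
    """
    rich = richness_table(matrix)[scope.members]
    if matrix.counts is not None:
        cnt = matrix.counts[scope.members]
    else:
        # richness-only datasets: counts unavailable; reuse richness so the
        # count-side descriptors mirror the richness side.
        cnt = rich
    R = rich.to_numpy(dtype=float)
    C = cnt.to_numpy(dtype=float)
    n = R.shape[1]

    out = pd.DataFrame(index=rich.index)
    out["SR"] = R.sum(axis=1)
    out["SC"] = C.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out["SnR"] = (R > 0).sum(axis=1)
    out["SnC"] = (C > 0).sum(axis=1)
    out["sigmaR"] = R.std(axis=1, ddof=1)
    out["sigmaC"] = C.std(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        ratio = np.where(C > 0, R / np.where(C > 0, C, 1.0), np.nan)
        phi_eff = np.nanmean(ratio, axis=1)
        kappaR = (R.mean(axis=1)) / out["sigmaR"].to_numpy()
        kappaC = (C.mean(axis=1)) / out["sigmaC"].to_numpy()
        phi_bal = np.abs(np.log2(kappaR / kappaC))

    valid = (
        (out["SR"].to_numpy() > 0)
        & (out["SC"].to_numpy() > 0)
        & (out["sigmaR"].to_numpy() > 0)
        & (out["sigmaC"].to_numpy() > 0)
    )
    out["phi_eff"] = np.where(valid, phi_eff, np.nan)
    out["kappaR"] = np.where(valid, kappaR, np.nan)
    out["kappaC"] = np.where(valid, kappaC, np.nan)
    out["phi_bal"] = np.where(valid, phi_bal, np.nan)
    out["valid_tier3"] = valid
    out.attrs["scope"] = scope.name
    out.attrs["n_members"] = n
    return out


def apply_validity_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Split a descriptor table into Tier-3-valid rows and a removal log.

    Validity requires non-zero sum of richness, sum of counts, and both
    standard deviations; nothing else (a compound seen in a single replicate
    is retained here as long as those four quantities are non-zero).
    """
    valid_mask = table["valid_tier3"].to_numpy(dtype=bool)
    removed = [
        (str(c), "invalid_tier3: zero SR, SC, sigmaR or sigmaC (or undefined richness)")
        for c in table.index[~valid_mask]
    ]
    return table.loc[valid_mask], removed
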