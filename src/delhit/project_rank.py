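"""IPCA projection, comparison indicator, conditional summation, and ranking.

Surviving candidates are projected onto a phospho/total plane: the first
incremental-PCA component of the six Tier-2 descriptors computed on the
total-arm replicates gives the x coordinate, the phospho-arm component the
y coordinate (each sign-oriented so it correlates non-negatively with that
arm's sum of richness).  Compounds right of the central axis (x > 0 after
the mean-zero projection) form the positive cluster.

Agonist bias is injected through two replicate-level metrics:

* **comparison indicator** I = sum over paired replicates of
  sign(R_phospho - R_total); the dominant side is the arm preferred in
  strictly more than half the pairs.
* **conditional summation**: richness/count sums restricted to the dominant
  replicate set, so one aberrant replicate cannot swamp the contrast.

The similarity score of a candidate (positive side, phospho-dominant) is
1 / (1 + d) where d is the Euclidean distance to the global ideal vertex —
the component-wise maximum of the candidate cloud in the scaled feature
space (x, y, I, log1p richness-contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import IncrementalPCA

__all__ = [
    "ipca_axes",
    "assign_clusters",
    "comparison_indicator",
    "conditional_sums",
    "similarity_rank",
]


def _fit_axis(X: np.ndarray, sr: np.ndarray, batch_size: int | None) -> np.ndarray:
    """First incremental principal component score, sign-fixed against SR."""
    if X.shape[0] < 2:
        raise ValueError("need >= 2 compounds for IPCA")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("no signal in arm: zero-variance feature block")
    n, d = X.shape
    if batch_size is None:
        batch_size = max(5 * d, min(n, 5000))
    batch_size = max(batch_size, d)
    ipca = IncrementalPCA(n_components=1, batch_size=batch_size)
    scores = ipca.fit_transform(X)[:, 0]
    # orient: correlation with the arm's sum of richness must be >= 0
    if np.std(sr) > 0 and np.corrcoef(scores, sr)[0, 1] < 0:
        scores = -scores
    return scores


def ipca_axes(
    total_block: pd.DataFrame,
    phospho_block: pd.DataFrame,
    batch_size: int | None = None,
) -> pd.DataFrame:
    """Per-compound (x, y) scores from per-arm descriptor blocks.

    ``total_block`` / ``phospho_block``: normalized Tier-2 descriptor tables
    computed on the respective arm's replicates, same compound index.  Both
    must contain an ``SR`` column for sign orientation.
    """
    if not total_block.index.equals(phospho_block.index):
        raise ValueError("arm blocks must share the same compound index")
    x = _fit_axis(total_block.to_numpy(dtype=float), total_block["SR"].to_numpy(dtype=float), batch_size)
    y = _fit_axis(phospho_block.to_numpy(dtype=float), phospho_block["SR"].to_numpy(dtype=float), batch_size)
    return pd.DataFrame({"x": x, "y": y}, index=total_block.index)


def assign_clusters(xy: pd.DataFrame) -> pd.Series:
    """positive <=> strictly right of the central axis (x > 0); x = 0 -> negative."""
    return pd.Series(np.where(xy["x"].to_numpy(dtype=float) > 0, "positive", "negative"), index=xy.index)


def comparison_indicator(
    rich_phospho: pd.DataFrame, rich_total: pd.DataFrame
) -> pd.DataFrame:
    """Signed replicate-preference tally between the paired arms.

    Inputs are richness tables with one column per paired replicate, in the
    same replicate order and with identical compound indexes.  Returns per
    compound: ``indicator`` (I), ``dominant_side`` in {phospho, total, tie},
    and a boolean mask of dominant replicates in ``dominant_mask``
    (object column of numpy arrays).
    """
    if rich_phospho.shape != rich_total.shape:
        raise ValueError("paired richness tables must have identical shape")
    if rich_phospho.shape[1] == 0:
        raise ValueError("no paired replicates")
    P = rich_phospho.to_numpy(dtype=float)
    T = rich_total.to_numpy(dtype=float)
    n = P.shape[1]
    pref_p = P > T
    pref_t = T > P
    I = pref_p.sum(axis=1) - pref_t.sum(axis=1)
    side = np.where(pref_p.sum(axis=1) * 2 > n, "phospho", np.where(pref_t.sum(axis=1) * 2 > n, "total", "tie"))
    masks = []
    for i in range(P.shape[0]):
        if side[i] == "phospho":
            masks.append(pref_p[i])
        elif side[i] == "total":
            masks.append(pref_t[i])
        else:
            masks.append(np.ones(n, dtype=bool))  # tie: fall back to all replicates
    out = pd.DataFrame(index=rich_phospho.index)
    out["indicator"] = I.astype(int)
    out["dominant_side"] = side
    out["dominant_mask"] = masks
    return out


def conditional_sums(
    rich_phospho: pd.DataFrame,
    rich_total: pd.DataFrame,
    indicator: pd.DataFrame,
    counts_phospho: pd.DataFrame | None = None,
    counts_total: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Richness/count sums restricted to each compound's dominant replicate set.

    Ties keep the full sums and set ``tie_flag``.  Conditional sums never
    exceed the full-arm sums for non-negative inputs.
    """
    M = np.stack(indicator["dominant_mask"].to_numpy())
    out = pd.DataFrame(index=rich_phospho.index)
    P = rich_phospho.to_numpy(dtype=float)
    T = rich_total.to_numpy(dtype=float)
    out["SR_cond_phospho"] = (P * M).sum(axis=1)
    out["SR_cond_total"] = (T * M).sum(axis=1)
    if counts_phospho is not None and counts_total is not None:
        out["SC_cond_phospho"] = (counts_phospho.to_numpy(dtype=float) * M).sum(axis=1)
        out["SC_cond_total"] = (counts_total.to_numpy(dtype=float) * M).sum(axis=1)
    out["tie_flag"] = (indicator["dominant_side"] == "tie").to_numpy()
    return out


def _maxabs(v: np.ndarray) -> np.ndarray:
    s = np.abs(v).max()
    return v / s if s > 0 else v


def similarity_rank(
    xy: pd.DataFrame,
    cluster_side: pd.Series,
    indicator: pd.DataFrame,
    cond: pd.DataFrame,
    use_enhancement: bool = True,
    use_centroid: bool = False,
) -> pd.DataFrame:
    """Score and rank candidates by proximity to the global ideal vertex.

    Candidate pool: positive-cluster compounds whose dominant side is
    phospho (the pool is all positives when ``use_enhancement`` is False —
    the ablation of the indicator/conditional-sum metrics).  Feature point
    per candidate: (x, y) plus, with enhancement, the normalized indicator
    and the log1p conditional richness contrast; all max-abs scaled over
    the pool.  Score = 1 / (1 + Euclidean distance to the component-wise
    maximum of the pool).  Rank 1 = best; ties broken by larger y, then by
    lexicographic compound code.
    """
    pool = cluster_side == "positive"
    if use_enhancement:
        pool &= (indicator["dominant_side"] == "phospho").reindex(xy.index, fill_value=False)
    idx = xy.index[pool]
    if len(idx) == 0:
        warnings.warn("empty candidate pool: no positive-cluster phospho-dominant compounds", stacklevel=2)
        return pd.DataFrame(
            columns=["x", "y", "cluster_side", "indicator", "SR_cond_phospho",
                     "SR_cond_total", "centroid_distance", "score", "rank"]
        )

    feats = [
        _maxabs(xy.loc[idx, "x"].to_numpy(dtype=float)),
        _maxabs(xy.loc[idx, "y"].to_numpy(dtype=float)),
    ]
    if use_enhancement:
        feats.append(_maxabs(indicator.loc[idx, "indicator"].to_numpy(dtype=float)))
        contrast = np.log1p(cond.loc[idx, "SR_cond_phospho"].to_numpy(dtype=float)) - np.log1p(
            cond.loc[idx, "SR_cond_total"].to_numpy(dtype=float)
        )
        feats.append(_maxabs(contrast))
    F = np.column_stack(feats)
    vertex = F.max(axis=0)
    d_vertex = np.sqrt(((F - vertex) ** 2).sum(axis=1))
    centroid = F.mean(axis=0)
    d_centroid = np.sqrt(((F - centroid) ** 2).sum(axis=1))
    dist = 0.5 * (d_vertex + d_centroid) if use_centroid else d_vertex
    score = 1.0 / (1.0 + dist)

    out = pd.DataFrame(index=idx)
    out["x"] = xy.loc[idx, "x"]
    out["y"] = xy.loc[idx, "y"]
    out["cluster_side"] = "positive"
    out["indicator"] = indicator["indicator"].reindex(idx)
    for col in ("SR_cond_phospho", "SR_cond_total", "SC_cond_phospho", "SC_cond_total"):
        if col in cond.columns:
            out[col] = cond[col].reindex(idx)
    out["centroid_distance"] = d_centroid
    out["score"] = score

    code_key = [tuple(int(t) for t in str(c).split("-")) for c in idx]
    order = sorted(
        range(len(idx)),
        key=lambda i: (-score[i], -out["y"].iloc[i], code_key[i]),
    )
    rank = np.empty(len(idx), dtype=int)
    rank[order] = np.arange(1, len(idx) + 1)
    out["rank"] = rank
    return out.sort_values("rank")
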