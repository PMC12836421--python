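"""Density-based outlier exclusion with automatic eps calibration (AEC).

The DBSCAN eps radius is chosen from the data: sort the k-nearest-neighbor
distances (k = min_pts) ascending and take the value at the knee of the
curve, where the knee is the index maximizing the discrete curvature
(second difference).  This makes the filter self-adaptive — re-fed with new
data, the radius is recomputed, and rescaling all features by a common
constant rescales eps proportionally, leaving the noise set unchanged.

Outlier filtering runs as three independent layers over the Tier-3
descriptors of the block-filter survivors: the efficiency descriptor
phi_eff (1-D), the balance descriptor phi_bal (1-D), and the stability
array [kappaR, kappaC] (2-D), each max-abs normalized per layer.  The
removed set is the union of the per-layer DBSCAN noise points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

__all__ = ["AECParams", "LayerResult", "auto_eps", "dbscan_layer", "filter_outliers", "default_min_pts"]

DEFAULT_LAYERS = {
    "phi_eff": ["phi_eff"],
    "phi_bal": ["phi_bal"],
    "kappa_array": ["kappaR", "kappaC"],
}


def default_min_pts(n: int) -> int:
    """max(4, ceil(ln n)) — common heuristic; capped at n - 1."""
    return max(2, min(max(4, math.ceil(math.log(max(n, 2)))), n - 1))


@dataclass
class AECParams:
    min_pts: int
    eps: float | None = None
    layer: str = ""
    knee_method: str = "max_curvature"

    def __post_init__(self) -> None:
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")


@dataclass
class LayerResult:
    layer: str
    eps: float
    labels: pd.Series  # -1 = noise, >= 0 = cluster id

    @property
    def noise(self) -> pd.Index:
        return self.labels.index[self.labels == -1]


def auto_eps(points: np.ndarray, min_pts: int, knee_method: str = "max_curvature") -> float:
    """eps = k-distance at the knee of the sorted k-distance curve.

    k = min_pts (neighbor count includes the point itself, matching the
    DBSCAN core-point rule).  A constant curve has no knee; eps is then the
    constant plus 10% relative slack.  All-coincident points give eps of a
    vanishing positive value, under which every point is core and nothing
    is noise.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n <= min_pts:
        raise ValueError(f"need n > min_pts points for AEC, got n={n}, min_pts={min_pts}")
    nn = NearestNeighbors(n_neighbors=min_pts).fit(points)
    dist, _ = nn.kneighbors(points)
    kdist = np.sort(dist[:, -1])
    if kdist[-1] - kdist[0] <= 1e-12 * max(kdist[-1], 1.0):
        return float(kdist[-1] * 1.1) if kdist[-1] > 0 else 1e-12
    if knee_method == "kneedle":
        # normalized distance from the chord joining curve endpoints
        x = np.linspace(0.0, 1.0, n)
        y = (kdist - kdist[0]) / (kdist[-1] - kdist[0])
        knee = int(np.argmax(y - x))
    else:
        second = np.diff(kdist, 2)
        knee = int(np.argmax(second)) + 1
    return float(kdist[knee]) if kdist[knee] > 0 else 1e-12


def dbscan_layer(points: np.ndarray, params: AECParams, index: pd.Index | None = None) -> LayerResult:
    """Standard density-reachability clustering at the AEC-calibrated eps.

    A point is core iff it has >= min_pts neighbors within eps, counting
    itself; noise points are those not density-reachable from any core.
    Labels are deterministic given a fixed input order.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    eps = params.eps
    if eps is None:
        eps = auto_eps(points, params.min_pts, params.knee_method)
    labels = DBSCAN(eps=eps, min_samples=params.min_pts).fit_predict(points)
    if index is None:
        index = pd.RangeIndex(len(points))
    return LayerResult(layer=params.layer, eps=float(eps), labels=pd.Series(labels, index=index))


def filter_outliers(
    table: pd.DataFrame,
    min_pts: int | None = None,
    layers: dict[str, list[str]] | None = None,
    knee_method: str = "max_curvature",
) -> tuple[pd.DataFrame, list[tuple[str, str]], dict[str, LayerResult]]:
    """Remove the union of per-layer DBSCAN noise points.

    ``table`` holds Tier-3-valid descriptors (one row per surviving
    compound).  Each layer's features are max-abs normalized independently
    before clustering.  Returns (kept rows, removal log with layer
    attribution, per-layer results).
    """
    layers = dict(DEFAULT_LAYERS) if layers is None else layers
    n = len(table)
    if min_pts is None:
        min_pts = default_min_pts(n)
    if n <= min_pts:
        warnings.warn(
            f"too few compounds (n={n}) for DBSCAN with min_pts={min_pts}; skipping outlier filter",
            stacklevel=2,
        )
        return table, [], {}

    flagged: dict[str, list[str]] = {}
    results: dict[str, LayerResult] = {}
    for lname, cols in layers.items():
        pts = table[cols].to_numpy(dtype=float)
        scale = np.abs(pts).max(axis=0)
        scale[scale == 0] = 1.0
        res = dbscan_layer(pts / scale, AECParams(min_pts=min_pts, layer=lname, knee_method=knee_method), index=table.index)
        results[lname] = res
        for c in res.noise:
            flagged.setdefault(str(c), []).append(lname)

    removed = [(c, "dbscan_layer:" + "+".join(ls)) for c, ls in flagged.items()]
    keep_mask = ~table.index.astype(str).isin(flagged.keys())
    return table.loc[keep_mask], removed, results
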