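"""APT-OCSVM: one-class SVM with automated nu selection.

A one-class SVM with RBF kernel is fitted in-sample on the six normalized
Tier-2 descriptors {SR, SC, SnR, SnC, sigmaR, sigmaC}; compounds on the
negative side of the learned boundary are the presumed background.  The nu
parameter (an upper bound on the training outlier fraction) is tuned
automatically: a 2-means clustering of the same features provides an
unsupervised reference partition (minority cluster = reference-negative),
and among grid values of nu whose resulting negative fraction falls inside
the target band (default 10–20%), the one whose labels best agree with the
reference partition wins.  If no grid point lands in the band, the nu whose
negative fraction is closest to the band midpoint is used with a warning.

At level 0 the negative class is filtered out; at level 1 the classifier
only labels (the positive label marks the most-promising subset) and
nothing is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.svm import OneClassSVM

__all__ = ["APTConfig", "ClassificationResult", "tune_nu", "classify", "apply_level_policy"]

OCSVM_FEATURES = ["SR", "SC", "SnR", "SnC", "sigmaR", "sigmaC"]


def _default_grid() -> list[float]:
    return [round(0.02 * k, 2) for k in range(1, 16)]  # 0.02 .. 0.30


@dataclass
class APTConfig:
    nu_grid: list[float] = field(default_factory=_default_grid)
    gamma_rule: str = "scale"
    negative_band: tuple[float, float] = (0.10, 0.20)
    kmeans_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.negative_band
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("negative_band must satisfy 0 < lo < hi < 1")
        if any(not (0.0 < nu < 1.0) for nu in self.nu_grid):
            raise ValueError("nu grid values must lie in (0, 1)")


@dataclass
class ClassificationResult:
    labels: pd.Series          # "positive" / "negative"
    decision: pd.Series        # signed distance to hyperplane; positive <=> decision >= 0
    nu: float
    negative_fraction: float
    agreement: dict[float, float]   # per attempted grid point (band members only)
    in_band: bool
    model: OneClassSVM | None = None
    features: pd.DataFrame | None = None  # the table the model was fit on

    @property
    def positives(self) -> pd.Index:
        return self.labels.index[self.labels == "positive"]

    @property
    def negatives(self) -> pd.Index:
        return self.labels.index[self.labels == "negative"]


def _fit_ocsvm(X: np.ndarray, nu: float, gamma_rule: str) -> tuple[OneClassSVM, np.ndarray]:
    model = OneClassSVM(kernel="rbf", gamma=gamma_rule, nu=nu)
    model.fit(X)
    dec = model.decision_function(X)
    return model, dec


def tune_nu(features: pd.DataFrame, config: APTConfig | None = None) -> tuple[float, dict]:
    """Pick nu by agreement between OCSVM labels and a 2-means reference partition.

    Agreement for one grid point = fraction of points identically
    partitioned, maximized over the two possible label alignments.  Ties go
    to the smaller nu.  Returns (nu*, diagnostics).
    """
    config = config or APTConfig()
    X = features[OCSVM_FEATURES].to_numpy(dtype=float) if set(OCSVM_FEATURES) <= set(features.columns) else features.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 20:
        raise ValueError(f"need >= 20 compounds to tune nu, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate feature matrix: all compounds identical")

    km = KMeans(n_clusters=2, n_init=config.kmeans_restarts, random_state=config.seed)
    ref = km.fit_predict(X)
    counts = np.bincount(ref, minlength=2)
    minority = int(np.argmin(counts))
    ref_neg = ref == minority  # reference-negative mask

    lo, hi = config.negative_band
    agreement: dict[float, float] = {}
    fractions: dict[float, float] = {}
    for nu in sorted(config.nu_grid):
        _, dec = _fit_ocsvm(X, nu, config.gamma_rule)
        neg = dec < 0
        frac = float(neg.mean())
        fractions[nu] = frac
        if lo <= frac <= hi:
            match = float((neg == ref_neg).mean())
            agreement[nu] = max(match, 1.0 - match)

    if len(config.nu_grid) == 1:
        nu_star = float(config.nu_grid[0])
        in_band = lo <= fractions[nu_star] <= hi
        if not in_band:
            warnings.warn(
                f"no nu in the grid yields a negative fraction inside [{lo}, {hi}]; "
                f"using nu={nu_star} (fraction {fractions[nu_star]:.3f})",
                stacklevel=2,
            )
    elif agreement:
        best = max(agreement.values())
        nu_star = min(nu for nu, a in agreement.items() if a == best)
        in_band = True
    else:
        mid = 0.5 * (lo + hi)
        nu_star = min(fractions, key=lambda nu: (abs(fractions[nu] - mid), nu))
        in_band = False
        warnings.warn(
            f"no nu in the grid yields a negative fraction inside [{lo}, {hi}]; "
            f"using nu={nu_star} (fraction {fractions[nu_star]:.3f})",
            stacklevel=2,
        )
    diagnostics = {
        "agreement": agreement,
        "negative_fractions": fractions,
        "in_band": in_band,
        "reference_minority_size": int(counts[minority]),
    }
    return float(nu_star), diagnostics


def classify(features: pd.DataFrame, nu: float, config: APTConfig | None = None,
             diagnostics: dict | None = None) -> ClassificationResult:
    """Fit the final RBF one-class SVM at nu and label every compound."""
    config = config or APTConfig()
    if not (0.0 < nu < 1.0):
        raise ValueError("nu must lie in (0, 1)")
    cols = OCSVM_FEATURES if set(OCSVM_FEATURES) <= set(features.columns) else list(features.columns)
    X = features[cols].to_numpy(dtype=float)
    model, dec = _fit_ocsvm(X, nu, config.gamma_rule)
    labels = pd.Series(np.where(dec >= 0, "positive", "negative"), index=features.index)
    decision = pd.Series(dec, index=features.index)
    neg_frac = float((dec < 0).mean())
    diagnostics = diagnostics or {}
    return ClassificationResult(
        labels=labels,
        decision=decision,
        nu=float(nu),
        negative_fraction=neg_frac,
        agreement=diagnostics.get("agreement", {}),
        in_band=diagnostics.get("in_band", True),
        model=model,
        features=features[cols],
    )


def apply_level_policy(result: ClassificationResult, level: int) -> tuple[pd.Index, list[tuple[str, str]]]:
    """Level 0: drop negatives (logged).  Level 1: keep all, labels attached."""
    if level == 0:
        removed = [(str(c), "ocsvm:negative") for c in result.negatives]
        return result.positives, removed
    return result.labels.index, []
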