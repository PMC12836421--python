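"""Synthetic DEL selection datasets with known ground truth.

The generator emulates the structure of a cell-based DEL selection
campaign: a combinatorial library of 3-building-block compounds with a
skewed (log-normal) pre-selection frequency distribution, several paired
biological replicates per antibody arm, heavy overdispersed background
noise, a population of nonspecific binders that enrich equally in both arms
in expectation, phospho-antibody artifact binders that enrich in the
phospho arm only, and a planted set of agonists enriched preferentially in
the phospho arm.  Per selection file, a compound's count is drawn from a
negative-binomial (default) or Poisson model around

    depth x pre_frequency x enrichment / (normalization),

where the enrichment factor is 1 for inert compounds, a per-compound
log-normal factor for binders and artifacts, and the configured
phospho/total factors for agonists — applied only in replicates where the
agonist "hits" (independent Bernoulli per replicate, the reproducibility
parameter).

It does not attempt to model read-level artifacts (PCR bias, sequencing
error, barcode collisions): the noise enters only through the count draw.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from delhit.io_manifest import CountMatrix, ManifestEntry, SelectionManifest

__all__ = ["SimulationSpec", "simulate", "write_dataset", "worked_example_fixture"]


@dataclass
class SimulationSpec:
    """Ground-truth generative model for one synthetic selection campaign.

    Defaults describe the study conditions used throughout the test suite: a
    100k-member library sequenced at ~1.5 reads per compound over 6 paired
    replicates per arm; a modestly skewed pre-selection pool; 3% weak
    nonspecific binders (affinity continuum, equal in both arms in
    expectation); 1% phospho-antibody artifact binders (phospho arm only);
    and 40 planted agonists at 50x phospho / 5x total enrichment that are
    far more replicate-stable than the background.
    """

    n_compounds: int = 100_000
    bb_sizes: tuple[int, int, int] = (50, 50, 40)
    n_replicates: int = 6
    depth: int = 150_000
    pre_depth: int = 5_000_000
    pre_lognormal_mu: float = 0.0
    pre_lognormal_sigma: float = 0.3
    background_fraction: float = 0.03
    background_enrichment_mu: float = math.log(4.0)   # log-normal, both arms
    background_enrichment_sigma: float = 0.9
    background_arm_bias_sigma: float = 0.2  # compound-level capture bias, zero-mean in log
    # phospho-antibody artifact binders: enrich in the phospho pulldown only
    # (classic antibody/matrix binder failure mode); the positive/negative
    # cluster split along the total-arm axis exists to reject exactly these
    artifact_fraction: float = 0.01
    artifact_enrichment_mu: float = math.log(40.0)
    artifact_enrichment_sigma: float = 0.8
    n_actives: int = 40
    phospho_enrichment: float = 50.0
    total_enrichment: float = 5.0
    active_enrichment_sigma: float = 0.1  # log-normal spread around the factors
    # per-(compound, replicate) biological jitter: nonspecific background is
    # far less reproducible than genuine (covalently captured) actives —
    # replicate stability is the signature the descriptor system keys on
    replicate_noise_sigma: float = 0.6
    active_replicate_noise_sigma: float = 0.25
    reproducibility: float = 1.0
    noise_model: str = "negative_binomial"  # or "poisson"
    dispersion: float = 8.0                 # NB size parameter; larger = closer to Poisson
    phospho_label: str = "pY1355"
    total_label: str = "INSR"
    seed: int = 42

    def __post_init__(self) -> None:
        b1, b2, b3 = self.bb_sizes
        if b1 * b2 * b3 < self.n_compounds:
            raise ValueError("building-block grid smaller than n_compounds")
        if self.depth <= 0 or self.pre_depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.n_compounds <= 0:
            raise ValueError("empty library")
        if self.phospho_enrichment < 1 or self.total_enrichment < 1:
            raise ValueError("enrichment factors must be >= 1")
        if self.noise_model not in ("negative_binomial", "poisson"):
            raise ValueError("noise_model must be 'negative_binomial' or 'poisson'")


def _codes(spec: SimulationSpec) -> list[str]:
    _, b2, b3 = spec.bb_sizes
    ks = np.arange(spec.n_compounds)
    return [f"{k // (b2 * b3)}-{(k // b3) % b2}-{k % b3}" for k in ks]


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    mean = np.maximum(mean, 0.0)
    if spec.noise_model == "poisson":
        return rng.poisson(mean)
    k = spec.dispersion
    # NB with mean m and size k: var = m + m^2/k
    p = k / (k + np.maximum(mean, 1e-300))
    out = np.zeros_like(mean, dtype=np.int64)
    nz = mean > 0
    out[nz] = rng.negative_binomial(k, p[nz])
    return out


def simulate(spec: SimulationSpec | None = None) -> tuple[CountMatrix, SelectionManifest, pd.DataFrame]:
    """Draw one campaign; returns (CountMatrix, SelectionManifest, truth).

    ``truth`` has one row per compound with columns ``label`` (agonist /
    binder / inert), ``phospho_enrichment`` and ``total_enrichment``.
    Identical spec + seed reproduce the draw exactly.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    codes = _codes(spec)
    n = spec.n_compounds
    idx = pd.Index(codes, name="compound")

    pre_freq = rng.lognormal(spec.pre_lognormal_mu, spec.pre_lognormal_sigma, n)
    pre_freq /= pre_freq.sum()
    # the naive-library reference is deep, well-mixed sequencing with no
    # selection step, so plain Poisson sampling noise applies
    pre_counts = rng.poisson(spec.pre_depth * pre_freq)

    labels = np.full(n, "inert", dtype=object)
    n_bg = int(round(spec.background_fraction * n))
    n_art = int(round(spec.artifact_fraction * n))
    special = rng.choice(n, size=n_bg + n_art + spec.n_actives, replace=False)
    bg_ids = special[:n_bg]
    art_ids = special[n_bg : n_bg + n_art]
    active_ids = special[n_bg + n_art :]
    labels[bg_ids] = "binder"
    labels[art_ids] = "artifact"
    labels[active_ids] = "agonist"

    enrich_p = np.ones(n)
    enrich_t = np.ones(n)
    bg_factor = rng.lognormal(spec.background_enrichment_mu, spec.background_enrichment_sigma, n_bg)
    # nonspecific binders capture equally in expectation; individual compounds
    # carry a consistent arm-capture bias (e.g. affinity for one antibody)
    bias = np.exp(rng.normal(0.0, spec.background_arm_bias_sigma, n_bg))
    enrich_p[bg_ids] = bg_factor * bias
    enrich_t[bg_ids] = bg_factor / bias
    enrich_p[art_ids] = rng.lognormal(spec.artifact_enrichment_mu, spec.artifact_enrichment_sigma, n_art)
    s = spec.active_enrichment_sigma
    scale = rng.lognormal(0.0, s, spec.n_actives) if s > 0 else np.ones(spec.n_actives)
    enrich_p[active_ids] = spec.phospho_enrichment * scale
    enrich_t[active_ids] = np.maximum(spec.total_enrichment * scale, 1.0)

    entries = []
    count_cols: dict[str, np.ndarray] = {}
    for arm, arm_label, base_enrich in (
        ("phospho", spec.phospho_label, enrich_p),
        ("total", spec.total_label, enrich_t),
    ):
        for rep in range(1, spec.n_replicates + 1):
            e = base_enrich.copy()
            # agonists hit a replicate with probability = reproducibility
            miss = rng.random(spec.n_actives) > spec.reproducibility
            e[active_ids[miss]] = 1.0
            jitter_sigma = np.full(n, spec.replicate_noise_sigma)
            jitter_sigma[active_ids] = spec.active_replicate_noise_sigma
            if (jitter_sigma > 0).any():
                e = e * rng.lognormal(0.0, 1.0, n) ** jitter_sigma
            w = pre_freq * e
            mean = spec.depth * w / w.sum()
            entry = ManifestEntry(
                path=f"{rep}-{arm_label}.erh", arm=arm, arm_label=arm_label,
                replicate=rep, value_kind="count",
            )
            entries.append(entry)
            count_cols[entry.key] = _draw_counts(rng, mean, spec)

    manifest = SelectionManifest(files=entries, pre_selection="pre.erh")
    counts = pd.DataFrame(count_cols, index=idx).astype(float)
    matrix = CountMatrix(
        counts=counts,
        richness=None,
        pre_counts=pd.Series(pre_counts.astype(float), index=idx),
        manifest=manifest,
    )
    truth = pd.DataFrame(
        {"label": labels, "phospho_enrichment": enrich_p, "total_enrichment": enrich_t},
        index=idx,
    )
    return matrix, manifest, truth


def write_dataset(spec: SimulationSpec, out_dir: str | Path) -> Path:
    """Write the simulated campaign as ERH files + manifest.yaml + truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, manifest, truth = simulate(spec)
    for e in manifest.files:
        col = matrix.counts[e.key]
        nz = col[col > 0]
        df = pd.DataFrame({"compound": nz.index, "count": nz.astype(int).to_numpy()})
        df.to_csv(out / Path(e.path).name, sep="\t", index=False)
    pre = matrix.pre_counts
    nz = pre[pre > 0]
    pd.DataFrame({"compound": nz.index, "count": nz.astype(int).to_numpy()}).to_csv(
        out / "pre.erh", sep="\t", index=False
    )
    man = {
        "pre_selection": "pre.erh",
        "files": [
            {
                "path": Path(e.path).name,
                "arm": e.arm,
                "arm_label": e.arm_label,
                "replicate": e.replicate,
                "value_kind": e.value_kind,
            }
            for e in manifest.files
        ],
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(man, fh, sort_keys=False)
    truth.to_csv(out / "truth.csv")
    spec_dict = {k: (float(v) if isinstance(v, (np.floating, float)) else v)
                 for k, v in asdict(spec).items()}
    spec_dict["bb_sizes"] = [int(b) for b in spec.bb_sizes]
    with open(out / "spec.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=False)
    return out / "manifest.yaml"


# Synthetic stand-in for the published single-compound worked example:
# compound 186-5-89 over five paired replicates {1, 7, 10, 12, 13}.  Two
# single-file richness values are anchored to the published record (2.35 in
# the replicate-10 phospho file, 3153.48 in the replicate-12 total file);
# the remaining pairs are synthetic, constructed so the phospho arm wins in
# replicates 1, 7 and 13 with conditional richness sums of 1628.53
# (phospho) vs 8.85 (total).
_WORKED_REPS = (1, 7, 10, 12, 13)
_WORKED_PHOSPHO = (800.00, 600.00, 2.35, 10.00, 228.53)
_WORKED_TOTAL = (5.00, 2.60, 6.20, 3153.48, 1.25)


def worked_example_fixture() -> CountMatrix:
    """One-compound, five-paired-replicate richness fixture (code 186-5-89).

    Three of the five replicate pairs are synthetic stand-ins; see the
    module-level note for which values are anchored.  Used to exercise the
    comparison-indicator and conditional-summation operations.
    """
    entries = []
    vals: dict[str, float] = {}
    for rep, p, t in zip(_WORKED_REPS, _WORKED_PHOSPHO, _WORKED_TOTAL):
        ep = ManifestEntry(path=f"{rep}-pY1355.erh", arm="phospho", arm_label="pY1355",
                           replicate=rep, value_kind="richness")
        et = ManifestEntry(path=f"{rep}-INSR.erh", arm="total", arm_label="INSR",
                           replicate=rep, value_kind="richness")
        entries.extend([ep, et])
        vals[ep.key] = p
        vals[et.key] = t
    manifest = SelectionManifest(files=entries, pre_selection=None)
    idx = pd.Index(["186-5-89"], name="compound")
    richness = pd.DataFrame({k: [v] for k, v in vals.items()}, index=idx)
    return CountMatrix(counts=None, richness=richness, pre_counts=None, manifest=manifest)
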