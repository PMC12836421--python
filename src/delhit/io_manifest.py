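"""Dataset manifest and count-table I/O.

A DEL selection campaign is described by a *manifest*: one pre-selection
reference table plus a list of per-replicate selection files, each assigned
to an arm (``phospho`` = phospho-specific antibody pulldown, ``total`` =
total-target antibody pulldown), an arm label (e.g. ``pY1355``, ``INSR``),
and a replicate index.  Selection files are plain delimited text ("ERH"
dialect): column 1 is the compound code ``bb1-bb2-bb3``, the remaining
column(s) carry the abundance count and/or a precomputed richness value.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CompoundCode",
    "ManifestEntry",
    "SelectionManifest",
    "CountMatrix",
    "FilterReport",
    "ManifestError",
    "TableFormatError",
    "read_manifest",
    "read_count_tables",
    "write_results",
]

_CODE_RE = re.compile(r"^(\d+)-(\d+)-(\d+)$")

VALUE_KINDS = ("count", "richness", "both")
ARMS = ("phospho", "total")


class ManifestError(ValueError):
    """Raised when a manifest is structurally invalid."""


class TableFormatError(ValueError):
    """Raised when a selection file cannot be parsed."""


@dataclass(frozen=True, order=True)
class CompoundCode:
    """A 3-building-block compound identifier, e.g. ``132-172-139``."""

    bb1: int
    bb2: int
    bb3: int

    def __post_init__(self) -> None:
        if min(self.bb1, self.bb2, self.bb3) < 0:
            raise ValueError(f"building-block indices must be >= 0, got {self}")

    def __str__(self) -> str:
        return f"{self.bb1}-{self.bb2}-{self.bb3}"

    @classmethod
    def parse(cls, text: str) -> "CompoundCode":
        m = _CODE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"malformed compound code: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)), int(m.group(3)))


@dataclass(frozen=True)
class ManifestEntry:
    """One selection file: path, arm, free-text arm label, replicate index."""

    path: str
    arm: str
    arm_label: str
    replicate: int
    value_kind: str = "count"

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ManifestError(f"{self.path}: arm must be one of {ARMS}, got {self.arm!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ManifestError(
                f"{self.path}: value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.replicate < 1:
            raise ManifestError(f"{self.path}: replicate index must be >= 1")

    @property
    def key(self) -> str:
        """Column key used in count/richness tables."""
        return f"{self.replicate}-{self.arm_label}"


@dataclass
class SelectionManifest:
    """Validated file-to-(arm, replicate) mapping for one campaign."""

    files: list[ManifestEntry]
    pre_selection: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for e in self.files:
            k = (e.arm, e.arm_label, e.replicate)
            if k in seen:
                raise ManifestError(f"duplicate (arm, label, replicate) entry: {k}")
            seen.add(k)
        for arm in ARMS:
            if self.files and len([e for e in self.files if e.arm == arm]) == 0:
                raise ManifestError(f"manifest has no files for arm {arm!r}")
        for arm in ARMS:
            reps = [e.replicate for e in self.files if e.arm == arm]
            if reps and len(set(reps)) < 2:
                raise ManifestError(f"arm {arm!r} needs >= 2 replicates, got {sorted(set(reps))}")
        total_reps = {e.replicate for e in self.files if e.arm == "total"}
        for e in self.files:
            if e.arm == "phospho" and e.replicate not in total_reps:
                raise ManifestError(
                    f"unpaired replicate: phospho file {e.path!r} (replicate {e.replicate}) "
                    "has no total-arm file with the same replicate index"
                )
        needs_pre = any(e.value_kind in ("count", "both") for e in self.files)
        if needs_pre and self.pre_selection is None:
            raise ManifestError(
                "manifest lists count-valued files but no pre_selection reference "
                "(richness cannot be derived)"
            )

    @property
    def phospho_labels(self) -> list[str]:
        out: list[str] = []
        for e in self.files:
            if e.arm == "phospho" and e.arm_label not in out:
                out.append(e.arm_label)
        return out

    def arm_files(self, arm: str, arm_label: str | None = None) -> list[ManifestEntry]:
        out = [e for e in self.files if e.arm == arm]
        if arm_label is not None:
            out = [e for e in out if e.arm_label == arm_label]
        return sorted(out, key=lambda e: e.replicate)

    def paired_replicates(self, phospho_label: str) -> list[tuple[ManifestEntry, ManifestEntry]]:
        """(phospho, total) entry pairs sharing a replicate index."""
        total_by_rep = {e.replicate: e for e in self.arm_files("total")}
        pairs = []
        for e in self.arm_files("phospho", phospho_label):
            pairs.append((e, total_by_rep[e.replicate]))
        return pairs


@dataclass
class CountMatrix:
    """Compounds x selection-files table of counts and/or richness.

    ``counts`` and ``richness`` are dense DataFrames indexed by canonical
    compound-code strings with one column per manifest entry key; a compound
    absent from a file holds 0 in that column.  ``pre_counts`` is the
    pre-selection reference (counts per compound; zeros allowed).
    """

    counts: pd.DataFrame | None
    richness: pd.DataFrame | None
    pre_counts: pd.Series | None
    manifest: SelectionManifest
    # full-file totals, preserved through subset() so richness frequencies
    # always refer to the complete selection files
    file_totals: pd.Series | None = None
    pre_total: float | None = None

    def __post_init__(self) -> None:
        if self.file_totals is None and self.counts is not None:
            self.file_totals = self.counts.sum(axis=0)
        if self.pre_total is None and self.pre_counts is not None:
            self.pre_total = float(self.pre_counts.sum())

    @property
    def compounds(self) -> pd.Index:
        if self.counts is not None:
            return self.counts.index
        assert self.richness is not None
        return self.richness.index

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    def subset(self, compounds: Sequence[str]) -> "CountMatrix":
        idx = pd.Index(compounds)
        return CountMatrix(
            counts=None if self.counts is None else self.counts.loc[idx],
            richness=None if self.richness is None else self.richness.loc[idx],
            pre_counts=None if self.pre_counts is None else self.pre_counts.loc[idx],
            manifest=self.manifest,
            file_totals=self.file_totals,
            pre_total=self.pre_total,
        )


@dataclass
class FilterReport:
    """Ordered per-stage record of compounds removed and why."""

    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, level: int, n_in: int, removed: list[tuple[str, str]]) -> None:
        if self.stages:
            prev = self.stages[-1]
            if prev["level"] == level and n_in != prev["n_out"]:
                raise ValueError(
                    f"stage {name!r}: n_in={n_in} does not chain from previous n_out={prev['n_out']}"
                )
        self.stages.append(
            {
                "stage": name,
                "level": level,
                "n_in": n_in,
                "n_out": n_in - len(removed),
                "removed": [{"compound": str(c), "reason": r} for c, r in removed],
            }
        )

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def read_manifest(path: str | Path) -> SelectionManifest:
    """Read a JSON or YAML manifest file into a validated SelectionManifest.

    Expected structure::

        pre_selection: pre.erh          # optional when all files are richness
        files:
          - {path: 1-pY1355.erh, arm: phospho, arm_label: pY1355,
             replicate: 1, value_kind: count}

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "files" not in raw:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'files' list")
    base = path.parent
    entries = []
    for i, item in enumerate(raw["files"]):
        try:
            entries.append(
                ManifestEntry(
                    path=str(base / item["path"]),
                    arm=item["arm"],
                    arm_label=str(item.get("arm_label", item["arm"])),
                    replicate=int(item["replicate"]),
                    value_kind=item.get("value_kind", "count"),
                )
            )
        except KeyError as exc:
            raise ManifestError(f"{path}: files[{i}] missing key {exc}") from exc
    pre = raw.get("pre_selection")
    return SelectionManifest(
        files=entries, pre_selection=None if pre is None else str(base / pre)
    )


def _sniff_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def _read_erh(path: str, value_kind: str) -> pd.DataFrame:
    """Read one delimited selection file.

    Returns a DataFrame indexed by compound-code string with columns
    ``count`` and/or ``richness`` depending on ``value_kind``.  A 3-column
    file carries (code, count, richness) and is only accepted when
    value_kind is ``both``.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(path)
    with open(p, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first:
        raise TableFormatError(f"{path}: empty file")
    sep = _sniff_delimiter(first)
    tokens = first.rstrip("\n").split(sep)
    has_header = _CODE_RE.match(tokens[0].strip()) is None
    df = pd.read_csv(
        p,
        sep=sep if sep is not None else r"\s+",
        header=0 if has_header else None,
        engine="python" if sep is None else "c",
        dtype=str,
        comment=None,
    )
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected >= 2 columns, found {df.shape[1]}")
    ncols = df.shape[1]
    if value_kind == "both":
        if ncols < 3:
            raise TableFormatError(f"{path}: value_kind=both requires 3 columns (code, count, richness)")
        names = ["code", "count", "richness"]
    elif value_kind == "count":
        names = ["code", "count"]
    else:
        names = ["code", "richness"]
    df = df.iloc[:, : len(names)]
    df.columns = names

    codes = []
    for lineno, text in enumerate(df["code"], start=2 if has_header else 1):
        m = _CODE_RE.match(str(text).strip())
        if m is None:
            raise TableFormatError(f"{path}:{lineno}: malformed compound code {text!r}")
        codes.append(str(CompoundCode(int(m.group(1)), int(m.group(2)), int(m.group(3)))))
    out = pd.DataFrame(index=pd.Index(codes, name="compound"))
    for col in names[1:]:
        vals = pd.to_numeric(df[col].str.strip() if df[col].dtype == object else df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            lineno = int(np.argmax(bad.to_numpy())) + (2 if has_header else 1)
            raise TableFormatError(f"{path}:{lineno}: unparseable numeric value {df[col].iloc[int(np.argmax(bad.to_numpy()))]!r}")
        if (vals < 0).any():
            lineno = int(np.argmax((vals < 0).to_numpy())) + (2 if has_header else 1)
            raise TableFormatError(f"{path}:{lineno}: negative value")
        out[col] = vals.to_numpy()
    if out.index.has_duplicates:
        out = out.groupby(level=0).sum()
    return out


def read_count_tables(manifest: SelectionManifest) -> CountMatrix:
    """Load every manifest file into a CountMatrix (union of compounds, zero-filled)."""
    per_file: dict[str, pd.DataFrame] = {}
    for e in manifest.files:
        per_file[e.key] = _read_erh(e.path, e.value_kind)

    pre = None
    if manifest.pre_selection is not None:
        pre_df = _read_erh(manifest.pre_selection, "count")
        pre = pre_df["count"]

    universe: pd.Index = pd.Index([], name="compound")
    for df in per_file.values():
        universe = universe.union(df.index)
    if pre is not None:
        universe = universe.union(pre.index)
    universe = _sort_codes(universe)

    any_counts = any(e.value_kind in ("count", "both") for e in manifest.files)
    any_rich = any(e.value_kind in ("richness", "both") for e in manifest.files)
    counts = pd.DataFrame(0.0, index=universe, columns=[e.key for e in manifest.files]) if any_counts else None
    richness = pd.DataFrame(0.0, index=universe, columns=[e.key for e in manifest.files]) if any_rich else None
    for e in manifest.files:
        df = per_file[e.key]
        if counts is not None and "count" in df.columns:
            counts.loc[df.index, e.key] = df["count"].to_numpy()
        if richness is not None and "richness" in df.columns:
            richness.loc[df.index, e.key] = df["richness"].to_numpy()
    if pre is not None:
        pre = pre.reindex(universe, fill_value=0.0)
    return CountMatrix(counts=counts, richness=richness, pre_counts=pre, manifest=manifest)


def _sort_codes(idx: Iterable[str]) -> pd.Index:
    keyed = sorted(idx, key=lambda s: tuple(int(t) for t in s.split("-")))
    return pd.Index(keyed, name="compound")


HIT_COLUMNS = [
    "compound",
    "arm_label",
    "x",
    "y",
    "cluster_side",
    "indicator",
    "SR_cond_phospho",
    "SR_cond_total",
    "SC_cond_phospho",
    "SC_cond_total",
    "centroid_distance",
    "score",
    "rank",
    "overlap_flag",
]


def write_results(hits: pd.DataFrame, report: FilterReport, out_dir: str | Path) -> dict[str, Path]:
    """Write hits.csv (stable column order) and filter_report.json; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [c for c in HIT_COLUMNS if c in hits.columns] + [
        c for c in hits.columns if c not in HIT_COLUMNS
    ]
    hits_path = out / "hits.csv"
    hits.loc[:, cols].to_csv(hits_path, index=False, float_format="%.12g")
    report_path = out / "filter_report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return {"hits": hits_path, "report": report_path}
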