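"""Tabular text readers and writers, and the run configuration.

Every interchange format is comma-separated text with an explicit
header.  Files that describe a single structured object (a tank pattern,
a pen survey) start with a ``#`` metadata line of ``key=value`` pairs
followed by a regular CSV table; flat record files (assays, saponin
library, profiles) are plain CSV.  Malformed headers are rejected with
the offending file and line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assays import AssayRecord
from .patterns import EnvelopeTestResult, KEstimate, PointPattern
from .quadrats import QuadratSurvey
from .saponins import (
    LibraryEntry,
    SampleProfile,
    SaponinLibrary,
    SaponinProfileSet,
)
from .windows import Disk


class FormatError(ValueError):
    """Malformed input file; message carries file and line number."""


def _parse_meta(path: Path, expected_keys) -> dict:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith("#"):
        raise FormatError(f"{path}:1: expected a '# key=value,...' metadata line")
    meta = {}
    for i, item in enumerate(first.lstrip("#").strip().split(",")):
        if "=" not in item:
            raise FormatError(f"{path}:1: malformed metadata item {item!r}")
        k, v = item.split("=", 1)
        meta[k.strip()] = v.strip()
    missing = set(expected_keys) - set(meta)
    if missing:
        raise FormatError(f"{path}:1: metadata missing keys {sorted(missing)}")
    return meta


def _read_table(path: Path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != list(columns):
        raise FormatError(
            f"{path}:2: expected header {','.join(columns)!r}, got "
            f"{','.join(df.columns)!r}"
        )
    return df


# -- tank coordinate patterns ----------------------------------------------

def write_pattern(path, tank_id: str, pattern: PointPattern) -> None:
    if not isinstance(pattern.window, Disk):
        raise ValueError("pattern files describe disk (tank) windows")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tank_id={tank_id},diameter_cm={2 * pattern.window.radius:g}\n")
        fh.write("id,x_cm,y_cm\n")
        for i, (x, y) in enumerate(pattern.points, start=1):
            fh.write(f"{i},{x:.6g},{y:.6g}\n")


def read_pattern(path) -> tuple[str, PointPattern]:
    """Read a tank file; coordinates are cm with the origin at the centre."""
    path = Path(path)
    meta = _parse_meta(path, ("tank_id", "diameter_cm"))
    try:
        diameter = float(meta["diameter_cm"])
    except ValueError:
        raise FormatError(f"{path}:1: diameter_cm={meta['diameter_cm']!r} is not a number")
    df = _read_table(path, ("id", "x_cm", "y_cm"))
    pts = df[["x_cm", "y_cm"]].to_numpy(dtype=float)
    return meta["tank_id"], PointPattern(pts, Disk((0.0, 0.0), diameter / 2.0))


# -- quadrat surveys --------------------------------------------------------

def write_survey(path, survey: QuadratSurvey) -> None:
    rows, cols = survey.counts_surface.shape
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# pen_id={survey.pen_id},month={survey.month},"
            f"quadrat_area_m2={survey.quadrat_area:g},n_rows={rows},n_cols={cols}\n"
        )
        fh.write("row,col,surface,buried\n")
        for r in range(rows):
            for c in range(cols):
                fh.write(
                    f"{r},{c},{survey.counts_surface[r, c]},{survey.counts_buried[r, c]}\n"
                )


def read_survey(path) -> QuadratSurvey:
    path = Path(path)
    meta = _parse_meta(
        path, ("pen_id", "month", "quadrat_area_m2", "n_rows", "n_cols")
    )
    try:
        rows, cols = int(meta["n_rows"]), int(meta["n_cols"])
        area = float(meta["quadrat_area_m2"])
    except ValueError as exc:
        raise FormatError(f"{path}:1: bad numeric metadata ({exc})")
    df = _read_table(path, ("row", "col", "surface", "buried"))
    if len(df) != rows * cols:
        raise FormatError(
            f"{path}: expected {rows * cols} quadrat rows for a {rows}x{cols} grid, "
            f"got {len(df)}"
        )
    surface = np.zeros((rows, cols), dtype=int)
    buried = np.zeros((rows, cols), dtype=int)
    for line_no, rec in enumerate(df.itertuples(index=False), start=3):
        r, c = int(rec.row), int(rec.col)
        if not (0 <= r < rows and 0 <= c < cols):
            raise FormatError(f"{path}:{line_no}: quadrat index ({r},{c}) outside grid")
        surface[r, c] = int(rec.surface)
        buried[r, c] = int(rec.buried)
    return QuadratSurvey(meta["pen_id"], meta["month"], surface, buried, area)


# -- behavioural assays -----------------------------------------------------

def write_assays(path, records, control_labels=()) -> None:
    control_labels = set(control_labels)
    with open(path, "w") as fh:
        fh.write("stimulus_label,moved,total,is_control\n")
        for rec in records:
            fh.write(
                f"{rec.stimulus},{rec.moved},{rec.total},"
                f"{int(rec.stimulus in control_labels)}\n"
            )


def read_assays(path) -> tuple[list[AssayRecord], list[AssayRecord]]:
    """Read assay records; returns (stimulus records, control records)."""
    path = Path(path)
    df = _read_table(path, ("stimulus_label", "moved", "total", "is_control"))
    stim, ctrl = [], []
    for line_no, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            r = AssayRecord(str(rec.stimulus_label), int(rec.moved), int(rec.total))
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: {exc}")
        (ctrl if int(rec.is_control) else stim).append(r)
    return stim, ctrl


# -- saponin library and profiles ------------------------------------------

def write_library(path, library: SaponinLibrary) -> None:
    with open(path, "w") as fh:
        fh.write("names,mz_na,n_sugars\n")
        for e in library:
            fh.write(f"{'|'.join(e.names)},{e.mz_na:g},{e.n_sugars}\n")


def read_library(path) -> SaponinLibrary:
    path = Path(path)
    df = _read_table(path, ("names", "mz_na", "n_sugars"))
    entries = []
    for line_no, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(
                LibraryEntry(tuple(str(rec.names).split("|")), float(rec.mz_na), int(rec.n_sugars))
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: {exc}")
    return SaponinLibrary(entries)


def write_profiles(path, profiles: SaponinProfileSet) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id,attractive,detected_mz\n")
        for s in profiles.samples:
            mzs = " ".join(f"{m:g}" for m in sorted(s.detected, reverse=True))
            fh.write(f"{s.sample_id},{int(s.attractive)},{mzs}\n")


def read_profiles(path, library: SaponinLibrary) -> SaponinProfileSet:
    path = Path(path)
    df = _read_table(path, ("sample_id", "attractive", "detected_mz"))
    samples = []
    for line_no, rec in enumerate(df.itertuples(index=False), start=2):
        raw = "" if pd.isna(rec.detected_mz) else str(rec.detected_mz)
        try:
            detected = frozenset(float(v) for v in raw.split())
            samples.append(
                SampleProfile(str(rec.sample_id), bool(int(rec.attractive)), detected)
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: {exc}")
    try:
        return SaponinProfileSet(library, samples)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}")


# -- result writers ---------------------------------------------------------

def write_k_estimate(path, estimate: KEstimate) -> None:
    pd.DataFrame({"r": estimate.r_grid, "k": estimate.k_values}).to_csv(path, index=False)


def write_envelope_result(path, result: EnvelopeTestResult, label: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("label,observed_stat,n_sim,p_value,reference\n")
        fh.write(
            f"{label},{result.observed_stat:.6g},{result.n_sim},"
            f"{result.p_value:.6g},{result.reference}\n"
        )


def write_heatmap_grid(path, heatmap) -> None:
    pd.DataFrame(
        heatmap.density, index=heatmap.y_centers, columns=heatmap.x_centers
    ).to_csv(path, index_label="y\\x")


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Effective configuration for an end-to-end run.

    CLI flags override their file counterparts; the effective config is
    echoed into the report for provenance.
    """

    seed: int = 0
    alpha_dispersion: float = 0.025
    alpha_pattern: float = 0.05
    alpha_assay: float = 0.05
    n_sim: int = 199
    bandwidth_cm: float = 5.0
    n_r: int = 50
    clustered: bool = True
    out_dir: str = "results/run"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_dispersion", "alpha_pattern", "alpha_assay"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.n_sim < 19:
            raise ValueError("n_sim must be at least 19")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = unknown
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"}
        d.update(self.extra)
        return d
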