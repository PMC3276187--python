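"""Developmental-time normalization of growth curves.

Plants under a common environment are developmentally heterogeneous, so
growth curves are compared on a relative developmental timescale: for each
plant, stage 1.04 (beginning of the day its fourth true leaf reached ~10 px)
maps to 0 and stage 1.10 (end of the day its tenth leaf did) maps to 1,
linearly.  Noon trait values inside the window are fitted with a cubic
smoothing spline (smoothing by generalized cross-validation) and resampled on
a uniform relative-time grid, which puts every plant on the same scale for
genetic analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "StageAnnotation",
    "RelativeCurve",
    "read_stage_annotations",
    "relative_time",
    "fit_growth_curve",
    "assemble_phenotype_table",
    "grid_columns",
]

TRAITS = ("RA", "CA", "compactness")


@dataclass(frozen=True)
class StageAnnotation:
    """Per-plant developmental anchors: times of stage 1.04 and 1.10."""

    plant_id: str
    t_104: datetime
    t_110: datetime

    def __post_init__(self) -> None:
        if self.t_110 <= self.t_104:
            raise ValueError(f"plant {self.plant_id}: T1.10 must follow T1.04")


@dataclass
class RelativeCurve:
    plant_id: str
    trait: str
    grid: np.ndarray  # M evenly spaced relative times spanning [0, 1]
    values: np.ndarray  # NaN where the plant has no data coverage

    def __post_init__(self) -> None:
        if abs(self.grid[0]) > 1e-12 or abs(self.grid[-1] - 1.0) > 1e-12:
            raise ValueError("grid must span [0, 1]")


def read_stage_annotations(path: str | Path) -> dict[str, StageAnnotation]:
    """Read stage annotations from CSV (plant_id, t_104, t_110; ISO times)."""
    out: dict[str, StageAnnotation] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ann = StageAnnotation(
                plant_id=row["plant_id"],
                t_104=datetime.fromisoformat(row["t_104"]),
                t_110=datetime.fromisoformat(row["t_110"]),
            )
            out[ann.plant_id] = ann
    return out


def relative_time(t: datetime | float, ann: StageAnnotation) -> float:
    """Linear developmental scaling: (t - T1.04) / (T1.10 - T1.04).

    0 at stage 1.04, 1 at stage 1.10; values outside [0, 1] are legal here
    and excluded downstream.  ``t`` may be a datetime or a number on the same
    axis as the anchors.
    """
    if isinstance(t, datetime):
        num = (t - ann.t_104).total_seconds()
        den = (ann.t_110 - ann.t_104).total_seconds()
    else:
        num = t - _as_number(ann.t_104)
        den = _as_number(ann.t_110) - _as_number(ann.t_104)
    return float(num / den)


def _as_number(t) -> float:
    return t.timestamp() if isinstance(t, datetime) else float(t)


def fit_growth_curve(
    times: Sequence[datetime | float],
    values: Sequence[float],
    ann: StageAnnotation,
    plant_id: str | None = None,
    trait: str = "RA",
    grid_size: int = 101,
    method: str = "smoothing",
) -> RelativeCurve:
    """Fit a spline to noon trait values within the stage window and resample.

    Data points with relative time outside [0, 1] are dropped; at least four
    must remain.  ``method="smoothing"`` uses a cubic smoothing spline with
    GCV-selected stiffness (an interpolating cubic spline is used when too
    few points remain for GCV, and available via ``method="interpolating"``).
    Grid points outside the observed relative-time range are left NaN (no
    extrapolation).
    """
    plant_id = plant_id or ann.plant_id
    rel = np.array([relative_time(t, ann) for t in times], dtype=float)
    vals = np.asarray(values, dtype=float)
    inside = (rel >= -1e-9) & (rel <= 1 + 1e-9) & np.isfinite(vals)
    rel, vals = rel[inside], vals[inside]
    order = np.argsort(rel)
    rel, vals = rel[order], vals[order]
    # collapse duplicate abscissae (splines need strictly increasing x)
    uniq, inv = np.unique(np.round(rel, 12), return_inverse=True)
    if uniq.size != rel.size:
        vals = np.array([vals[inv == i].mean() for i in range(uniq.size)])
        rel = uniq
    if rel.size < 4:
        raise ValueError(f"plant {plant_id}: needs >= 4 noon points in the stage window, got {rel.size}")

    if method == "interpolating" or rel.size < 5:
        spline = CubicSpline(rel, vals)
    elif method == "smoothing":
        spline = make_smoothing_spline(rel, vals)
    else:
        raise ValueError(f"unknown spline method {method!r}")

    grid = np.linspace(0.0, 1.0, grid_size)
    out = np.full(grid_size, np.nan)
    covered = (grid >= rel[0] - 1e-9) & (grid <= rel[-1] + 1e-9)
    out[covered] = spline(grid[covered])
    return RelativeCurve(plant_id=plant_id, trait=trait, grid=grid, values=out)


def grid_columns(grid_size: int) -> list[str]:
    return [f"g{i:03d}" for i in range(grid_size)]


def assemble_phenotype_table(
    curves: Sequence[RelativeCurve],
    metadata: Mapping[str, Mapping[str, str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Join relative curves with plant metadata into a phenotype table.

    ``metadata`` maps plant_id -> {accession, environment} (or an equivalent
    DataFrame indexed by plant_id).  Output: one row per (plant, trait) with
    columns plant_id, accession, environment, trait, g000..g{M-1}.
    """
    if not curves:
        raise ValueError("no curves to assemble")
    if isinstance(metadata, pd.DataFrame):
        meta = metadata.set_index("plant_id") if "plant_id" in metadata.columns else metadata
        metadata = {str(pid): dict(row) for pid, row in meta.iterrows()}
    rows = []
    grid_size = len(curves[0].grid)
    cols = grid_columns(grid_size)
    for curve in curves:
        if len(curve.grid) != grid_size:
            raise ValueError("all curves must share the same grid")
        if curve.plant_id not in metadata:
            raise KeyError(f"plant {curve.plant_id} has no metadata entry")
        m = metadata[curve.plant_id]
        row = {"plant_id": curve.plant_id, "accession": m["accession"],
               "environment": m.get("environment", "E1"), "trait": curve.trait}
        row.update(dict(zip(cols, curve.values)))
        rows.append(row)
    return pd.DataFrame(rows)
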