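"""Indexing, day/night filtering and cropping of flat image series.

A *flat* is a 6x6 grid of pots photographed top-down by one camera at a fixed
interval.  This module turns a directory of time-stamped frames into
per-plant image stacks: it indexes frames inside the analysis window (from
thinning to first bolting), separates day from night frames by the mean
green-minus-red intensity, and crops each frame at the pot coordinates.

Timestamps are parsed from the filename (default pattern
``YYYYmmdd-HHMMSS``), with EXIF DateTimeOriginal as a fallback; channel
intensities are 8-bit values divided by 255, on a common [0, 1] scale.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FlatImage",
    "PotEntry",
    "CoordinateMap",
    "StackFrame",
    "PlantStack",
    "load_flat_image",
    "read_coordinate_maps",
    "build_flat_index",
    "mean_filtered_intensity",
    "suggest_cutoff",
    "classify_day_night",
    "crop_to_stacks",
]

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png"}
DEFAULT_TIME_REGEX = re.compile(r"(\d{8}-\d{6})")
DEFAULT_TIME_FORMAT = "%Y%m%d-%H%M%S"


@dataclass
class FlatImage:
    """One time-stamped RGB frame of a flat, channels on [0, 1]."""

    timestamp: datetime
    pixels: np.ndarray  # H x W x 3 float in [0, 1]
    flat_id: str = "flat"
    season: str = "spring"

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[-1] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("pixels must be a non-empty H x W x 3 array")
        if float(p.min()) < 0.0 or float(p.max()) > 1.0:
            raise ValueError("channel values must lie in [0, 1]")
        if self.season not in ("spring", "summer"):
            raise ValueError("season must be 'spring' or 'summer'")


@dataclass(frozen=True)
class PotEntry:
    pot_id: str
    center_x: float
    center_y: float
    crop_w: int
    crop_h: int
    accession: str

    def box(self) -> tuple[int, int, int, int]:
        """Half-open crop box (row0, row1, col0, col1): [c - w/2, c + w/2)."""
        col0 = int(np.floor(self.center_x - self.crop_w / 2))
        row0 = int(np.floor(self.center_y - self.crop_h / 2))
        return row0, row0 + self.crop_h, col0, col0 + self.crop_w


@dataclass
class CoordinateMap:
    """Pot coordinates for one flat, valid from a given time onward.

    A flat may have several maps with disjoint validity windows because the
    flat can shift slightly during the experiment; a map is valid from its
    ``valid_from`` until the next map's ``valid_from``.
    """

    flat_id: str
    valid_from: datetime
    pots: list[PotEntry]

    def __post_init__(self) -> None:
        ids = [p.pot_id for p in self.pots]
        if len(set(ids)) != len(ids):
            raise ValueError("pot_ids must be unique within a coordinate map")
        if len(self.pots) > 36:
            raise ValueError("at most 36 pots per flat")


@dataclass
class StackFrame:
    timestamp: datetime
    pixels: np.ndarray
    day_index: int  # calendar-day rank k, 1-based
    within_day_index: int  # time-order rank j within the day, 1-based


@dataclass
class PlantStack:
    accession: str
    pot_id: str
    frames: list[StackFrame]

    def __post_init__(self) -> None:
        times = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("stack frames must be strictly increasing in time")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all stack frames must share crop dimensions")


def load_flat_image(path: str | Path, timestamp: datetime, flat_id: str = "flat",
                    season: str = "spring") -> FlatImage:
    """Read an 8-bit RGB image file onto the [0, 1] intensity scale."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    pixels = np.asarray(arr, dtype=float) / 255.0
    return FlatImage(timestamp=timestamp, pixels=pixels, flat_id=flat_id, season=season)


def _exif_timestamp(path: Path) -> datetime | None:
    try:
        from PIL import Image

        with Image.open(path) as im:
            exif = im.getexif()
        raw = exif.get(36867) or exif.get(306)  # DateTimeOriginal, DateTime
        if raw:
            return datetime.strptime(str(raw), "%Y:%m:%d %H:%M:%S")
    except Exception:
        return None
    return None


def parse_timestamp(path: Path, time_regex: re.Pattern = DEFAULT_TIME_REGEX,
                    time_format: str = DEFAULT_TIME_FORMAT) -> datetime | None:
    m = time_regex.search(path.name)
    if m:
        try:
            return datetime.strptime(m.group(1), time_format)
        except ValueError:
            pass
    return _exif_timestamp(path)


def build_flat_index(
    image_dir: str | Path,
    window_start: datetime,
    window_end: datetime,
    corrupt_list: Iterable[str] = (),
    time_regex: re.Pattern = DEFAULT_TIME_REGEX,
    time_format: str = DEFAULT_TIME_FORMAT,
) -> list[tuple[str, datetime]]:
    """Index frame files in time order within the analysis window.

    The window runs from plant thinning to first bolting of the flat.  Files
    in ``corrupt_list`` are excluded; files whose timestamp cannot be parsed
    are excluded with a warning.  Ties in timestamp break by filename.
    """
    if window_start >= window_end:
        raise ValueError("window_start must precede window_end")
    image_dir = Path(image_dir)
    corrupt = set(corrupt_list)
    entries: list[tuple[str, datetime]] = []
    for path in sorted(image_dir.iterdir()):
        if path.suffix.lower() not in IMAGE_EXTENSIONS or path.name in corrupt:
            continue
        t = parse_timestamp(path, time_regex, time_format)
        if t is None:
            warnings.warn(f"could not parse a timestamp for {path.name}; excluded")
            continue
        if window_start <= t <= window_end:
            entries.append((path.name, t))
    entries.sort(key=lambda e: (e[1], e[0]))
    if not entries:
        raise ValueError(f"no usable frames in window for {image_dir}")
    return entries


def mean_filtered_intensity(img: FlatImage | np.ndarray) -> float:
    """Mean over all pixels of (green - red); in [-1, 1]."""
    pixels = img.pixels if isinstance(img, FlatImage) else np.asarray(img, dtype=float)
    return float((pixels[..., 1] - pixels[..., 0]).mean())


def suggest_cutoff(values: Sequence[float]) -> float:
    """Suggest a day/night cutoff: midpoint of the two cluster means under the
    best two-class split of the 1-D values (Otsu-style, exact over splits).

    Raises ``ValueError("no bimodality")`` on (near-)constant series.  The
    suggestion is for operator review; classification always takes an
    explicit cutoff.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2 or np.ptp(v) < 1e-12:
        raise ValueError("no bimodality: series is constant")
    best = None
    for k in range(1, v.size):
        lo, hi = v[:k], v[k:]
        within = lo.var() * lo.size + hi.var() * hi.size
        if best is None or within < best[0]:
            best = (within, float(lo.mean()), float(hi.mean()))
    return (best[1] + best[2]) / 2.0


def classify_day_night(
    series: Sequence[tuple[datetime, float]],
    cutoff: float,
) -> list[str]:
    """Label frames 'day' iff the mean filtered intensity exceeds the cutoff."""
    if not series:
        raise ValueError("series is empty")
    return ["day" if v > cutoff else "night" for _, v in series]


# ---------------------------------------------------------------------------
# Coordinate maps and cropping
# ---------------------------------------------------------------------------

def read_coordinate_maps(path: str | Path) -> list[CoordinateMap]:
    """Read coordinate maps from CSV.

    Columns: flat_id, valid_from (ISO timestamp), pot_id, center_x, center_y,
    crop_w, crop_h, accession; 0-based pixel coordinates, x rightward,
    y downward.
    """
    groups: dict[tuple[str, datetime], list[PotEntry]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["flat_id"], datetime.fromisoformat(row["valid_from"]))
            groups.setdefault(key, []).append(
                PotEntry(
                    pot_id=row["pot_id"],
                    center_x=float(row["center_x"]),
                    center_y=float(row["center_y"]),
                    crop_w=int(row["crop_w"]),
                    crop_h=int(row["crop_h"]),
                    accession=row["accession"],
                )
            )
    maps = [CoordinateMap(flat_id=f, valid_from=t, pots=pots)
            for (f, t), pots in groups.items()]
    maps.sort(key=lambda m: (m.flat_id, m.valid_from))
    return maps


def _map_for(maps: Sequence[CoordinateMap], t: datetime) -> CoordinateMap:
    candidates = [m for m in maps if m.valid_from <= t]
    if not candidates:
        raise ValueError(f"no coordinate map valid at {t.isoformat()}")
    return max(candidates, key=lambda m: m.valid_from)


def crop_to_stacks(
    index: Sequence[tuple[str, datetime]],
    maps: Sequence[CoordinateMap],
    labels: Sequence[str],
    image_dir: str | Path,
    season: str = "spring",
) -> list[PlantStack]:
    """Crop the daytime frames of a flat into one stack per pot.

    ``index`` and ``labels`` are parallel (from :func:`build_flat_index` and
    :func:`classify_day_night`).  Day index k is the calendar-date rank
    within the window (1-based); within-day index j is the time-order rank of
    the daytime frames of that day (1-based).  Night frames are excluded.
    """
    if len(index) != len(labels):
        raise ValueError("index and labels must be parallel sequences")
    image_dir = Path(image_dir)
    day_frames = [(name, t) for (name, t), lab in zip(index, labels) if lab == "day"]
    if not day_frames:
        raise ValueError("no daytime frames to crop")

    dates = sorted({t.date() for _, t in day_frames})
    day_rank = {d: k + 1 for k, d in enumerate(dates)}
    within: dict[date, int] = {}

    stacks: dict[str, dict] = {}
    for name, t in day_frames:
        cmap = _map_for(maps, t)
        img = load_flat_image(image_dir / name, t, cmap.flat_id, season)
        h, w = img.pixels.shape[:2]
        within[t.date()] = within.get(t.date(), 0) + 1
        j = within[t.date()]
        for pot in cmap.pots:
            r0, r1, c0, c1 = pot.box()
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"crop box out of bounds for pot {pot.pot_id}")
            crop = img.pixels[r0:r1, c0:c1].copy()
            rec = stacks.setdefault(pot.pot_id, {"accession": pot.accession, "frames": []})
            rec["frames"].append(StackFrame(timestamp=t, pixels=crop,
                                            day_index=day_rank[t.date()],
                                            within_day_index=j))
    return [
        PlantStack(accession=rec["accession"], pot_id=pot_id, frames=rec["frames"])
        for pot_id, rec in sorted(stacks.items())
    ]
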