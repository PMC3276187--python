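"""Per-plant trait extraction: the noon-anchored daily detection loop.

Each day of a plant's stack is processed in two passes.  First the *noon*
frame — the frame with the highest mean (green - red) intensity, when leaves
lie flat — is segmented with the noon filter/threshold variant anchored on
the previous day's area A_(k-1) (1000 px on day one), yielding the day's
reference area A_k.  Then every frame of the day (noon included, re-processed
for a homogeneous trait series) is segmented with the intra-day variant
anchored on A_k.  The chain of daily areas is the only cross-frame coupling.

Traits per frame: rosette area RA (foreground pixel count), radius (max
centroid-to-edge distance), circular area CA = pi * radius^2, and
compactness = RA / CA (missing when RA = 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import (
    FilterParams,
    ThresholdParams,
    blue_weight,
    filter_intraday,
    filter_noon,
    threshold_intraday,
    threshold_noon,
)
from .image_io import PlantStack, StackFrame
from .segmentation import (
    DetectionResult,
    SegmentationParams,
    binarize,
    label_objects,
    merge_and_measure,
    prune_noise,
)

__all__ = [
    "DailyState",
    "PipelineParams",
    "select_noon_frame",
    "process_day",
    "run_stack",
    "TRAIT_COLUMNS",
]

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = [
    "timestamp", "day", "frame", "RA_px", "radius_px", "CA_px",
    "compactness", "is_noon", "threshold", "U", "D",
]


@dataclass
class PipelineParams:
    """Bundle of all detection parameters."""

    filter: FilterParams = field(default_factory=FilterParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    day_one_area: float = 1000.0  # prior A_i1 for the first day's noon pass
    carry_forward_on_empty: bool = False


@dataclass
class DailyState:
    """Per-day noon areas A_k threading through the stack."""

    day_one_area: float = 1000.0
    noon_areas: dict[int, float] = field(default_factory=dict)

    def anchor_for(self, day: int) -> float:
        """Area anchor for day k's noon pass: A_(k-1), or the prior on day 1."""
        prior_days = [d for d in self.noon_areas if d < day]
        if not prior_days:
            return self.day_one_area
        return self.noon_areas[max(prior_days)]


def select_noon_frame(day_frames: list[StackFrame]) -> int:
    """Index of the frame with maximal mean (green - red); ties -> earliest."""
    if not day_frames:
        raise ValueError("day has no frames")
    scores = [float((f.pixels[..., 1] - f.pixels[..., 0]).mean()) for f in day_frames]
    return int(np.argmax(scores))


def _detect(F: np.ndarray, T: float, prune_anchor: float,
            params: PipelineParams) -> DetectionResult:
    fg = binarize(F, T)
    objects = label_objects(fg, params.segmentation)
    kept, removed = prune_noise(objects, prune_anchor, params.segmentation)
    return merge_and_measure(kept, fg.shape, params.segmentation,
                             threshold=T, removed=removed)


def process_day(
    day_frames: list[StackFrame],
    prev_area: float,
    season: str,
    params: PipelineParams = PipelineParams(),
) -> tuple[float, list[dict], DetectionResult]:
    """Process one day of frames; returns (A_k, per-frame records, noon result).

    Pass 1 (noon): blue weight and threshold anchored on ``prev_area``;
    the detected area becomes A_k.  Pass 2 (all frames): intra-day filter and
    threshold anchored on A_k.  An empty noon detection records A_k = 0 with
    a warning (or carries ``prev_area`` forward if configured).
    """
    if prev_area < 0:
        raise ValueError("prev_area must be nonnegative")
    noon_idx = select_noon_frame(day_frames)
    noon = day_frames[noon_idx]

    # pass 1: noon detection anchored on the previous day
    d_noon = blue_weight(prev_area, params.filter)
    f_noon = filter_noon(noon.pixels, d_noon, params.filter)
    u_noon = float(f_noon.mean())
    t_noon = threshold_noon(u_noon, prev_area, params.threshold)
    noon_result = _detect(f_noon, t_noon, prev_area, params)
    area_k = float(noon_result.area)
    if noon_result.area == 0:
        if params.carry_forward_on_empty:
            area_k = prev_area
            logger.warning("empty noon detection at %s; carrying A=%.0f forward",
                           noon.timestamp, prev_area)
        else:
            logger.warning("empty noon detection at %s; A_k set to 0", noon.timestamp)

    # pass 2: every frame of the day with A_k introduced
    d_intra = blue_weight(area_k, params.filter)
    records = []
    for idx, frame in enumerate(day_frames):
        f_img = filter_intraday(frame.pixels, d_intra, params.filter)
        u = float(f_img.mean())
        t = threshold_intraday(u, area_k, season, params.threshold)
        det = _detect(f_img, t, area_k, params)
        ca = math.pi * det.radius ** 2
        records.append({
            "timestamp": frame.timestamp,
            "day": frame.day_index,
            "frame": frame.within_day_index,
            "RA_px": det.area,
            "radius_px": det.radius,
            "CA_px": ca,
            "compactness": det.area / ca if det.area > 0 else np.nan,
            "is_noon": idx == noon_idx,
            "threshold": t,
            "U": u,
            "D": d_intra,
        })
    return area_k, records, noon_result


def run_stack(
    stack: PlantStack,
    season: str,
    params: PipelineParams = PipelineParams(),
) -> tuple[pd.DataFrame, DailyState]:
    """Run the daily loop over a plant stack.

    Returns the trait series (one row per daytime frame, columns
    ``TRAIT_COLUMNS``) and the :class:`DailyState` of noon areas.  Missing
    days are allowed; the noon anchor is the most recent available day's
    area.
    """
    if not stack.frames:
        raise ValueError("stack is empty")
    state = DailyState(day_one_area=params.day_one_area)
    by_day: dict[int, list[StackFrame]] = {}
    for frame in stack.frames:
        by_day.setdefault(frame.day_index, []).append(frame)

    rows: list[dict] = []
    for day in sorted(by_day):
        prev = state.anchor_for(day)
        area_k, records, _ = process_day(by_day[day], prev, season, params)
        state.noon_areas[day] = area_k
        rows.extend(records)
    series = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    return series, state
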