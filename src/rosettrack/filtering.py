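"""Size-weighted color filtering and the dynamic background-threshold model.

Top-view chamber images of Arabidopsis flats have a bright, speckled soil
background (perlite/vermiculite reflections) and blue pot edges that confound
naive green-pixel extraction.  Foreground enhancement therefore uses a linear
color filter whose blue-channel contribution is weighted by rosette size, and
binarization uses a background threshold that is itself a linear model in the
mean filtered intensity (tracking diurnal/seasonal light) and the rosette
area of the focal plant (tracking growth-dependent reflectance).

Two variants exist:

* the *noon* variant, anchored on the previous day's rosette area, used to
  estimate the daily reference area ``A_k``;
* the *intra-day* variant (with a +0.4 additive offset), anchored on the
  current day's noon area, used for every frame of the day.

All intensities are 8-bit channel values divided by 255, i.e. on a common
[0, 1] scale; the printed model constants are interpreted on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FilterParams",
    "ThresholdParams",
    "TrainingFrame",
    "blue_weight",
    "filter_intraday",
    "filter_noon",
    "threshold_intraday",
    "threshold_noon",
    "calibrate_threshold_params",
]

SEASONS = ("spring", "summer")


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the size-weighted color filter.

    Attributes
    ----------
    offset : additive constant of the intra-day filter (the noon filter has
        none).
    blue_weight_base : maximum weight of the red/blue mixture term; the blue
        correction exists because blue pot edges blend into the foreground
        while plants are small, so the weight decays with rosette area.
    reference_area : rosette area (px) at which the blue correction vanishes.
    rb_weights : weights of the red/blue mixture RB = w_r*R + w_b*B.
    """

    offset: float = 0.4
    blue_weight_base: float = 0.35
    reference_area: float = 50_000.0
    rb_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.blue_weight_base <= 1.0:
            raise ValueError("blue_weight_base must lie in [0, 1]")
        if self.reference_area <= 0:
            raise ValueError("reference_area must be positive")
        wr, wb = self.rb_weights
        if wr < 0 or wb < 0 or abs(wr + wb - 1.0) > 1e-9:
            raise ValueError("rb_weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class ThresholdParams:
    """Coefficients of the hierarchical background-threshold model.

    The intra-day threshold is ``T = C_s + c2_intraday*U - c3_intraday*A``
    with a season-dependent intercept ``C_s``; the noon threshold is
    ``T = c1_noon + c2_noon*U - c3_noon*A_prev``.  ``U`` is the mean filtered
    intensity of the frame and ``A`` the relevant rosette-area anchor (px).
    """

    c1_spring: float = 0.335
    c1_summer: float = 0.305
    c2_intraday: float = 0.470
    c3_intraday: float = 0.00000146
    c1_noon: float = 0.12
    c2_noon: float = 0.475
    c3_noon: float = 0.00000130

    def __post_init__(self) -> None:
        vals = (
            self.c1_spring, self.c1_summer, self.c2_intraday,
            self.c3_intraday, self.c1_noon, self.c2_noon, self.c3_noon,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("threshold parameters must be finite")
        if self.c2_intraday <= 0 or self.c2_noon <= 0:
            raise ValueError("c2 coefficients must be positive")
        if self.c3_intraday < 0 or self.c3_noon < 0:
            raise ValueError("c3 coefficients must be nonnegative")

    def c1_for(self, season: str) -> float:
        if season not in SEASONS:
            raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
        return self.c1_spring if season == "spring" else self.c1_summer


def blue_weight(area_anchor: float, params: FilterParams = FilterParams()) -> float:
    """Blue-mixture weight D for a given rosette-area anchor.

    ``D = base * (reference_area - area_anchor) / reference_area`` clamped to
    ``[0, base]``: once the rosette exceeds the reference area the formula
    goes negative, but the blue correction is only needed for small plants,
    so it is clamped to zero there.
    """
    if area_anchor < 0:
        raise ValueError("area_anchor must be nonnegative")
    d = params.blue_weight_base * (params.reference_area - area_anchor) / params.reference_area
    return float(np.clip(d, 0.0, params.blue_weight_base))


def _rb_mixture(img: np.ndarray, params: FilterParams) -> np.ndarray:
    wr, wb = params.rb_weights
    return wr * img[..., 0] + wb * img[..., 2]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    return img


def filter_intraday(img: np.ndarray, D: float, params: FilterParams = FilterParams()) -> np.ndarray:
    """Intra-day color filter ``F = (G-R+c)(1-D) + (G-RB+c)D``.

    ``c`` is ``params.offset`` (default 0.4) and RB the red/blue mixture.
    Output is not clipped; thresholds operate on the raw affine scale.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError("D must lie in [0, 1]")
    img = _check_rgb(img)
    g, r = img[..., 1], img[..., 0]
    rb = _rb_mixture(img, params)
    c = params.offset
    return (g - r + c) * (1.0 - D) + (g - rb + c) * D


def filter_noon(img: np.ndarray, D: float, params: FilterParams = FilterParams()) -> np.ndarray:
    """Noon color filter: like :func:`filter_intraday` but with no offset."""
    return filter_intraday(img, D, replace(params, offset=0.0))


def threshold_intraday(
    U: float,
    area_anchor: float,
    season: str,
    params: ThresholdParams = ThresholdParams(),
) -> float:
    """Intra-day background threshold ``T = C_s + c2*U - c3*A``."""
    return float(params.c1_for(season) + params.c2_intraday * U - params.c3_intraday * area_anchor)


def threshold_noon(
    U: float,
    prev_area: float,
    params: ThresholdParams = ThresholdParams(),
) -> float:
    """Noon background threshold ``T = c1 + c2*U - c3*A_prev``."""
    if prev_area < 0:
        raise ValueError("prev_area must be nonnegative")
    return float(params.c1_noon + params.c2_noon * U - params.c3_noon * prev_area)


# ---------------------------------------------------------------------------
# Threshold-parameter calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingFrame:
    """One calibration frame: a filtered image with its ground-truth mask.

    ``filtered`` is the already color-filtered intensity image F; ``U`` its
    mean; ``area_anchor`` the rosette-area anchor entering the threshold
    model; ``season`` selects the C1 intercept.
    """

    filtered: np.ndarray
    truth_mask: np.ndarray
    U: float
    area_anchor: float
    season: str = "spring"


def _disagreement(frames: Sequence[TrainingFrame], c1: Mapping[str, float],
                  c2: float, c3: float) -> float:
    """Mean per-frame (symmetric difference / truth area) of the threshold masks."""
    scores = []
    for fr in frames:
        t = c1[fr.season] + c2 * fr.U - c3 * fr.area_anchor
        pred = fr.filtered >= t
        truth = fr.truth_mask.astype(bool)
        denom = max(int(truth.sum()), 1)
        scores.append(float(np.logical_xor(pred, truth).sum()) / denom)
    return float(np.mean(scores))


def calibrate_threshold_params(
    training: Sequence[TrainingFrame],
    grid: Mapping[str, Iterable[float]],
    params: ThresholdParams = ThresholdParams(),
    early_fraction: float = 0.25,
    max_sweeps: int = 5,
) -> tuple[ThresholdParams, dict]:
    """Staged grid search for the intra-day threshold coefficients.

    Mirrors the original estimation procedure, made quantitative: the
    intercept C1 is fit on early-stage frames (smallest area anchors, where
    the growth term is negligible and fore/background separation is sharp);
    the area coefficient C3 is then probed with C1 fixed; finally the light
    coefficient C2 with C1 and C3 fixed.  The stages are swept until the
    parameters stop changing.  The objective is the mean pixel-wise symmetric
    difference between the threshold mask and the truth mask, normalized by
    truth area; ties take the first-best point in grid order.

    ``grid`` maps ``"c1"``, ``"c2"``, ``"c3"`` to candidate values.  Seasons
    present in the training set each get their own C1 fit.  Returns the
    calibrated :class:`ThresholdParams` (other fields copied from ``params``)
    plus a report dict with the achieved disagreement.
    """
    if not training:
        raise ValueError("training set is empty")
    for key in ("c1", "c2", "c3"):
        if key not in grid or len(list(grid[key])) == 0:
            raise ValueError(f"grid must provide non-empty candidate list for {key!r}")
    c1_grid = [float(v) for v in grid["c1"]]
    c2_grid = [float(v) for v in grid["c2"]]
    c3_grid = [float(v) for v in grid["c3"]]

    seasons = sorted({fr.season for fr in training})
    for s in seasons:
        if s not in SEASONS:
            raise ValueError(f"unknown season {s!r} in training set")

    anchors = np.array([fr.area_anchor for fr in training])
    cutoff = np.quantile(anchors, early_fraction)
    early = [fr for fr in training if fr.area_anchor <= cutoff] or list(training)

    # start from grid midpoints (deterministic)
    c1 = {s: c1_grid[len(c1_grid) // 2] for s in seasons}
    c2 = c2_grid[len(c2_grid) // 2]
    c3 = c3_grid[len(c3_grid) // 2]

    history = []
    for sweep in range(max_sweeps):
        prev = (dict(c1), c2, c3)
        # stage 1: C1 per season on early frames
        for s in seasons:
            sub = [fr for fr in early if fr.season == s] or [fr for fr in training if fr.season == s]
            best = min(
                ((cand, _disagreement(sub, {**c1, s: cand}, c2, c3)) for cand in c1_grid),
                key=lambda t: t[1],
            )
            c1[s] = best[0]
        # stage 2: C3 with C1 fixed
        c3 = min(((cand, _disagreement(training, c1, c2, cand)) for cand in c3_grid),
                 key=lambda t: t[1])[0]
        # stage 3: C2 with C1, C3 fixed
        c2 = min(((cand, _disagreement(training, c1, cand, c3)) for cand in c2_grid),
                 key=lambda t: t[1])[0]
        score = _disagreement(training, c1, c2, c3)
        history.append({"sweep": sweep + 1, "c1": dict(c1), "c2": c2, "c3": c3,
                        "disagreement": score})
        if (dict(c1), c2, c3) == prev:
            break

    fitted = replace(
        params,
        c1_spring=c1.get("spring", params.c1_spring),
        c1_summer=c1.get("summer", params.c1_summer),
        c2_intraday=c2,
        c3_intraday=c3,
    )
    report = {
        "disagreement": history[-1]["disagreement"],
        "n_sweeps": len(history),
        "history": history,
        "n_training_frames": len(training),
        "n_early_frames": len(early),
    }
    return fitted, report
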