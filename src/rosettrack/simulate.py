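"""Synthetic flat imagery with ground truth.

Renders time-lapse top-view image series of a pot flat that emulate the
growth-chamber scenes the detection model was built for: bright speckled soil
(perlite/vermiculite reflections) whose green and red channels are nearly
equal, blue pot edges, green rosettes drawn as unions of rotated elliptical
leaves whose count and size grow along a logistic area curve, a diurnal
brightness schedule peaking at midday, dim green-shifted night frames (green
LED illumination), and a seasonal brightness offset.  Every frame comes with
per-plant truth masks, areas and radii; every plant with true stage-anchor
times, genotype and growth parameters, so each pipeline stage can be checked
against truth without any real imagery.

Growth variation is genotype-structured: per-plant logistic rates are
``base_rate + g + e`` with genotype effects g ~ N(0, sigma2_G) and plant
residuals e ~ N(0, sigma2_E), sigma2_G/(sigma2_G + sigma2_E) equal to the
target broad-sense heritability.  Leaf initiation speed scales with the rate,
so developmental stage times vary accordingly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .segmentation import mask_radius

__all__ = [
    "SceneSpec",
    "GrowthModel",
    "GroundTruth",
    "logistic_area",
    "simulate_phenotypes",
    "render_series",
]

GOLDEN_ANGLE = math.radians(137.508)


@dataclass
class SceneSpec:
    """Scene geometry, textures and light schedule of a simulated flat."""

    rows: int = 6
    cols: int = 6
    pot_px: int = 256
    flat_id: str = "flat01"
    season: str = "spring"
    start: datetime = field(default_factory=lambda: datetime(2021, 4, 1))
    n_days: int = 10
    day_start_hour: float = 8.0
    day_end_hour: float = 18.0
    frame_interval_min: int = 20
    night_hours: tuple[float, ...] = (20.0, 23.0)
    # textures (full-brightness base colors on [0,1])
    soil_rgb: tuple[float, float, float] = (0.52, 0.60, 0.46)
    speckle_rgb: tuple[float, float, float] = (0.92, 0.96, 0.88)
    speckle_density: float = 0.05
    dark_patch_rgb: tuple[float, float, float] = (0.30, 0.34, 0.28)
    dark_patch_density: float = 0.002
    plant_rgb: tuple[float, float, float] = (0.20, 0.55, 0.16)
    pot_edge_rgb: tuple[float, float, float] = (0.25, 0.35, 0.75)
    pot_edge_width: int = 3
    texture_noise: float = 0.015
    frame_noise: float = 0.008
    # light schedule
    brightness_floor: float = 0.7
    season_brightness: dict = field(default_factory=lambda: {"spring": 1.0, "summer": 1.08})
    night_tint: tuple[float, float, float] = (0.6, 1.0, 0.7)
    night_brightness: float = 0.06
    jpeg_quality: int = 95

    def __post_init__(self) -> None:
        if self.night_brightness <= 0 or self.brightness_floor <= 0:
            raise ValueError("brightness multipliers must be positive")
        day_minutes = (self.day_end_hour - self.day_start_hour) * 60
        if day_minutes <= 0 or abs(day_minutes % self.frame_interval_min) > 1e-9:
            raise ValueError("frame interval must divide the daytime window")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rows * self.pot_px, self.cols * self.pot_px

    def brightness(self, hour: float) -> float:
        span = self.day_end_hour - self.day_start_hour
        rel = (hour - self.day_start_hour) / span
        b = self.brightness_floor + (1.0 - self.brightness_floor) * math.sin(math.pi * rel)
        return b * self.season_brightness[self.season]


@dataclass
class GrowthModel:
    """Population of per-plant logistic growth curves with genetic structure."""

    plants: pd.DataFrame  # plant_id, genotype, rate, init_area, asymptote, leaf_rate
    h2_target: float
    sigma2_g: float
    sigma2_e: float
    seed: int

    def area_at(self, plant_row, t_days: float) -> float:
        return logistic_area(t_days, plant_row.init_area, plant_row.asymptote, plant_row.rate)


@dataclass
class GroundTruth:
    """Per-frame per-plant truth plus per-plant annotations."""

    areas: pd.DataFrame  # plant_id, filename, timestamp, day, true_area, true_radius
    stages: pd.DataFrame  # plant_id, t_104, t_110
    genotypes: pd.DataFrame  # plant_id, accession, environment
    frames: pd.DataFrame  # filename, timestamp, is_day, brightness
    masks: dict  # (plant_id, filename) -> bool crop mask (day frames)


def logistic_area(t_days: float, init_area: float, asymptote: float, rate: float) -> float:
    """Logistic rosette-area curve A(t) = K / (1 + (K/A0 - 1) exp(-r t))."""
    return asymptote / (1.0 + (asymptote / init_area - 1.0) * math.exp(-rate * t_days))


def simulate_phenotypes(
    n_geno: int,
    n_rep: int,
    h2_target: float,
    seed: int,
    base_rate: float = 0.75,
    total_sd: float = 0.06,
    init_area: float = 150.0,
    asymptote: float = 30_000.0,
    leaf_rate_base: float = 1.3,
    initial_leaves: float = 2.0,
) -> tuple[GrowthModel, pd.DataFrame]:
    """Draw a plant population with a target broad-sense heritability.

    Genotype effects on the logistic rate are N(0, sigma2_G) and plant
    residuals N(0, sigma2_E) with sigma2_G/(sigma2_G + sigma2_E) =
    ``h2_target`` and total variance ``total_sd**2``.  Leaf initiation speed
    scales with the rate (faster genotypes stage earlier).  Returns the
    population and an expected-trait table (true rate, area at a reference
    day, stage-crossing times in days) for oracle comparisons.
    """
    if not 0.0 <= h2_target <= 1.0:
        raise ValueError("h2_target must lie in [0, 1]")
    if n_geno < 1 or n_rep < 1:
        raise ValueError("need at least one genotype and one replicate")
    rng = np.random.default_rng(seed)
    sigma2_g = h2_target * total_sd ** 2
    sigma2_e = (1.0 - h2_target) * total_sd ** 2
    g_eff = rng.normal(0.0, math.sqrt(sigma2_g), n_geno) if sigma2_g > 0 else np.zeros(n_geno)
    e_eff = rng.normal(0.0, math.sqrt(sigma2_e), n_geno * n_rep) if sigma2_e > 0 else np.zeros(n_geno * n_rep)

    rows = []
    for gi in range(n_geno):
        for ri in range(n_rep):
            rate = base_rate + g_eff[gi] + e_eff[gi * n_rep + ri]
            rate = max(rate, 0.05 * base_rate)
            leaf_rate = leaf_rate_base * rate / base_rate
            rows.append({
                "plant_id": f"acc{gi:02d}_r{ri:02d}",
                "genotype": f"acc{gi:02d}",
                "rate": rate,
                "init_area": init_area,
                "asymptote": asymptote,
                "leaf_rate": leaf_rate,
                "initial_leaves": initial_leaves,
            })
    plants = pd.DataFrame(rows)
    model = GrowthModel(plants=plants, h2_target=h2_target,
                        sigma2_g=sigma2_g, sigma2_e=sigma2_e, seed=seed)

    ref_day = 7.0
    expected = plants[["plant_id", "genotype", "rate"]].copy()
    expected["area_ref_day"] = [
        logistic_area(ref_day, r.init_area, r.asymptote, r.rate)
        for r in plants.itertuples()
    ]
    expected["t104_days"] = (4.0 - initial_leaves) / plants["leaf_rate"]
    expected["t110_days"] = (10.0 - initial_leaves) / plants["leaf_rate"]
    return model, expected


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fill_ellipse(mask: np.ndarray, cy: float, cx: float, a: float, b: float,
                  theta: float) -> None:
    """Rasterize a filled rotated ellipse (semi-axes a along theta, b across)."""
    h, w = mask.shape
    r_ext = max(a, b) + 1
    r0, r1 = max(int(cy - r_ext), 0), min(int(cy + r_ext) + 2, h)
    c0, c1 = max(int(cx - r_ext), 0), min(int(cx + r_ext) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask[r0:r1, c0:c1] |= inside


def _rosette_mask(shape: tuple[int, int], cy: float, cx: float, target_area: float,
                  n_leaves: int, leaf_jitter: np.ndarray) -> np.ndarray:
    """Union of rotated elliptical leaves around (cy, cx), scaled to the
    target pixel area (exact geometric scaling; one correction pass)."""
    mask = np.zeros(shape, dtype=bool)
    if target_area < 1 or n_leaves < 1:
        return mask

    def render(tip_len: float) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        for i in range(n_leaves):
            theta = i * GOLDEN_ANGLE + leaf_jitter[i % leaf_jitter.size]
            rel = 0.35 + 0.65 * (n_leaves - i) / n_leaves  # older leaves longer
            length = tip_len * rel
            a = length / 2.0
            b = max(0.225 * length, 0.8)
            ecy = cy + a * math.sin(theta)
            ecx = cx + a * math.cos(theta)
            _fill_ellipse(m, ecy, ecx, max(a, 0.8), b, theta)
        return m

    tip = max(2.0, 1.6 * math.sqrt(target_area))
    for _ in range(3):
        m = render(tip)
        area = m.sum()
        if area == 0:
            tip *= 1.5
            continue
        if abs(area - target_area) / target_area < 0.02:
            return m
        tip *= math.sqrt(target_area / area)
    return render(tip)


def _static_scene(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Soil texture and pot edges at full brightness (no plants)."""
    h, w = spec.shape
    scene = np.empty((h, w, 3), dtype=np.float32)
    scene[:] = spec.soil_rgb
    scene += rng.normal(0.0, spec.texture_noise, (h, w, 1)).astype(np.float32)
    # perlite speckles: bright near-white grains with G ~ R (filtered away)
    speckle = rng.random((h, w)) < spec.speckle_density
    scene[speckle] = spec.speckle_rgb
    # vermiculite: darker patches
    n_patches = int(spec.dark_patch_density * h * w / 20)
    for _ in range(n_patches):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        rad = rng.integers(2, 6)
        patch = np.zeros((h, w), dtype=bool)
        _fill_ellipse(patch, cy, cx, rad, rad, 0.0)
        scene[patch] = spec.dark_patch_rgb
    # blue pot edges on the pot grid
    ew = spec.pot_edge_width
    for r in range(spec.rows + 1):
        y = min(r * spec.pot_px, h - 1)
        scene[max(y - ew // 2, 0): y + ew // 2 + 1, :] = spec.pot_edge_rgb
    for c in range(spec.cols + 1):
        x = min(c * spec.pot_px, w - 1)
        scene[:, max(x - ew // 2, 0): x + ew // 2 + 1] = spec.pot_edge_rgb
    return np.clip(scene, 0.0, 1.0)


def _timestamps(spec: SceneSpec) -> list[tuple[datetime, bool]]:
    out = []
    for d in range(spec.n_days):
        day0 = spec.start + timedelta(days=d)
        minutes = spec.day_start_hour * 60
        end = spec.day_end_hour * 60
        while minutes <= end + 1e-9:
            out.append((day0 + timedelta(minutes=minutes), True))
            minutes += spec.frame_interval_min
        for hr in spec.night_hours:
            out.append((day0 + timedelta(hours=hr), False))
    out.sort(key=lambda e: e[0])
    return out


def render_series(
    spec: SceneSpec,
    growth: GrowthModel,
    seed: int,
    out_dir: str | Path | None = None,
    store_masks: bool = True,
    write_masks: bool = False,
) -> GroundTruth:
    """Render the image series for a scene and return its ground truth.

    Plants fill pots row-major in the order of ``growth.plants`` (at most
    rows*cols).  If ``out_dir`` is given, writes ``images/*.jpg``,
    ``coords.csv``, and ``truth/`` CSVs (areas, stages, genotypes), directly
    consumable by the preprocessing stage; truth masks are returned in memory
    (day frames) and optionally written as PNG.  Fully deterministic given
    the seed.
    """
    n_pots = spec.rows * spec.cols
    plants = growth.plants
    if len(plants) > n_pots:
        raise ValueError(f"{len(plants)} plants do not fit {n_pots} pots")
    rng = np.random.default_rng(seed)
    scene = _static_scene(spec, rng)
    h, w = spec.shape

    # fixed per-plant leaf-angle jitters (leaf identity stable across frames)
    jitters = {row.plant_id: rng.normal(0.0, math.radians(8.0), 24) for row in plants.itertuples()}
    pots = []
    for idx, row in enumerate(plants.itertuples()):
        pr, pc = divmod(idx, spec.cols)
        cy = (pr + 0.5) * spec.pot_px
        cx = (pc + 0.5) * spec.pot_px
        pots.append({"plant_id": row.plant_id, "pot_id": f"r{pr}c{pc}",
                     "cy": cy, "cx": cx, "row": row})

    timestamps = _timestamps(spec)
    frame_rows, area_rows, masks = [], [], {}
    overflow: list[str] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "truth").mkdir(parents=True, exist_ok=True)
        if write_masks:
            (out_dir / "truth" / "masks").mkdir(parents=True, exist_ok=True)

    half = spec.pot_px / 2.0
    for fi, (ts, is_day) in enumerate(timestamps):
        t_days = (ts - spec.start).total_seconds() / 86400.0
        img = scene.copy()
        fname = f"{spec.flat_id}_{ts:%Y%m%d-%H%M%S}.jpg"
        frng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + fi]))
        for pot in pots:
            row = pot["row"]
            target = logistic_area(t_days, row.init_area, row.asymptote, row.rate)
            n_leaves = int(row.initial_leaves + row.leaf_rate * t_days)
            pmask = _rosette_mask((h, w), pot["cy"], pot["cx"], target,
                                  max(n_leaves, 1), jitters[pot["plant_id"]])
            npix = int(pmask.sum())
            if npix:
                img[pmask] = np.clip(
                    np.asarray(spec.plant_rgb)
                    + frng.normal(0.0, 0.02, (npix, 3)), 0.0, 1.0)
            if is_day:
                r0, r1 = int(pot["cy"] - half), int(pot["cy"] + half)
                c0, c1 = int(pot["cx"] - half), int(pot["cx"] + half)
                crop_mask = pmask[r0:r1, c0:c1]
                if npix and crop_mask.sum() < npix:
                    overflow.append(f"{pot['plant_id']}@day{int(t_days) + 1}")
                radius, _ = mask_radius(crop_mask)
                area_rows.append({
                    "plant_id": pot["plant_id"], "pot_id": pot["pot_id"],
                    "filename": fname, "timestamp": ts, "day": int(t_days) + 1,
                    "true_area": int(crop_mask.sum()), "true_radius": radius,
                })
                if store_masks:
                    masks[(pot["plant_id"], fname)] = crop_mask
                if write_masks and out_dir is not None:
                    Image.fromarray((crop_mask * 255).astype(np.uint8)).save(
                        out_dir / "truth" / "masks" / f"{pot['plant_id']}_{ts:%Y%m%d-%H%M%S}.png")

        if is_day:
            hour = ts.hour + ts.minute / 60.0
            b = spec.brightness(hour)
            img = img * b
        else:
            b = spec.night_brightness
            img = img * np.asarray(spec.night_tint, dtype=np.float32) * b
        img += frng.normal(0.0, spec.frame_noise, img.shape).astype(np.float32)
        arr = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
        frame_rows.append({"filename": fname, "timestamp": ts, "is_day": is_day,
                           "brightness": b})
        if out_dir is not None:
            Image.fromarray(arr).save(out_dir / "images" / fname,
                                      quality=spec.jpeg_quality, subsampling=0)

    if overflow:
        warnings.warn("plants overflow their crop boxes: " + ", ".join(sorted(set(overflow))))

    # per-plant stage anchors from the leaf schedule: T1.04 = start of the day
    # the 4th leaf appears, T1.10 = end of the day the 10th leaf appears
    stage_rows, geno_rows = [], []
    for pot in pots:
        row = pot["row"]
        t4 = (4.0 - row.initial_leaves) / row.leaf_rate
        t10 = (10.0 - row.initial_leaves) / row.leaf_rate
        day4 = spec.start + timedelta(days=math.floor(t4))
        day10 = spec.start + timedelta(days=math.floor(t10) + 1)
        stage_rows.append({"plant_id": pot["plant_id"], "t_104": day4, "t_110": day10})
        geno_rows.append({"plant_id": pot["plant_id"], "pot_id": pot["pot_id"],
                          "accession": row.genotype, "environment": spec.season})

    truth = GroundTruth(
        areas=pd.DataFrame(area_rows),
        stages=pd.DataFrame(stage_rows),
        genotypes=pd.DataFrame(geno_rows),
        frames=pd.DataFrame(frame_rows),
        masks=masks,
    )

    if out_dir is not None:
        coords = pd.DataFrame([
            {"flat_id": spec.flat_id, "valid_from": spec.start.isoformat(),
             "pot_id": pot["pot_id"], "center_x": pot["cx"], "center_y": pot["cy"],
             "crop_w": spec.pot_px, "crop_h": spec.pot_px,
             "accession": pot["row"].genotype}
            for pot in pots
        ])
        coords.to_csv(out_dir / "coords.csv", index=False)
        truth.areas.to_csv(out_dir / "truth" / "areas.csv", index=False)
        stages = truth.stages.copy()
        stages["t_104"] = stages["t_104"].map(lambda t: t.isoformat())
        stages["t_110"] = stages["t_110"].map(lambda t: t.isoformat())
        stages.to_csv(out_dir / "truth" / "stages.csv", index=False)
        truth.genotypes.to_csv(out_dir / "truth" / "genotypes.csv", index=False)
        truth.frames.to_csv(out_dir / "truth" / "frames.csv", index=False)
    return truth
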