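"""Shared fixtures: small rendered scenes and hand-built frames."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from rosettrack.image_io import PlantStack, StackFrame
from rosettrack.simulate import SceneSpec, render_series, simulate_phenotypes

SOIL = (0.52, 0.60, 0.46)
PLANT = (0.20, 0.55, 0.16)


def make_frame(shape=(128, 128), disk=None, soil=SOIL, plant=PLANT,
               brightness=1.0, rng=None):
    """A crop-like RGB frame: soil background, optional (cy, cx, r) plant disk.

    Returns (pixels, truth_mask).
    """
    h, w = shape
    img = np.empty((h, w, 3), dtype=float)
    img[:] = soil
    if rng is not None:
        img += rng.normal(0.0, 0.01, (h, w, 1))
    mask = np.zeros((h, w), dtype=bool)
    if disk is not None:
        cy, cx, r = disk
        yy, xx = np.ogrid[:h, :w]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        img[mask] = plant
    img = np.clip(img * brightness, 0.0, 1.0)
    return img, mask


def make_stack(day_radii, shape=(128, 128), frames_per_day=3, pot_id="p1",
               accession="acc", start=datetime(2021, 4, 1), seed=0):
    """A plant stack of disk rosettes with per-day radii (None = no plant)."""
    rng = np.random.default_rng(seed)
    frames = []
    for k, r in enumerate(day_radii):
        for j in range(frames_per_day):
            ts = start + timedelta(days=k, hours=10 + 2 * j)
            brightness = 0.85 + 0.15 * (j == frames_per_day // 2)  # noon peak
            disk = (shape[0] // 2, shape[1] // 2, r) if r else None
            pixels, _ = make_frame(shape, disk, brightness=brightness, rng=rng)
            frames.append(StackFrame(timestamp=ts, pixels=pixels,
                                     day_index=k + 1, within_day_index=j + 1))
    return PlantStack(accession=accession, pot_id=pot_id, frames=frames)


@pytest.fixture(scope="session")
def small_scene(tmp_path_factory):
    """A rendered 3x3-pot, 6-day scene with ground truth, written to disk."""
    out = tmp_path_factory.mktemp("scene")
    model, expected = simulate_phenotypes(
        3, 3, h2_target=0.8, seed=11, asymptote=12000.0, base_rate=0.9,
        leaf_rate_base=1.6,
    )
    spec = SceneSpec(rows=3, cols=3, pot_px=192, n_days=6, frame_interval_min=120)
    truth = render_series(spec, model, seed=11, out_dir=out)
    return {"dir": out, "spec": spec, "model": model, "expected": expected,
            "truth": truth}
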