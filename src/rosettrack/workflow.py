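"""Stage orchestration: simulate -> preprocess -> detect -> normalize -> genetics.

Each stage reads its inputs from a base directory, writes its outputs there,
and records a manifest entry (an identity hash over the relevant config
sections and the upstream outputs, plus the produced files).  Re-running
skips stages whose identity hash is unchanged and whose outputs exist, unless
forced; changing a parameter re-runs only the stages downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import image_io, simulate as sim
from .config import RunConfig
from .devtime import (
    StageAnnotation,
    assemble_phenotype_table,
    fit_growth_curve,
    read_stage_annotations,
)
from .genetics import h2_trajectory, trait_correlation
from .image_io import PlantStack, StackFrame
from .traits import PipelineParams, run_stack

__all__ = ["STAGES", "run_pipeline", "load_stacks", "write_stacks"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "detect", "normalize", "genetics"]
STAGE_ALIASES = {"traits": "detect"}  # detection and trait extraction are one loop


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _outputs_of(entry: dict, base: Path) -> bool:
    return all((base / rel).exists() for rel in entry.get("outputs", []))


class _Manifest:
    def __init__(self, base: Path):
        self.path = base / "manifest.json"
        self.base = base
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def should_skip(self, stage: str, identity: str, force: bool) -> bool:
        entry = self.data.get(stage)
        return (not force and entry is not None and entry.get("identity") == identity
                and _outputs_of(entry, self.base))

    def record(self, stage: str, identity: str, outputs: list[Path]) -> None:
        rels = [str(p.relative_to(self.base)) for p in outputs]
        self.data[stage] = {
            "identity": identity,
            "outputs": rels,
            "out_hash": _hash_files(outputs),
            "recorded": datetime.now().isoformat(timespec="seconds"),
        }
        self.path.write_text(json.dumps(self.data, indent=2))

    def out_hash(self, stage: str) -> str:
        entry = self.data.get(stage)
        return entry["out_hash"] if entry else ""


# ---------------------------------------------------------------------------
# stack (de)serialization
# ---------------------------------------------------------------------------

def write_stacks(stacks: list[PlantStack], out_dir: Path) -> list[Path]:
    """Write per-plant stack directories of PNG crops plus a manifest CSV."""
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, written = [], []
    for stack in stacks:
        sdir = out_dir / stack.pot_id
        sdir.mkdir(exist_ok=True)
        for fr in stack.frames:
            name = f"{fr.timestamp:%Y%m%d-%H%M%S}.png"
            arr = (np.clip(fr.pixels, 0, 1) * 255.0).round().astype(np.uint8)
            Image.fromarray(arr).save(sdir / name)
            written.append(sdir / name)
            rows.append({"pot_id": stack.pot_id, "accession": stack.accession,
                         "filename": f"{stack.pot_id}/{name}",
                         "timestamp": fr.timestamp.isoformat(),
                         "day": fr.day_index, "frame": fr.within_day_index})
    manifest = out_dir / "stacks_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    written.append(manifest)
    return written


def load_stacks(stacks_dir: Path) -> list[PlantStack]:
    df = pd.read_csv(stacks_dir / "stacks_manifest.csv")
    stacks = []
    for (pot_id, accession), sub in df.groupby(["pot_id", "accession"], sort=True):
        frames = []
        for row in sub.sort_values("timestamp").itertuples():
            arr = np.asarray(Image.open(stacks_dir / row.filename), dtype=float) / 255.0
            frames.append(StackFrame(timestamp=datetime.fromisoformat(row.timestamp),
                                     pixels=arr, day_index=int(row.day),
                                     within_day_index=int(row.frame)))
        stacks.append(PlantStack(accession=str(accession), pot_id=str(pot_id), frames=frames))
    return stacks


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, base: Path) -> list[Path]:
    s = cfg["simulate"]
    model, _ = sim.simulate_phenotypes(
        n_geno=s["n_geno"], n_rep=s["n_rep"], h2_target=s["h2_target"],
        seed=cfg["run"]["seed"], base_rate=s["base_rate"],
        asymptote=s["asymptote"], leaf_rate_base=s["leaf_rate_base"],
    )
    spec = sim.SceneSpec(
        rows=s["rows"], cols=s["cols"], pot_px=s["pot_px"], n_days=s["n_days"],
        day_start_hour=s["day_start_hour"], day_end_hour=s["day_end_hour"],
        frame_interval_min=s["frame_interval_min"], season=s["season"],
        start=datetime.fromisoformat(s["start"]),
    )
    out = base / "sim"
    sim.render_series(spec, model, seed=cfg["run"]["seed"], out_dir=out, store_masks=False)
    return sorted((out / "images").iterdir()) + [
        out / "coords.csv", out / "truth" / "areas.csv", out / "truth" / "stages.csv",
        out / "truth" / "genotypes.csv", out / "truth" / "frames.csv",
    ]


def _stage_preprocess(cfg: RunConfig, base: Path) -> list[Path]:
    io_cfg = cfg["io"]
    image_dir = base / "sim" / "images"
    coords = base / "sim" / "coords.csv"
    names = sorted(p.name for p in image_dir.iterdir())
    times = [image_io.parse_timestamp(image_dir / n) for n in names]
    start = (datetime.fromisoformat(io_cfg["window_start"]) if io_cfg["window_start"]
             else min(times))
    end = (datetime.fromisoformat(io_cfg["window_end"]) if io_cfg["window_end"]
           else max(times))
    index = image_io.build_flat_index(image_dir, start, end)
    values = [image_io.mean_filtered_intensity(
        image_io.load_flat_image(image_dir / name, t)) for name, t in index]
    cutoff = (float(io_cfg["cutoff"]) if io_cfg["cutoff"]
              else image_io.suggest_cutoff(values))
    labels = image_io.classify_day_night(list(zip([t for _, t in index], values)), cutoff)
    maps = image_io.read_coordinate_maps(coords)
    stacks = image_io.crop_to_stacks(index, maps, labels, image_dir, season=io_cfg["season"])
    return write_stacks(stacks, base / "stacks")


def _pipeline_params(cfg: RunConfig) -> PipelineParams:
    return PipelineParams(
        filter=cfg.filter_params(),
        threshold=cfg.threshold_params(),
        segmentation=cfg.segmentation_params(),
        day_one_area=cfg["segmentation"]["day_one_area"],
    )


def _stage_detect(cfg: RunConfig, base: Path) -> list[Path]:
    stacks = load_stacks(base / "stacks")
    params = _pipeline_params(cfg)
    out = base / "traits"
    out.mkdir(exist_ok=True)
    written = []
    for stack in stacks:
        series, _ = run_stack(stack, cfg["io"]["season"], params)
        path = out / f"{stack.pot_id}.csv"
        series.to_csv(path, index=False)
        written.append(path)
    return written


def _stage_normalize(cfg: RunConfig, base: Path) -> list[Path]:
    anns = read_stage_annotations(base / "sim" / "truth" / "stages.csv")
    geno = pd.read_csv(base / "sim" / "truth" / "genotypes.csv")
    meta = {str(r.pot_id): {"accession": r.accession, "environment": r.environment}
            for r in geno.itertuples()}
    pot_to_plant = {str(r.pot_id): str(r.plant_id) for r in geno.itertuples()}
    grid_size = cfg["devtime"]["grid_size"]
    curves = []
    for path in sorted((base / "traits").glob("*.csv")):
        pot_id = path.stem
        df = pd.read_csv(path, parse_dates=["timestamp"])
        noon = df[df["is_noon"]]
        ann = anns[pot_to_plant[pot_id]]
        ann = StageAnnotation(plant_id=pot_id, t_104=ann.t_104, t_110=ann.t_110)
        times = list(noon["timestamp"])
        for trait, col in (("RA", "RA_px"), ("CA", "CA_px"), ("compactness", "compactness")):
            curves.append(fit_growth_curve(times, noon[col].to_numpy(), ann,
                                           trait=trait, grid_size=grid_size,
                                           method=cfg["devtime"]["spline"]))
    table = assemble_phenotype_table(curves, meta)
    path = base / "phenotypes.csv"
    table.to_csv(path, index=False)
    return [path]


def _stage_genetics(cfg: RunConfig, base: Path) -> list[Path]:
    table = pd.read_csv(base / "phenotypes.csv")
    out = base / "genetics"
    out.mkdir(exist_ok=True)
    written = []
    summaries = {}
    for trait in cfg["genetics"]["traits"].split(","):
        trait = trait.strip()
        estimates, summary = h2_trajectory(table, trait)
        df = pd.DataFrame([{"grid_point": e.grid_point, "sigma2_g": e.sigma2_g,
                            "sigma2_e": e.sigma2_e, "h2": e.h2} for e in estimates])
        path = out / f"h2_{trait}.csv"
        df.to_csv(path, index=False)
        written.append(path)
        summaries[trait] = summary
    corr, corr_summary = trait_correlation(table, "RA", "CA")
    corr_path = out / "correlation_RA_CA.csv"
    corr.to_csv(corr_path, index=False)
    written.append(corr_path)
    summaries["RA_CA_correlation"] = corr_summary
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summaries, indent=2))
    written.append(summary_path)
    return written


_STAGE_FUNCS = {
    "simulate": (_stage_simulate, ("simulate", "run")),
    "preprocess": (_stage_preprocess, ("io",)),
    "detect": (_stage_detect, ("filter", "threshold", "segmentation", "io")),
    "normalize": (_stage_normalize, ("devtime",)),
    "genetics": (_stage_genetics, ("genetics",)),
}
_UPSTREAM = {"simulate": None, "preprocess": "simulate", "detect": "preprocess",
             "normalize": "detect", "genetics": "normalize"}


def run_pipeline(
    cfg: RunConfig,
    stages: list[str],
    base_dir: str | Path,
    force: bool = False,
) -> dict[str, str]:
    """Execute the requested stages in canonical order with manifest skipping.

    Returns a stage -> status map ('run' | 'skipped').  Missing inputs raise
    a named error before any output of the failing stage is touched.
    """
    base = Path(base_dir)
    base.mkdir(parents=True, exist_ok=True)
    requested = {STAGE_ALIASES.get(s, s) for s in stages}
    unknown = requested - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = _Manifest(base)
    status: dict[str, str] = {}
    for stage in STAGES:
        if stage not in requested:
            continue
        func, sections = _STAGE_FUNCS[stage]
        upstream = _UPSTREAM[stage]
        identity = hashlib.sha256(
            (cfg.section_hash(*sections) + manifest.out_hash(upstream) if upstream
             else cfg.section_hash(*sections)).encode()
        ).hexdigest()
        if manifest.should_skip(stage, identity, force):
            logger.info("stage %s up to date; skipped", stage)
            status[stage] = "skipped"
            continue
        logger.info("running stage %s", stage)
        outputs = func(cfg, base)
        manifest.record(stage, identity, outputs)
        status[stage] = "run"
    return status
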