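"""Run configuration: plain-text key-value file with sections.

Every tunable of the pipeline is surfaced here with the model's published
constants as defaults — nothing is hard-coded in the stages.  Unknown
sections or keys are rejected so a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

from .filtering import FilterParams, ThresholdParams
from .segmentation import SegmentationParams

__all__ = ["DEFAULTS", "RunConfig", "load_config", "default_config"]

DEFAULTS: dict[str, dict] = {
    "run": {"seed": 0, "log_level": "INFO"},
    "io": {
        "season": "spring",
        "window_start": "",   # empty = span of available frames
        "window_end": "",
        "cutoff": "",         # empty = Otsu-style suggestion
    },
    "filter": {
        "offset": 0.4,
        "blue_weight_base": 0.35,
        "reference_area": 50000.0,
        "rb_weight_red": 0.5,
        "rb_weight_blue": 0.5,
    },
    "threshold": {
        "c1_spring": 0.335,
        "c1_summer": 0.305,
        "c2_intraday": 0.470,
        "c3_intraday": 0.00000146,
        "c1_noon": 0.12,
        "c2_noon": 0.475,
        "c3_noon": 0.00000130,
    },
    "segmentation": {
        "watershed_tolerance": 1.0,
        "watershed_extension": 3,
        "n_small": 30,
        "n_large": 60,
        "area_switch": 20000.0,
        "ratio_min": 1.5,
        "radius_padding": 0.5,
        "day_one_area": 1000.0,
    },
    "devtime": {"grid_size": 101, "spline": "smoothing"},
    "genetics": {"traits": "RA,CA,compactness"},
    "simulate": {
        "rows": 3,
        "cols": 3,
        "pot_px": 192,
        "n_days": 6,
        "day_start_hour": 8.0,
        "day_end_hour": 18.0,
        "frame_interval_min": 60,
        "n_geno": 3,
        "n_rep": 3,
        "h2_target": 0.8,
        "season": "spring",
        "start": "2021-04-01T00:00:00",
        "asymptote": 12000.0,
        "base_rate": 0.9,
        "leaf_rate_base": 1.6,
    },
}


class RunConfig:
    """Validated configuration; sections accessible as dicts."""

    def __init__(self, sections: dict[str, dict]):
        self.sections = sections

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    def filter_params(self) -> FilterParams:
        f = self.sections["filter"]
        return FilterParams(
            offset=f["offset"], blue_weight_base=f["blue_weight_base"],
            reference_area=f["reference_area"],
            rb_weights=(f["rb_weight_red"], f["rb_weight_blue"]),
        )

    def threshold_params(self) -> ThresholdParams:
        t = self.sections["threshold"]
        return ThresholdParams(**t)

    def segmentation_params(self) -> SegmentationParams:
        s = {k: v for k, v in self.sections["segmentation"].items() if k != "day_one_area"}
        return SegmentationParams(**s)

    def section_hash(self, *names: str) -> str:
        payload = {n: self.sections[n] for n in names}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _coerce(raw: str, default):
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int) and not isinstance(default, bool):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def default_config() -> RunConfig:
    return RunConfig({s: dict(kv) for s, kv in DEFAULTS.items()})


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a config file on top of the defaults; unknown keys are rejected."""
    cfg = default_config()
    if path is not None:
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        for section in parser.sections():
            if section not in cfg.sections:
                raise ValueError(f"unknown config section [{section}]")
            for key, raw in parser.items(section):
                if key not in cfg.sections[section]:
                    raise ValueError(f"unknown key {key!r} in section [{section}]")
                cfg.sections[section][key] = _coerce(raw, DEFAULTS[section][key])
    for section, kv in (overrides or {}).items():
        if section not in cfg.sections:
            raise ValueError(f"unknown config section [{section}]")
        for key, val in kv.items():
            if key not in cfg.sections[section]:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            cfg.sections[section][key] = val
    return cfg
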