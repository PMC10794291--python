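"""Reproducible runs: configuration, dispatch, and run summaries.

Every run writes its outputs plus a ``run_summary.json`` that echoes the
full configuration (including every seed) and per-stage counts, so a job
can be re-run from its output directory alone.  Identical configuration
and seeds produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io as _io
from .core import LcfsdParams, dimension_distribution, lcfsd_map
from .fixtures import JULIA_PRESETS, make_fixture
from .julia import GridSpec, generate_julia_field, shuffle_magnitudes
from .multifractal import BoxGridConfig, alpha_skewness, spectrum
from .psr import (
    aggregate_animal,
    apply_psr_thresholds,
    collagen_stats,
    normalize_hue_to_height,
    rgb_to_hsi8,
)

__all__ = ["RunConfig", "RunSummary", "run_pipeline"]

log = logging.getLogger("lcfsd")


@dataclass
class RunConfig:
    subcommand: str
    out_dir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)

    def echo(self) -> dict:
        return {
            "subcommand": self.subcommand,
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "params": {k: (str(v) if isinstance(v, (Path, complex)) else v)
                       for k, v in self.params.items()},
        }


@dataclass
class RunSummary:
    config: dict
    version: str
    stages: dict[str, dict]

    def as_dict(self) -> dict:
        return {"config": self.config, "version": self.version, "stages": self.stages}


def _timed(stages: dict, name: str, fn):
    t0 = time.perf_counter()
    result = fn()
    stages.setdefault(name, {})["seconds"] = round(time.perf_counter() - t0, 3)
    return result


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute one subcommand and write outputs plus the run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    p = config.params

    if config.subcommand == "julia":
        if p.get("preset"):
            c, n_iter = JULIA_PRESETS[p["preset"]]
        else:
            c, n_iter = complex(p["c_re"], p["c_im"]), int(p["iterations"])
        grid = GridSpec(int(p.get("width", 1386)), int(p.get("height", 1386)),
                        tuple(p.get("x_range", (-2.0, 2.0))),
                        tuple(p.get("y_range", (-2.0, 2.0))))
        field_ = _timed(stages, "generate", lambda: generate_julia_field(c, n_iter, grid))
        if p.get("shuffle"):
            field_ = _timed(stages, "shuffle",
                            lambda: shuffle_magnitudes(field_, config.seed))
        _io.write_height_tiff(out / "magnitude.tif", field_.magnitude)
        _io.write_mask_png(out / "members.png", field_.member_mask)
        _io.write_png16(out / "escape.png",
                        np.where(field_.escape_time < 0, 0, field_.escape_time))
        stages["generate"]["member_pixels"] = int(field_.member_mask.sum())

    elif config.subcommand == "lcfsd":
        params = LcfsdParams(
            w=int(p.get("w", 8)),
            scales=tuple(p["scales"]) if p.get("scales") else None,
            global_max_F=p.get("F", "auto"),
            min_cluster_size=int(p.get("min_cluster", 6)),
        )
        paths = ([Path(p["image"])] if p.get("image")
                 else _io.read_manifest(p["manifest"]))
        images = [_io.read_image(path, "height") for path in paths]
        F = (None if params.global_max_F != "auto"
             else float(max(img.max() for img in images)))
        n_valid = 0
        for path, img in zip(paths, images):
            dmap = _timed(stages, f"lcfsd:{path.name}",
                          lambda img=img: lcfsd_map(img, params, F=F))
            n_valid += int(dmap.valid_mask.sum())
            stem = out / path.stem
            _io.write_height_tiff(f"{stem}_dims.tif",
                                  np.nan_to_num(dmap.dims, nan=0.0))
            _io.write_dimension_csv(f"{stem}_dims.csv", dmap)
            if dmap.valid_mask.any():
                dist = dimension_distribution(dmap, bandwidth=p.get("bandwidth"))
                _io.write_density_csv(f"{stem}_density.csv", dist)
                stages[f"lcfsd:{path.name}"]["mode_count"] = dist.mode_count
            stages[f"lcfsd:{path.name}"]["valid_pixels"] = int(dmap.valid_mask.sum())
            stages[f"lcfsd:{path.name}"]["F"] = dmap.F
        stages["total"] = {"valid_pixels": n_valid}

    elif config.subcommand == "psr":
        paths = ([Path(p["image"])] if p.get("image")
                 else _io.read_manifest(p["manifest"]))
        class_images, fractions = [], []
        for path in paths:
            rgb = _io.read_image(path, "rgb")
            hci = _timed(stages, f"psr:{path.name}",
                         lambda rgb=rgb: apply_psr_thresholds(rgb_to_hsi8(rgb)))
            mask = None
            if p.get("mask"):
                mask = int(_io.read_image(p["mask"], "binary").sum())
            st = collagen_stats(hci, mask)
            fractions.append(st.area_fraction)
            class_images.append(hci)
            _io.write_class_png(out / f"{path.stem}_classes.png", hci.classes)
            stages[f"psr:{path.name}"].update(
                {"area_fraction": st.area_fraction, **st.counts})
        heights = normalize_hue_to_height(class_images, p.get("experiment_id"))
        for path, him in zip(paths, heights):
            _io.write_height_tiff(out / f"{path.stem}_height.tif", him.values)
        agg = aggregate_animal(fractions)
        stages["animal"] = {"mean_area_fraction": agg.mean, "sd": agg.sd,
                            "n_images": agg.n, "sd_defined": agg.sd_defined}

    elif config.subcommand == "mfrac":
        img = _io.read_image(p["image"], "binary")
        cfg = BoxGridConfig(
            scales=tuple(p["scales"]) if p.get("scales") else None,
            offsets_scanned=int(p.get("offsets", 16)),
            q_grid=tuple(np.arange(p.get("q_min", -5.0),
                                   p.get("q_max", 5.0) + 1e-9,
                                   p.get("q_step", 0.25))),
            seed=config.seed,
        )
        spec = _timed(stages, "spectrum", lambda: spectrum(img, cfg))
        _io.write_spectrum_csv(out / "spectrum.csv", spec)
        _io.write_json(out / "spectrum.json", {
            "delta_alpha": spec.delta_alpha, "alpha_0": spec.alpha_0,
            "alpha_min": spec.alpha_min, "alpha_max": spec.alpha_max,
            "alpha_skewness": (alpha_skewness(spec) if spec.delta_alpha > 0 else None),
            "offsets": {str(k): list(v) for k, v in spec.offsets.items()},
        })
        stages["spectrum"]["delta_alpha"] = spec.delta_alpha

    elif config.subcommand == "fixture":
        truth = _timed(stages, "fixture",
                       lambda: make_fixture(p["kind"], out, seed=config.seed,
                                            **{k: v for k, v in p.items() if k != "kind"}))
        stages["fixture"].update({k: v for k, v in truth.items()
                                  if isinstance(v, (int, float, str, bool))})

    else:
        raise ValueError(f"unknown subcommand {config.subcommand!r}")

    summary = RunSummary(config=config.echo(), version=__version__, stages=stages)
    _io.write_json(out / "run_summary.json", summary.as_dict())
    return summary
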