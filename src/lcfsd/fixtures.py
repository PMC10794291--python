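"""Deterministic synthetic fixtures with ground-truth sidecars.

Everything here is generated by code at run time: Julia fields at the
published parameters, Henon/circle reference objects, constant "solid"
and "sheet" images with known analytic dimensions, random height images
for range sweeps, and a synthetic histology-like RGB image emulating a
polarized Picrosirius-red micrograph (dark background plus curvilinear
fiber strokes with per-class hues) whose exact per-class pixel counts
are tracked while painting.

The synthetic histology image is a stand-in constructed for testing the
hue pipeline's bookkeeping; it does not emulate optics, noise or real
fiber morphology.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io as _io
from .julia import GridSpec, generate_julia_field, shuffle_magnitudes
from .multifractal import filled_circle, henon_attractor
from .psr import HueClass, classify_hue, rgb_to_hsi8

__all__ = [
    "JULIA_PRESETS",
    "random_height_image",
    "synthetic_psr_image",
    "solid_image",
    "sheet_image",
    "make_fixture",
]

# (c, iterations) triples used as published exemplars
JULIA_PRESETS: dict[str, tuple[complex, int]] = {
    "spiral": (-0.5285 - 0.5285j, 97),
    "dendrite": (1j, 15),
    "bimodal": (-1.15 + 0.215j, 96),
}

# mid-band hues per class, far from the class boundaries so the 8-bit
# HSV round trip cannot change the class
_CLASS_HUES = {
    HueClass.RED: 4,
    HueClass.ORANGE: 24,
    HueClass.YELLOW: 45,
    HueClass.GREEN: 90,
}


def random_height_image(
    shape: tuple[int, int], rng: np.random.Generator,
    density_range: tuple[float, float] = (0.1, 0.95),
) -> np.ndarray:
    """Uniform random heights with a random sparsity level."""
    density = rng.uniform(*density_range)
    mask = rng.random(shape) < density
    return rng.random(shape) * mask


def solid_image(shape: tuple[int, int] = (64, 64), value: float = 1.0) -> np.ndarray:
    """Constant full-height image; interior LCFSD is exactly 3 at F = value."""
    return np.full(shape, float(value))


def sheet_image(shape: tuple[int, int] = (64, 64), value: float = 1.0, h: int = 17) -> np.ndarray:
    """Constant one-level image: value maps to level 1 at F = h * value."""
    return np.full(shape, float(value))


def _hue8_to_rgb(h8: int) -> tuple[int, int, int]:
    """Fully saturated, full-intensity RGB for an 8-bit hue."""
    import colorsys

    r, g, b = colorsys.hsv_to_rgb(h8 / 255.0, 1.0, 1.0)
    return (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))


def synthetic_psr_image(
    shape: tuple[int, int] = (256, 256),
    n_fibers: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Histology-like RGB image with exactly known per-class pixel counts.

    Curvilinear fiber strokes (random walks, 1-2 px wide) are painted in
    mid-band hues of the four collagen classes at full saturation and
    intensity over a dark background that fails the intensity cut.  The
    final class of every pixel is tracked while painting (later strokes
    overwrite earlier ones), so the sidecar counts are exact ground truth
    for the thresholding + classification pipeline.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    rgb = np.full((H, W, 3), 10, dtype=np.uint8)  # intensity 10 < 16: excluded
    painted = np.zeros((H, W), dtype=np.uint8)  # HueClass codes

    classes = list(_CLASS_HUES)
    for _ in range(n_fibers):
        cls = classes[rng.integers(len(classes))]
        col = _hue8_to_rgb(_CLASS_HUES[cls])
        i = float(rng.uniform(0, H))
        j = float(rng.uniform(0, W))
        angle = rng.uniform(0, 2 * np.pi)
        width = int(rng.integers(1, 3))
        for _ in range(int(rng.integers(30, 120))):
            angle += rng.normal(0, 0.3)
            i += np.sin(angle)
            j += np.cos(angle)
            ii, jj = int(round(i)), int(round(j))
            for di in range(width):
                for dj in range(width):
                    a, b = ii + di, jj + dj
                    if 0 <= a < H and 0 <= b < W:
                        rgb[a, b] = col
                        painted[a, b] = int(cls)

    counts = {cls.name.lower(): int((painted == int(cls)).sum())
              for cls in HueClass if cls != HueClass.BACKGROUND}
    n_coll = int(sum(counts.values()))
    truth = {
        "shape": [H, W],
        "seed": seed,
        "class_counts": counts,
        "collagen_pixels": n_coll,
        "area_fraction": n_coll / (H * W),
        "class_hues": {cls.name.lower(): _CLASS_HUES[cls] for cls in _CLASS_HUES},
    }
    return rgb, truth


def _verify_roundtrip() -> None:
    """The painted hues must classify back to their own class exactly."""
    for cls, h8 in _CLASS_HUES.items():
        rgb = np.array([[_hue8_to_rgb(h8)]], dtype=np.uint8)
        hsi = rgb_to_hsi8(rgb)
        assert classify_hue(int(hsi.hue[0, 0])) == int(cls)


def make_fixture(kind: str, out_dir: str | Path, seed: int = 0, **params) -> dict:
    """Write a deterministic fixture plus a JSON ground-truth sidecar.

    kinds: julia (params: preset or c/n_iter, size, shuffle), henon,
    circle, psr_synthetic, solid, sheet.  Returns the sidecar dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict

    if kind == "julia":
        preset = params.get("preset")
        if preset is not None:
            c, n_iter = JULIA_PRESETS[preset]
        else:
            c, n_iter = complex(params["c"]), int(params["n_iter"])
        size = int(params.get("size", 1386))
        grid = GridSpec(size, size)
        field = generate_julia_field(c, n_iter, grid)
        if params.get("shuffle", False):
            field = shuffle_magnitudes(field, seed)
        stem = out / f"julia_{preset or 'custom'}"
        _io.write_height_tiff(f"{stem}_magnitude.tif", field.magnitude)
        _io.write_mask_png(f"{stem}_members.png", field.member_mask)
        _io.write_png16(f"{stem}_escape.png",
                        np.where(field.escape_time < 0, 0, field.escape_time))
        truth = {
            "kind": kind, "c": [c.real, c.imag], "n_iter": n_iter, "size": size,
            "member_pixels": int(field.member_mask.sum()),
            "shuffled": bool(params.get("shuffle", False)), "seed": seed,
            "files": [f"{stem.name}_magnitude.tif", f"{stem.name}_members.png",
                      f"{stem.name}_escape.png"],
        }
    elif kind == "henon":
        img = henon_attractor(n_points=int(params.get("n_points", 200_000)))
        _io.write_mask_png(out / "henon.png", img)
        truth = {"kind": kind, "foreground_pixels": int(img.sum()), "files": ["henon.png"]}
    elif kind == "circle":
        size = int(params.get("size", 256))
        # disk nearly inscribed in its raster (radius 120 at the default 256)
        radius = int(params.get("radius", round(0.47 * size)))
        img = filled_circle(radius, (size, size))
        _io.write_mask_png(out / "circle.png", img)
        truth = {"kind": kind, "radius": radius,
                 "foreground_pixels": int(img.sum()), "files": ["circle.png"]}
    elif kind == "psr_synthetic":
        _verify_roundtrip()
        rgb, truth = synthetic_psr_image(
            shape=tuple(params.get("shape", (256, 256))),
            n_fibers=int(params.get("n_fibers", 40)), seed=seed,
        )
        _io.write_rgb_png(out / "psr_synthetic.png", rgb)
        truth = {"kind": kind, **truth, "files": ["psr_synthetic.png"]}
    elif kind in ("solid", "sheet"):
        h = int(params.get("h", 17))
        shape = tuple(params.get("shape", (64, 64)))
        if kind == "solid":
            img, F, expected = solid_image(shape), 1.0, 3.0
        else:
            img, F, expected = sheet_image(shape), float(h), 2.0
        _io.write_height_tiff(out / f"{kind}.tif", img)
        truth = {"kind": kind, "shape": list(shape), "F": F,
                 "expected_dimension": expected, "files": [f"{kind}.tif"]}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    with open(out / f"{kind}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
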