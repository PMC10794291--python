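"""Image, manifest and result readers/writers.

Coordinate convention throughout: row-major, 0-based pixel indices,
origin at the top-left of the image.  Height and dimension images travel
as float32 TIFF; masks as 8-bit PNG (0/255); RGB micrographs as 8-bit
PNG or TIFF.  Tabular output is CSV with floats at 9 significant digits.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "read_image",
    "write_height_tiff",
    "write_png16",
    "write_mask_png",
    "write_rgb_png",
    "write_class_png",
    "write_dimension_csv",
    "write_density_csv",
    "write_spectrum_csv",
    "write_json",
    "read_manifest",
]

_FLOAT_FMT = "{:.9g}"

# paletted PNG colors for the collagen classes (background, red, orange,
# yellow, green)
_CLASS_PALETTE = [(0, 0, 0), (220, 30, 30), (240, 140, 20), (235, 220, 40), (60, 180, 60)]


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(str(path))
    return np.asarray(Image.open(path))


def read_image(path: str | Path, expected_kind: str) -> np.ndarray:
    """Read an image and validate it against the declared kind.

    kinds: "rgb" (8-bit, 3 channels), "height" (single-channel float or
    integer, returned as float64 >= 0), "binary" (single-channel, returned
    as bool).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _load_array(path)

    if expected_kind == "rgb":
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
            raise ValueError(
                f"{path}: expected an 8-bit RGB image, got shape {arr.shape} dtype {arr.dtype}")
        return arr
    if expected_kind == "height":
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel height image, got shape {arr.shape}")
        out = arr.astype(np.float64)
        if not np.isfinite(out).all() or (out < 0).any():
            raise ValueError(f"{path}: height image must be finite and nonnegative")
        return out
    if expected_kind == "binary":
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel mask, got shape {arr.shape}")
        return arr > 0
    raise ValueError(f"unknown image kind {expected_kind!r}")


def write_height_tiff(path: str | Path, values: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


def write_png16(path: str | Path, values: np.ndarray) -> None:
    arr = np.asarray(values)
    if arr.max(initial=0) > 0xFFFF or arr.min(initial=0) < 0:
        raise ValueError("values do not fit in 16 bits")
    Image.fromarray(arr.astype(np.uint16)).save(str(path))


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(str(path))


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(str(path))


def write_class_png(path: str | Path, classes: np.ndarray) -> None:
    img = Image.fromarray(np.asarray(classes, dtype=np.uint8), mode="P")
    palette = []
    for rgb in _CLASS_PALETTE:
        palette.extend(rgb)
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(str(path))


def _fmt(v) -> str:
    return _FLOAT_FMT.format(v) if isinstance(v, float) else str(v)


def write_dimension_csv(path: str | Path, dim_map) -> None:
    """CSV of (row, col, dimension) for valid pixels; origin top-left."""
    rows, cols = np.nonzero(dim_map.valid_mask)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["# row-major 0-based pixel indices, origin top-left"])
        wr.writerow(["row", "col", "dimension"])
        for i, j in zip(rows, cols):
            wr.writerow([int(i), int(j), _fmt(float(dim_map.dims[i, j]))])


def write_density_csv(path: str | Path, dist) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["dimension", "density"])
        for x, d in zip(dist.grid, dist.density):
            wr.writerow([_fmt(float(x)), _fmt(float(d))])


def write_spectrum_csv(path: str | Path, spec) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["q", "alpha", "f_of_alpha"])
        for q, a, f in zip(spec.q_grid, spec.alpha, spec.f_of_alpha):
            wr.writerow([_fmt(float(q)), _fmt(float(a)), _fmt(float(f))])


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> list[Path]:
    """Plain manifest: one image path per line (relative to the manifest)."""
    path = Path(path)
    base = path.parent
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            p = Path(line)
            out.append(p if p.is_absolute() else base / p)
    if not out:
        raise ValueError(f"manifest {path} lists no images")
    return out
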