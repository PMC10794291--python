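"""Locally connected fractal surface dimension (LCFSD).

The LCFSD assigns a fractal dimension to every nonzero pixel of a
nonnegative "height" image (intensity treated as a third spatial
dimension).  For a pixel r, an h x h window (h = 2w + 1, default 17) is
centered on r and restricted to the 8-connected component of nonzero
pixels containing r.  Heights f on that component are rescaled by the
global maximum F over the image set and binned into h levels by rounding
up,

    f* = ceil(h * f / F),  clamped to 1..h for f > 0,

turning the window into an h x h x h cube of voxels in which column (x, y)
holds f*(x, y) occupied voxels.  For each odd box size L in
S_L = {3, 5, ..., h}, the number of occupied voxels of the centered
L x L x L cube is

    N(L) = sum over the L x L subwindow of min(f*, L),

and the dimension at r is the least-squares slope of log N(L) against
log L.  A solid cube gives N(L) = L**3 (slope 3), a flat unit-height sheet
N(L) = L**2 (slope 2), an isolated column N(L) = L (slope 1); meaningful
values lie in [0, 3].

Eligibility follows the application rules: 8-connected clusters of fewer
than ``min_cluster_size`` nonzero pixels are removed first, and pixels
within w of an image edge are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from . import _kernels

__all__ = [
    "LcfsdParams",
    "HeightImage",
    "ConnectedWindow",
    "DimensionMap",
    "DimensionDistribution",
    "remove_small_clusters",
    "extract_connected_window",
    "rescale_and_bin",
    "occupancy_count",
    "fit_dimension",
    "lcfsd_map",
    "dimension_distribution",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def _default_scales(h: int) -> tuple[int, ...]:
    return tuple(range(3, h + 1, 2))


@dataclass(frozen=True)
class LcfsdParams:
    """Parameters of the LCFSD pipeline.

    w : half-window in pixels; the window side is h = 2w + 1.
    scales : odd box sizes L used in the log-log fit; default {3, 5, ..., h}.
    global_max_F : normalization maximum F shared across an image set, or
        "auto" to take the maximum of the image(s) supplied to the run.
    min_cluster_size : smallest 8-connected nonzero cluster kept (default 6,
        i.e. clusters of 5 or fewer pixels are discarded).
    pixel_size : physical pixel edge length in micrometers.
    """

    w: int = 8
    scales: tuple[int, ...] | None = None
    global_max_F: float | str = "auto"
    min_cluster_size: int = 6
    pixel_size: float = 0.369

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        scales = self.scales if self.scales is not None else _default_scales(self.h)
        scales = tuple(int(L) for L in scales)
        for L in scales:
            if L % 2 == 0 or not (3 <= L <= self.h):
                raise ValueError(f"scales must be odd and within [3, {self.h}]; got {L}")
        if len(scales) < 2:
            raise ValueError("need at least two scales for a slope fit")
        object.__setattr__(self, "scales", scales)
        if not isinstance(self.global_max_F, str):
            if self.global_max_F <= 0:
                raise ValueError("global_max_F must be positive")
        elif self.global_max_F != "auto":
            raise ValueError("global_max_F must be a positive number or 'auto'")

    @property
    def h(self) -> int:
        return 2 * self.w + 1

    @property
    def window_physical_size(self) -> float:
        """Window side length in micrometers (h pixels times pixel size)."""
        return self.h * self.pixel_size


@dataclass
class HeightImage:
    """Nonnegative 2D height field; zero marks background."""

    values: np.ndarray
    pixel_size: float = 0.369

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("height image must be 2D")
        if not np.isfinite(self.values).all():
            raise ValueError("height values must be finite")
        if (self.values < 0).any():
            raise ValueError("height values must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class ConnectedWindow:
    """h x h patch around a center pixel with its 8-connected nonzero mask."""

    center: tuple[int, int]
    region: np.ndarray
    connected_mask: np.ndarray


@dataclass
class DimensionMap:
    """Per-pixel LCFSD values; ``dims`` is NaN off the validity mask."""

    dims: np.ndarray
    valid_mask: np.ndarray
    F: float
    params: LcfsdParams

    @property
    def sample(self) -> np.ndarray:
        """Dimension values of all valid pixels, as a flat array."""
        return self.dims[self.valid_mask]


@dataclass
class DimensionDistribution:
    """Gaussian-kernel density of a dimension sample with its mode count."""

    sample: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    mode_count: int


def remove_small_clusters(values: np.ndarray, min_cluster_size: int) -> np.ndarray:
    """Zero out 8-connected nonzero components smaller than the threshold."""
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    values = np.asarray(values, dtype=np.float64)
    if min_cluster_size == 1 or not (values > 0).any():
        return values.copy()
    labels, n = ndimage.label(values > 0, structure=_EIGHT)
    sizes = np.bincount(labels.ravel())
    small = sizes < min_cluster_size
    small[0] = False
    out = values.copy()
    out[small[labels]] = 0.0
    return out


def extract_connected_window(values: np.ndarray, r: tuple[int, int], w: int) -> ConnectedWindow:
    """h x h patch at r restricted to the 8-connected nonzero component of r.

    The component is computed within the patch only.  Raises if the center
    is zero (pixel not eligible) or lies within w pixels of an image edge.
    """
    values = np.asarray(values, dtype=np.float64)
    i, j = r
    H, W = values.shape
    if not (w <= i < H - w and w <= j < W - w):
        raise ValueError(f"pixel {r} is within {w} pixels of an image edge")
    if values[i, j] <= 0:
        raise ValueError(f"pixel {r} has zero height and is not eligible")
    region = values[i - w:i + w + 1, j - w:j + w + 1].copy()
    labels, _ = ndimage.label(region > 0, structure=_EIGHT)
    mask = labels == labels[w, w]
    return ConnectedWindow(center=(i, j), region=region, connected_mask=mask)


def rescale_and_bin(window: ConnectedWindow, F: float, h: int) -> np.ndarray:
    """Bin connected heights into levels 1..h via ceil(h*f/F); 0 off-mask."""
    if F <= 0:
        raise ValueError("F must be positive")
    wmax = window.region[window.connected_mask].max()
    if F < wmax:
        raise ValueError(f"F = {F:g} is below the window maximum {wmax:g}")
    levels = np.zeros(window.region.shape, dtype=np.int64)
    m = window.connected_mask
    levels[m] = np.clip(np.ceil(h * window.region[m] / F).astype(np.int64), 1, h)
    return levels


def occupancy_count(levels: np.ndarray, L: int) -> int:
    """Occupied voxels of the centered L x L x L cube: sum of min(level, L)."""
    h = levels.shape[0]
    if L % 2 == 0 or not (3 <= L <= h):
        raise ValueError(f"L must be odd and within [3, {h}]; got {L}")
    c = h // 2
    half = L // 2
    sub = levels[c - half:c + half + 1, c - half:c + half + 1]
    return int(np.minimum(sub, L).sum())


def fit_dimension(scales: np.ndarray, counts: np.ndarray) -> float:
    """OLS slope of log N(L) versus log L over the scale set."""
    scales = np.asarray(scales, dtype=np.float64)
    counts = np.asarray(counts, dtype=np.float64)
    usable = counts >= 1
    if usable.sum() < 2:
        raise ValueError("need at least two scales with N(L) >= 1")
    x = np.log(scales[usable])
    y = np.log(counts[usable])
    x = x - x.mean()
    return float((x @ y) / (x @ x))


def _lcfsd_dims_numpy(values: np.ndarray, params: LcfsdParams, F: float) -> np.ndarray:
    """Reference per-pixel loop through the individual operations."""
    H, W = values.shape
    w, h = params.w, params.h
    scales = np.array(params.scales)
    dims = np.full((H, W), np.nan)
    for i in range(w, H - w):
        for j in range(w, W - w):
            if values[i, j] <= 0:
                continue
            window = extract_connected_window(values, (i, j), w)
            levels = rescale_and_bin(window, F, h)
            counts = [occupancy_count(levels, L) for L in scales]
            dims[i, j] = fit_dimension(scales, np.array(counts))
    return dims


def lcfsd_map(
    img: HeightImage | np.ndarray,
    params: LcfsdParams | None = None,
    F: float | None = None,
    engine: str = "auto",
) -> DimensionMap:
    """Per-pixel LCFSD map of a height image.

    Small clusters are removed, then every nonzero pixel at least w from
    the image edges receives the slope of log N(L) vs log L computed on
    its connected h x h window.  ``F`` overrides the normalization maximum
    (use it to share F across an image set); otherwise ``params.global_max_F``
    applies, with "auto" meaning the maximum of this image.

    engine: "numba" (compiled), "numpy" (reference loop) or "auto".
    """
    if params is None:
        params = LcfsdParams()
    if isinstance(img, HeightImage):
        values = img.values
    else:
        values = HeightImage(np.asarray(img)).values
    H, W = values.shape
    if H < params.h or W < params.h:
        raise ValueError(f"image {values.shape} is smaller than the {params.h}x{params.h} window")

    cleaned = remove_small_clusters(values, params.min_cluster_size)

    if F is None:
        F = None if params.global_max_F == "auto" else float(params.global_max_F)
    if F is None:
        F = float(cleaned.max())
    if F <= 0 or not (cleaned > 0).any():
        # nothing survives cleaning: empty map, not an error
        warnings.warn("no eligible pixels after cluster removal", stacklevel=2)
        dims = np.full((H, W), np.nan)
        return DimensionMap(dims=dims, valid_mask=np.zeros((H, W), bool), F=F or 0.0, params=params)
    if F < cleaned.max():
        raise ValueError(f"F = {F:g} is below the image maximum {cleaned.max():g}")

    use_numba = _kernels.HAVE_NUMBA if engine == "auto" else engine == "numba"
    if engine not in ("auto", "numba", "numpy"):
        raise ValueError("engine must be 'auto', 'numba' or 'numpy'")
    if use_numba:
        dims = _kernels._dims_kernel(
            np.ascontiguousarray(cleaned), params.w,
            np.array(params.scales, dtype=np.int64), float(F),
        )
    else:
        dims = _lcfsd_dims_numpy(cleaned, params, float(F))

    valid = ~np.isnan(dims)
    eps = 1e-9  # regression round-off
    out_of_range = valid & ((dims < -eps) | (dims > 3 + eps))
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} pixel(s) have dimension outside [0, 3]; "
            "reported unclipped", stacklevel=2,
        )
    return DimensionMap(dims=dims, valid_mask=valid, F=float(F), params=params)


def dimension_distribution(
    dim_map: DimensionMap | np.ndarray,
    bandwidth: float | None = None,
    grid_points: int = 512,
    prominence_frac: float = 0.01,
) -> DimensionDistribution:
    """Gaussian-kernel density of the valid dimension values with mode count.

    Bandwidth defaults to Silverman's rule.  Modes are strict local maxima
    of the evaluated density with prominence at least ``prominence_frac``
    of the density maximum.
    """
    sample = dim_map.sample if isinstance(dim_map, DimensionMap) else np.asarray(dim_map, float)
    sample = sample[np.isfinite(sample)]
    if sample.size == 0:
        raise ValueError("cannot build a distribution from an empty dimension map")

    if np.ptp(sample) == 0.0:
        # degenerate sample: a point mass, rendered as one narrow Gaussian
        bw = bandwidth if bandwidth is not None else 1e-3
        grid = np.linspace(sample[0] - 6 * bw, sample[0] + 6 * bw, grid_points)
        density = stats.norm.pdf(grid, loc=sample[0], scale=bw)
        return DimensionDistribution(sample, grid, density, bw, mode_count=1)

    kde = stats.gaussian_kde(sample, bw_method="silverman" if bandwidth is None else None)
    if bandwidth is not None:
        kde.set_bandwidth(bandwidth / sample.std(ddof=1))
    bw = float(kde.factor * sample.std(ddof=1))
    grid = np.linspace(sample.min() - 3 * bw, sample.max() + 3 * bw, grid_points)
    density = kde(grid)
    peaks, _ = signal.find_peaks(density, prominence=prominence_frac * density.max())
    return DimensionDistribution(sample, grid, density, bw, mode_count=int(len(peaks)))
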