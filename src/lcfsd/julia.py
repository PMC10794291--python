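"""Julia-set test exemplars for the quadratic map z -> z**2 + c.

A Julia field is computed on a pixel grid mapped onto a rectangle of the
complex plane.  Each pixel is seeded with its own coordinate and iterated
under the quadratic map; pixels whose orbit modulus never exceeds the
escape radius 2 are members of the (filled) Julia set.  Members carry the
modulus of their final iterate, which serves as the height (third
dimension) for local fractal surface analysis; non-members carry the last
iteration index before escape.

A seeded magnitude shuffle provides the negative control: it preserves the
member support and the magnitude histogram exactly while destroying all
spatial correlation of the height surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "OrbitRecord",
    "JuliaField",
    "iterate_quadratic",
    "generate_julia_field",
    "critical_orbit_period",
    "shuffle_magnitudes",
]

ESCAPE_RADIUS = 2.0


@dataclass(frozen=True)
class GridSpec:
    """Pixel grid mapped linearly onto a rectangle of the complex plane.

    Pixel centers span the closed ranges; row 0 is the top of the
    imaginary axis (image convention), column 0 the left of the real axis.
    """

    width: int
    height: int
    x_range: tuple[float, float] = (-2.0, 2.0)
    y_range: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must have at least one pixel per axis")
        if not (self.x_range[1] > self.x_range[0] and self.y_range[1] > self.y_range[0]):
            raise ValueError("coordinate ranges must be nondegenerate increasing intervals")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def complex_coordinates(self) -> np.ndarray:
        """(height, width) array of pixel-center complex coordinates."""
        xs = np.linspace(self.x_range[0], self.x_range[1], self.width)
        ys = np.linspace(self.y_range[1], self.y_range[0], self.height)  # row 0 = top
        re, im = np.meshgrid(xs, ys)
        return re + 1j * im


@dataclass
class OrbitRecord:
    """Single orbit of the quadratic map, with escape and cycle diagnostics."""

    orbit: np.ndarray  # complex, z_0 ... z_n
    escaped: bool
    period: int | None = None
    detection_tolerance: float = 0.0


@dataclass
class JuliaField:
    """Julia-set membership, escape times and final magnitudes on a grid.

    ``magnitude`` is defined (finite, <= 2) exactly on ``member_mask``;
    ``escape_time`` is defined (>= 0) exactly off it.  The two supports are
    disjoint and tile the grid.
    """

    grid: GridSpec
    c: complex
    n_iter: int
    member_mask: np.ndarray  # bool
    escape_time: np.ndarray  # int, -1 on members
    magnitude: np.ndarray  # float, 0 on non-members

    def __post_init__(self) -> None:
        if abs(self.c) > ESCAPE_RADIUS:
            raise ValueError(f"|c| must be <= {ESCAPE_RADIUS}, got |c| = {abs(self.c):g}")


def iterate_quadratic(
    z0: complex,
    c: complex,
    n_max: int,
    escape_radius: float = ESCAPE_RADIUS,
) -> OrbitRecord:
    """Iterate z -> z**2 + c from ``z0``, recording the full orbit.

    Stops as soon as the modulus exceeds ``escape_radius`` (the orbit is
    then unbounded for |c| <= 2) or after ``n_max`` iterations.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if escape_radius <= 0:
        raise ValueError("escape_radius must be positive")
    if not (math.isfinite(z0.real) and math.isfinite(z0.imag)
            and math.isfinite(c.real) and math.isfinite(c.imag)):
        raise ValueError("z0 and c must be finite")

    orbit = [complex(z0)]
    z = complex(z0)
    escaped = abs(z) > escape_radius
    for _ in range(n_max):
        if escaped:
            break
        z = z * z + c
        orbit.append(z)
        if abs(z) > escape_radius:
            escaped = True
    return OrbitRecord(orbit=np.array(orbit, dtype=complex), escaped=escaped)


def generate_julia_field(c: complex, n_iter: int, grid: GridSpec) -> JuliaField:
    """Compute membership, escape times and final magnitudes for every pixel.

    A pixel belongs to the set if its orbit modulus stays <= 2 through all
    ``n_iter`` iterations; its height is then |z| after the final iteration.
    A pixel that first exceeds modulus 2 at iteration k carries escape time
    k - 1 (the last iteration on which it was still inside).
    """
    if abs(c) > ESCAPE_RADIUS:
        raise ValueError(f"|c| must be <= {ESCAPE_RADIUS}, got |c| = {abs(c):g}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    z = grid.complex_coordinates()
    active = np.abs(z) <= ESCAPE_RADIUS
    escape_time = np.full(grid.shape, -1, dtype=np.int64)
    # Seeds already outside modulus 2 never entered the set: escape time 0
    # would claim one surviving iteration, so they escape "at" iteration 1
    # with last-inside index 0.
    escape_time[~active] = 0

    for it in range(1, n_iter + 1):
        zn = z[active]
        zn = zn * zn + c
        z[active] = zn
        left = np.abs(zn) > ESCAPE_RADIUS
        if left.any():
            idx = np.flatnonzero(active.ravel())[left]
            escape_time.ravel()[idx] = it - 1
            active.ravel()[idx] = False

    magnitude = np.zeros(grid.shape, dtype=np.float64)
    magnitude[active] = np.abs(z[active])
    escape_time[active] = -1
    return JuliaField(
        grid=grid, c=c, n_iter=n_iter,
        member_mask=active, escape_time=escape_time, magnitude=magnitude,
    )


def critical_orbit_period(
    c: complex,
    max_iter: int = 20_000,
    tol: float = 0.0,
) -> int | None:
    """Eventual cycle length of the critical orbit 0, c, c**2+c, ...

    The orbit is iterated in double precision for a burn-in of
    ``max_iter // 2`` steps, then the smallest lag ``p`` at which the tail
    revisits itself (``|z[n+p] - z[n]| <= tol`` over ``3p`` consecutive
    steps) is returned.  With the default ``tol = 0.0`` this is the exact
    repeat length of the machine orbit, which is what escape-time renderers
    working in double precision observe; a small positive ``tol`` (e.g.
    1e-9) instead detects the underlying attracting cycle, which can be a
    divisor of the machine period when rounding splits the cycle into
    several nearly identical copies.

    Returns None if the orbit escapes (modulus > 2) or no cycle is found
    within the scanned lags.
    """
    if max_iter < 4:
        raise ValueError("max_iter too small to detect any cycle")
    if tol < 0:
        raise ValueError("tol must be >= 0")

    z = 0j
    burn = max_iter // 2
    for _ in range(burn):
        z = z * z + c
        if abs(z) > ESCAPE_RADIUS:
            return None
    tail = [z]
    for _ in range(max_iter - burn):
        z = z * z + c
        if abs(z) > ESCAPE_RADIUS:
            return None
        tail.append(z)
    arr = np.array(tail)
    n = len(arr)
    for p in range(1, n // 4 + 1):
        m = min(3 * p, n - p)
        if np.all(np.abs(arr[p:p + m] - arr[:m]) <= tol):
            return p
    return None


def shuffle_magnitudes(field: JuliaField, seed: int, window: int | None = None) -> JuliaField:
    """Randomly permute member magnitudes; support and histogram preserved.

    With ``window=None`` (default) a single seeded permutation is applied
    over the full member set, destroying all spatial correlation of the
    height surface.  With an integer ``window`` the permutation is applied
    independently within each window x window tile.
    """
    if not field.member_mask.any():
        raise ValueError("cannot shuffle a field with an empty member set")
    rng = np.random.default_rng(seed)
    magnitude = field.magnitude.copy()
    if window is None:
        vals = magnitude[field.member_mask]
        magnitude[field.member_mask] = rng.permutation(vals)
    else:
        if window < 1:
            raise ValueError("window must be >= 1")
        H, W = field.member_mask.shape
        for i0 in range(0, H, window):
            for j0 in range(0, W, window):
                tile = np.s_[i0:i0 + window, j0:j0 + window]
                m = field.member_mask[tile]
                if m.any():
                    sub = magnitude[tile]
                    sub[m] = rng.permutation(sub[m])
                    magnitude[tile] = sub
    return JuliaField(
        grid=field.grid, c=field.c, n_iter=field.n_iter,
        member_mask=field.member_mask.copy(),
        escape_time=field.escape_time.copy(),
        magnitude=magnitude,
    )
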