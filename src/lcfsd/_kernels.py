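"""Compiled hot path for the per-pixel dimension map.

The pure-numpy route in :mod:`lcfsd.core` is the readable reference; this
module re-implements the inner per-pixel loop (window flood fill, height
binning, occupancy counts, log-log slope) in nopython numba for full-image
runs.  Both routes are compared on random images in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _dims_kernel(values, w, scales, F):  # pragma: no cover - exercised via lcfsd_map
    H, W = values.shape
    h = 2 * w + 1
    n_s = scales.shape[0]

    log_l = np.empty(n_s)
    for k in range(n_s):
        log_l[k] = math.log(scales[k])
    ml = log_l.mean()
    denom = 0.0
    for k in range(n_s):
        denom += (log_l[k] - ml) ** 2

    dims = np.full((H, W), np.nan)
    levels = np.zeros((h, h), dtype=np.int64)
    stack = np.empty((h * h, 2), dtype=np.int64)
    log_n = np.empty(n_s)

    for i in range(w, H - w):
        for j in range(w, W - w):
            if values[i, j] <= 0.0:
                continue
            # 8-connected component of nonzero pixels containing the center,
            # computed within the h x h window only; levels = ceil(h*f/F)
            # clamped to [1, h] on the component, 0 elsewhere.
            for a in range(h):
                for b in range(h):
                    levels[a, b] = 0
            top = 0
            stack[top, 0] = w
            stack[top, 1] = w
            top = 1
            lev = int(math.ceil(h * values[i, j] / F))
            if lev < 1:
                lev = 1
            elif lev > h:
                lev = h
            levels[w, w] = lev
            while top > 0:
                top -= 1
                a = stack[top, 0]
                b = stack[top, 1]
                for da in range(-1, 2):
                    for db in range(-1, 2):
                        na = a + da
                        nb = b + db
                        if na < 0 or na >= h or nb < 0 or nb >= h:
                            continue
                        if levels[na, nb] != 0:
                            continue
                        v = values[i + na - w, j + nb - w]
                        if v <= 0.0:
                            continue
                        lev = int(math.ceil(h * v / F))
                        if lev < 1:
                            lev = 1
                        elif lev > h:
                            lev = h
                        levels[na, nb] = lev
                        stack[top, 0] = na
                        stack[top, 1] = nb
                        top += 1

            for k in range(n_s):
                L = scales[k]
                half = L // 2
                s = 0
                for a in range(w - half, w + half + 1):
                    for b in range(w - half, w + half + 1):
                        lv = levels[a, b]
                        if lv > L:
                            lv = L
                        s += lv
                log_n[k] = math.log(s)

            num = 0.0
            for k in range(n_s):
                num += (log_l[k] - ml) * log_n[k]
            dims[i, j] = num / denom
    return dims
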