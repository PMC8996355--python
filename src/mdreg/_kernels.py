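"""Fused trilinear interpolation kernels.

Trilinear gathers and their adjoint scatters dominate the cost of
scaling-and-squaring and warping, so they are JIT-compiled with numba when it
is importable; a vectorized NumPy path provides the identical result
otherwise. Both paths clamp out-of-range positions to the border and zero the
position gradient wherever clamping is active.

Shapes: ``img`` is (C, D, H, W); ``coords`` is (3, M) absolute voxel
positions; outputs are (C, M) / gradients match their primals.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every warp
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _trilin_fwd_nb(img, coords, out):  # pragma: no cover - numba
    C = img.shape[0]
    D, H, W = img.shape[1], img.shape[2], img.shape[3]
    M = coords.shape[1]
    for m in range(M):
        x = min(max(coords[0, m], 0.0), D - 1.0)
        y = min(max(coords[1, m], 0.0), H - 1.0)
        z = min(max(coords[2, m], 0.0), W - 1.0)
        i0 = min(int(x), max(D - 2, 0))
        j0 = min(int(y), max(H - 2, 0))
        k0 = min(int(z), max(W - 2, 0))
        fx = x - i0
        fy = y - j0
        fz = z - k0
        i1 = min(i0 + 1, D - 1)
        j1 = min(j0 + 1, H - 1)
        k1 = min(k0 + 1, W - 1)
        w000 = (1 - fx) * (1 - fy) * (1 - fz)
        w001 = (1 - fx) * (1 - fy) * fz
        w010 = (1 - fx) * fy * (1 - fz)
        w011 = (1 - fx) * fy * fz
        w100 = fx * (1 - fy) * (1 - fz)
        w101 = fx * (1 - fy) * fz
        w110 = fx * fy * (1 - fz)
        w111 = fx * fy * fz
        for c in range(C):
            out[c, m] = (w000 * img[c, i0, j0, k0] + w001 * img[c, i0, j0, k1]
                         + w010 * img[c, i0, j1, k0] + w011 * img[c, i0, j1, k1]
                         + w100 * img[c, i1, j0, k0] + w101 * img[c, i1, j0, k1]
                         + w110 * img[c, i1, j1, k0] + w111 * img[c, i1, j1, k1])


@njit(cache=True, fastmath=True)
def _trilin_bwd_nb(img, coords, gout, gimg, gcoords,
                   need_img, need_coords):  # pragma: no cover - numba
    C = img.shape[0]
    D, H, W = img.shape[1], img.shape[2], img.shape[3]
    M = coords.shape[1]
    for m in range(M):
        cx = coords[0, m]
        cy = coords[1, m]
        cz = coords[2, m]
        x = min(max(cx, 0.0), D - 1.0)
        y = min(max(cy, 0.0), H - 1.0)
        z = min(max(cz, 0.0), W - 1.0)
        i0 = min(int(x), max(D - 2, 0))
        j0 = min(int(y), max(H - 2, 0))
        k0 = min(int(z), max(W - 2, 0))
        fx = x - i0
        fy = y - j0
        fz = z - k0
        i1 = min(i0 + 1, D - 1)
        j1 = min(j0 + 1, H - 1)
        k1 = min(k0 + 1, W - 1)
        gx = 0.0
        gy = 0.0
        gz = 0.0
        for c in range(C):
            g = gout[c, m]
            if need_img:
                gimg[c, i0, j0, k0] += (1 - fx) * (1 - fy) * (1 - fz) * g
                gimg[c, i0, j0, k1] += (1 - fx) * (1 - fy) * fz * g
                gimg[c, i0, j1, k0] += (1 - fx) * fy * (1 - fz) * g
                gimg[c, i0, j1, k1] += (1 - fx) * fy * fz * g
                gimg[c, i1, j0, k0] += fx * (1 - fy) * (1 - fz) * g
                gimg[c, i1, j0, k1] += fx * (1 - fy) * fz * g
                gimg[c, i1, j1, k0] += fx * fy * (1 - fz) * g
                gimg[c, i1, j1, k1] += fx * fy * fz * g
            if need_coords:
                v000 = img[c, i0, j0, k0]
                v001 = img[c, i0, j0, k1]
                v010 = img[c, i0, j1, k0]
                v011 = img[c, i0, j1, k1]
                v100 = img[c, i1, j0, k0]
                v101 = img[c, i1, j0, k1]
                v110 = img[c, i1, j1, k0]
                v111 = img[c, i1, j1, k1]
                gx += g * ((1 - fy) * (1 - fz) * (v100 - v000)
                           + (1 - fy) * fz * (v101 - v001)
                           + fy * (1 - fz) * (v110 - v010)
                           + fy * fz * (v111 - v011))
                gy += g * ((1 - fx) * (1 - fz) * (v010 - v000)
                           + (1 - fx) * fz * (v011 - v001)
                           + fx * (1 - fz) * (v110 - v100)
                           + fx * fz * (v111 - v101))
                gz += g * ((1 - fx) * (1 - fy) * (v001 - v000)
                           + (1 - fx) * fy * (v011 - v010)
                           + fx * (1 - fy) * (v101 - v100)
                           + fx * fy * (v111 - v110))
        if need_coords:
            gcoords[0, m] = gx if (cx > 0.0 and cx < D - 1.0) else 0.0
            gcoords[1, m] = gy if (cy > 0.0 and cy < H - 1.0) else 0.0
            gcoords[2, m] = gz if (cz > 0.0 and cz < W - 1.0) else 0.0


# ---------------------------------------------------------------------------
# NumPy fallback (identical semantics)
# ---------------------------------------------------------------------------

def _prep(img_shape, coords):
    spatial = img_shape[1:]
    cl = np.empty_like(coords)
    i0 = np.empty(coords.shape, dtype=np.intp)
    frac = np.empty_like(coords)
    inside = np.empty(coords.shape, dtype=bool)
    for a in range(3):
        hi = spatial[a] - 1
        c = coords[a]
        cla = np.clip(c, 0.0, hi)
        inside[a] = (c > 0.0) & (c < hi)
        ia = np.minimum(np.floor(cla).astype(np.intp), max(spatial[a] - 2, 0))
        cl[a], i0[a], frac[a] = cla, ia, cla - ia
    return i0, frac, inside


def _corners(i0, spatial):
    import itertools

    strides = (spatial[1] * spatial[2], spatial[2], 1)
    i1 = [np.minimum(i0[a] + 1, spatial[a] - 1) for a in range(3)]
    idx = {}
    for bits in itertools.product((0, 1), repeat=3):
        parts = [(i1[a] if bits[a] else i0[a]) * strides[a] for a in range(3)]
        idx[bits] = parts[0] + parts[1] + parts[2]
    return idx


def _trilin_fwd_np(img, coords, out):
    spatial = img.shape[1:]
    i0, frac, _ = _prep(img.shape, coords)
    idx = _corners(i0, spatial)
    w_ax = [(1.0 - frac[a], frac[a]) for a in range(3)]
    flat = img.reshape(img.shape[0], -1)
    out[:] = 0.0
    for bits, ix in idx.items():
        w = w_ax[0][bits[0]] * w_ax[1][bits[1]] * w_ax[2][bits[2]]
        out += w[None, :] * flat[:, ix]


def _trilin_bwd_np(img, coords, gout, gimg, gcoords, need_img, need_coords):
    spatial = img.shape[1:]
    C = img.shape[0]
    i0, frac, inside = _prep(img.shape, coords)
    idx = _corners(i0, spatial)
    w_ax = [(1.0 - frac[a], frac[a]) for a in range(3)]
    flat = img.reshape(C, -1)
    size = flat.shape[1]
    if need_img:
        gflatimg = gimg.reshape(C, -1)
        for bits, ix in idx.items():
            w = w_ax[0][bits[0]] * w_ax[1][bits[1]] * w_ax[2][bits[2]]
            for c in range(C):
                gflatimg[c] += np.bincount(ix, weights=(w * gout[c]).astype(np.float64),
                                           minlength=size).astype(np.float32)
    if need_coords:
        for a in range(3):
            if spatial[a] <= 1:
                gcoords[a] = 0.0
                continue
            acc = np.zeros(coords.shape[1], dtype=np.float32)
            for bits, ix in idx.items():
                sign = 1.0 if bits[a] else -1.0
                w = np.ones(coords.shape[1], dtype=np.float32)
                for b in range(3):
                    if b != a:
                        w = w * w_ax[b][bits[b]]
                acc += sign * np.einsum("n,cn,cn->n", w, flat[:, ix], gout)
            gcoords[a] = np.where(inside[a], acc, 0.0)


def trilinear_forward(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample ``img`` (C, D, H, W) at ``coords`` (3, M); returns (C, M)."""
    out = np.empty((img.shape[0], coords.shape[1]), dtype=np.float32)
    if _HAVE_NUMBA:
        _trilin_fwd_nb(img, coords, out)
    else:
        _trilin_fwd_np(img, coords, out)
    return out


def trilinear_backward(img: np.ndarray, coords: np.ndarray, gout: np.ndarray,
                       need_img: bool, need_coords: bool):
    """Adjoints of :func:`trilinear_forward` w.r.t. image and coordinates."""
    gimg = np.zeros_like(img) if need_img else np.zeros((img.shape[0], 1, 1, 1),
                                                        dtype=np.float32)
    gcoords = (np.zeros_like(coords) if need_coords
               else np.zeros((3, 1), dtype=np.float32))
    if _HAVE_NUMBA:
        _trilin_bwd_nb(img, coords, gout, gimg, gcoords, need_img, need_coords)
    else:
        _trilin_bwd_np(img, coords, gout, gimg, gcoords, need_img, need_coords)
    return (gimg if need_img else None), (gcoords if need_coords else None)
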