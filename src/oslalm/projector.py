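"""Matched forward/back projector pair for parallel-beam 2D CT.

The projector uses exact pixel-intersection lengths (Siddon-style grid
traversal): each sinogram element is the sum of image values weighted by the
chord length of the ray inside each pixel. The system matrix is assembled
once per geometry as a ``scipy.sparse`` CSR matrix (rays x pixels, view-major
ray ordering) and cached, so forward projection is ``A @ x`` and back
projection is the exact adjoint ``A.T @ s`` — the matched pair the iterative
solvers require.

:func:`dense_system_matrix` re-derives the same matrix with a deliberately
naive scalar per-ray loop and serves as the testing oracle for tiny
geometries. It shares the crossing formulas with the fast path so that
measure-zero boundary-riding rays resolve identically.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import Image, ScanGeometry, Sinogram

__all__ = [
    "system_matrix",
    "forward_project",
    "back_project",
    "dense_system_matrix",
    "clear_projector_cache",
]

_CACHE: dict = {}

_BIG = 1.0e12  # sentinel parameter value for crossings that do not exist


def _grid(geom: ScanGeometry):
    p = geom.pixel_size
    xs = (np.arange(geom.n_x + 1) - geom.n_x / 2.0) * p
    ys = (np.arange(geom.n_y + 1) - geom.n_y / 2.0) * p
    return xs, ys


def _view_entries(geom: ScanGeometry, view: int):
    """Sparse entries (bin index, pixel index, length) for one view."""
    phi = geom.view_angles[view]
    c, s = np.cos(phi), np.sin(phi)
    dx, dy = -s, c  # ray direction
    offs = geom.bin_positions()
    x0 = offs * c
    y0 = offs * s
    xs, ys = _grid(geom)
    xmin, xmax = xs[0], xs[-1]
    ymin, ymax = ys[0], ys[-1]

    n_rays = offs.size
    lo = np.full(n_rays, -_BIG)
    hi = np.full(n_rays, _BIG)

    if abs(dx) > 1e-14:
        tx = (xs[:, None] - x0[None, :]) / dx
        lo = np.maximum(lo, np.minimum(tx[0], tx[-1]))
        hi = np.minimum(hi, np.maximum(tx[0], tx[-1]))
    else:
        tx = np.full((xs.size, n_rays), _BIG)
        inside = (x0 >= xmin) & (x0 <= xmax)
        hi = np.where(inside, hi, -_BIG)  # miss: empty interval
    if abs(dy) > 1e-14:
        ty = (ys[:, None] - y0[None, :]) / dy
        lo = np.maximum(lo, np.minimum(ty[0], ty[-1]))
        hi = np.minimum(hi, np.maximum(ty[0], ty[-1]))
    else:
        ty = np.full((ys.size, n_rays), _BIG)
        inside = (y0 >= ymin) & (y0 <= ymax)
        hi = np.where(inside, hi, -_BIG)

    valid = hi > lo
    lo = np.where(valid, lo, 0.0)
    hi = np.where(valid, hi, 0.0)

    t = np.vstack([tx, ty, lo[None, :], hi[None, :]])
    t = np.clip(t, lo[None, :], hi[None, :])
    t.sort(axis=0)
    seg = np.diff(t, axis=0)
    tmid = 0.5 * (t[:-1] + t[1:])
    xm = x0[None, :] + tmid * dx
    ym = y0[None, :] + tmid * dy
    col = np.floor((xm - xmin) / geom.pixel_size).astype(int)
    row = np.floor((ymax - ym) / geom.pixel_size).astype(int)
    ok = (
        (seg > 1e-12)
        & (col >= 0)
        & (col < geom.n_x)
        & (row >= 0)
        & (row < geom.n_y)
        & valid[None, :]
    )
    bins = np.broadcast_to(np.arange(n_rays)[None, :], seg.shape)
    return bins[ok], (row[ok] * geom.n_x + col[ok]), seg[ok]


def system_matrix(geom: ScanGeometry) -> sp.csr_matrix:
    """CSR system matrix (n_views*n_bins rays x n_pixels), cached per geometry."""
    key = geom.cache_key()
    got = _CACHE.get(key)
    if got is not None:
        return got
    rows, cols, vals = [], [], []
    for v in range(geom.n_views):
        b, pix, ln = _view_entries(geom, v)
        rows.append(b + v * geom.n_bins)
        cols.append(pix)
        vals.append(ln)
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_rays, geom.n_pixels),
    ).tocsr()
    _CACHE[key] = A
    return A


def clear_projector_cache() -> None:
    _CACHE.clear()


def _ray_rows(geom: ScanGeometry, views) -> np.ndarray:
    views = np.asarray(views, dtype=int)
    return (views[:, None] * geom.n_bins + np.arange(geom.n_bins)[None, :]).ravel()


def forward_project(image, geom: ScanGeometry, views=None):
    """Line-integral projection ``Mx``.

    Returns a :class:`Sinogram` for the full view set, or a plain
    ``(len(views), n_bins)`` array when restricted to a view subset.
    """
    x = image.values if isinstance(image, Image) else np.asarray(image, dtype=float)
    if x.shape != geom.image_shape:
        raise ValueError(f"image shape {x.shape} does not match geometry {geom.image_shape}")
    A = system_matrix(geom)
    if views is None:
        return Sinogram((A @ x.ravel()).reshape(geom.shape), geom)
    rows = _ray_rows(geom, views)
    return (A[rows] @ x.ravel()).reshape(len(np.atleast_1d(views)), geom.n_bins)


def back_project(sino, geom: ScanGeometry, views=None) -> Image:
    """Adjoint projection ``M' s`` with the same ray model as the forward."""
    s = sino.values if isinstance(sino, Sinogram) else np.asarray(sino, dtype=float)
    A = system_matrix(geom)
    if views is None:
        if s.shape != geom.shape:
            raise ValueError(f"sinogram shape {s.shape} does not match geometry {geom.shape}")
        out = A.T @ s.ravel()
    else:
        views = np.atleast_1d(views)
        if s.shape != (len(views), geom.n_bins):
            raise ValueError("sinogram rows do not match the requested view subset")
        rows = _ray_rows(geom, views)
        out = A[rows].T @ s.ravel()
    return Image(out.reshape(geom.image_shape), geom.pixel_size)


def _dense_ray(geom: ScanGeometry, phi: float, off: float) -> np.ndarray:
    """One dense system-matrix row by a scalar Siddon trace (oracle path)."""
    c, s = np.cos(phi), np.sin(phi)
    dx, dy = -s, c
    x0, y0 = off * c, off * s
    xs, ys = _grid(geom)
    xmin, xmax, ymin, ymax = xs[0], xs[-1], ys[0], ys[-1]
    lo, hi = -_BIG, _BIG
    ts = []
    if abs(dx) > 1e-14:
        tx = [(xv - x0) / dx for xv in xs]
        lo, hi = max(lo, min(tx[0], tx[-1])), min(hi, max(tx[0], tx[-1]))
        ts.extend(tx)
    elif not (xmin <= x0 <= xmax):
        hi = -_BIG
    if abs(dy) > 1e-14:
        ty = [(yv - y0) / dy for yv in ys]
        lo, hi = max(lo, min(ty[0], ty[-1])), min(hi, max(ty[0], ty[-1]))
        ts.extend(ty)
    elif not (ymin <= y0 <= ymax):
        hi = -_BIG
    row = np.zeros(geom.n_pixels)
    if hi <= lo:
        return row
    ts = sorted(min(max(t, lo), hi) for t in ts + [lo, hi])
    for t0, t1 in zip(ts[:-1], ts[1:]):
        seg = t1 - t0
        if seg <= 1e-12:
            continue
        tm = 0.5 * (t0 + t1)
        col = int(np.floor((x0 + tm * dx - xmin) / geom.pixel_size))
        r = int(np.floor((ymax - (y0 + tm * dy)) / geom.pixel_size))
        if 0 <= col < geom.n_x and 0 <= r < geom.n_y:
            row[r * geom.n_x + col] += seg
    return row


def dense_system_matrix(geom: ScanGeometry) -> np.ndarray:
    """Explicit dense system matrix for tiny instances (testing oracle).

    Guarded to ``n_x * n_y * n_views * n_bins <= 1e7`` elements.
    """
    if geom.n_pixels * geom.n_rays > 10**7:
        raise ValueError("dense system matrix guard exceeded (> 1e7 elements)")
    M = np.zeros((geom.n_rays, geom.n_pixels))
    offs = geom.bin_positions()
    for v, phi in enumerate(geom.view_angles):
        for b in range(geom.n_bins):
            M[v * geom.n_bins + b] = _dense_ray(geom, phi, offs[b])
    return M
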