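"""Multilevel B-spline approximation (MBA) of scattered per-unit values.

Smooths point-referenced estimates onto a regular raster by fitting a
coarse-to-fine hierarchy of uniform cubic B-spline control lattices: each
level fits the residuals left by the coarser levels, so the surface sharpens
toward interpolation as levels increase while staying globally smooth.

The data are first detrended with a least-squares affine plane, which the
final surface adds back; constants and planes are therefore reproduced
exactly (to floating-point), and the B-spline hierarchy only models the
spatially structured remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSurface", "interpolate_surface"]


@dataclass
class GridSurface:
    """A raster of interpolated values with its planar bounding box."""

    values: np.ndarray  # (grid_n, grid_n), row 0 at y_min
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    #: root-mean-square residual at the data locations after the final level
    rms_residual: float | None = None

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    @property
    def cell_size(self) -> tuple:
        n = self.grid_n
        return ((self.x_max - self.x_min) / n, (self.y_max - self.y_min) / n)

    def grid_coords(self) -> tuple:
        """Cell-center coordinate vectors (x, y)."""
        cx, cy = self.cell_size
        x = self.x_min + cx * (np.arange(self.grid_n) + 0.5)
        y = self.y_min + cy * (np.arange(self.grid_n) + 0.5)
        return x, y


def _bspline_basis(s: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values B_0..B_3 at local coordinate s in [0,1]."""
    s2, s3 = s * s, s * s * s
    return np.stack(
        [
            (1 - s) ** 3 / 6.0,
            (3 * s3 - 6 * s2 + 4) / 6.0,
            (-3 * s3 + 3 * s2 + 3 * s + 1) / 6.0,
            s3 / 6.0,
        ]
    )


def _cells_and_weights(u: np.ndarray, m: int):
    """Cell index and basis weights for normalized coordinates u in [0, m]."""
    i = np.clip(np.floor(u).astype(int), 0, m - 1)
    return i, _bspline_basis(u - i)


def _ba_fit(u, v, z, m):
    """One BA pass: control lattice (m+3)^2 approximating scattered residuals z."""
    iu, Bu = _cells_and_weights(u, m)
    iv, Bv = _cells_and_weights(v, m)
    delta = np.zeros((m + 3, m + 3))
    omega = np.zeros((m + 3, m + 3))
    # per point: w_kl = B_k(s) B_l(t); phi_c = w * z / sum(w^2)
    w = Bu[:, None, :] * Bv[None, :, :]  # (4, 4, npts)
    wsq = w * w
    s2 = wsq.sum(axis=(0, 1))  # sum of squared weights per point
    contrib = wsq * (w * z / s2)  # = w^2 * phi_c with phi_c = w z / sum(w^2)
    for k in range(4):
        for l in range(4):
            np.add.at(delta, (iu + k, iv + l), contrib[k, l])
            np.add.at(omega, (iu + k, iv + l), wsq[k, l])
    phi = np.divide(delta, omega, out=np.zeros_like(delta), where=omega > 0)
    return phi


def _ba_eval_points(u, v, phi, m):
    iu, Bu = _cells_and_weights(u, m)
    iv, Bv = _cells_and_weights(v, m)
    out = np.zeros_like(u, dtype=float)
    for k in range(4):
        for l in range(4):
            out += Bu[k] * Bv[l] * phi[iu + k, iv + l]
    return out


def interpolate_surface(
    values,
    coords,
    grid_n: int = 300,
    levels: int = 7,
    bbox=None,
    pad_fraction: float = 0.05,
) -> GridSurface:
    """Fit the multilevel B-spline surface and sample it on a square raster.

    Parameters
    ----------
    values, coords
        Scattered per-unit values and their (n, 2) planar coordinates.
    grid_n
        Raster resolution per axis (default 300 x 300).
    levels
        Number of lattice refinement levels; level L uses ``2**(L-1)`` cells
        per axis, so more levels track the data more closely.
    bbox
        ``(x_min, y_min, x_max, y_max)``; defaults to the data extent padded
        by ``pad_fraction`` on each side.
    """
    z = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = len(z)
    if xy.shape != (n, 2) or n < 4:
        raise ValueError("need >= 4 (x, y) points")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), xy])) < 3:
        raise ValueError("points are collinear; cannot fit a surface")

    if bbox is None:
        x0, y0 = xy.min(axis=0)
        x1, y1 = xy.max(axis=0)
        px, py = pad_fraction * (x1 - x0), pad_fraction * (y1 - y0)
        bbox = (x0 - px, y0 - py, x1 + px, y1 + py)
    x_min, y_min, x_max, y_max = map(float, bbox)

    # affine detrend: the lattice hierarchy models only the residual field
    A = np.column_stack([np.ones(n), xy])
    plane, *_ = np.linalg.lstsq(A, z, rcond=None)
    resid = z - A @ plane

    # normalized data coordinates in [0, 1]
    un = (xy[:, 0] - x_min) / (x_max - x_min)
    vn = (xy[:, 1] - y_min) / (y_max - y_min)

    cx = (x_max - x_min) / grid_n
    cy = (y_max - y_min) / grid_n
    gxn = (np.arange(grid_n) + 0.5) / grid_n
    gyn = (np.arange(grid_n) + 0.5) / grid_n

    grid = np.add.outer(
        plane[0] + plane[2] * (y_min + cy * (np.arange(grid_n) + 0.5)),
        plane[1] * (x_min + cx * (np.arange(grid_n) + 0.5)),
    )

    for lev in range(levels):
        m = 2**lev
        phi = _ba_fit(un * m, vn * m, resid, m)
        resid = resid - _ba_eval_points(un * m, vn * m, phi, m)
        # evaluate this level on the raster (rows indexed by y)
        iu, Bu = _cells_and_weights(gxn * m, m)
        iv, Bv = _cells_and_weights(gyn * m, m)
        for k in range(4):
            for l in range(4):
                grid += np.outer(Bv[l], Bu[k]) * phi[np.ix_(iu + k, iv + l)].T
    rms = float(np.sqrt(np.mean(resid**2)))
    return GridSurface(grid, x_min, y_min, x_max, y_max, rms_residual=rms)
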