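"""Voxel grids, world/voxel coordinate handling, and trilinear sampling (SAMP).

An :class:`ImageGrid` couples a 4D array of per-voxel feature channels with a
4x4 voxel-to-world affine (mm).  Integer voxel coordinates sit at voxel
centers; the interpolation cell is the unit cube between adjacent centers.
All tracking mathematics lives in world mm — voxel space is entered only
inside :func:`samp`.

SAMP is the differentiable link between an image grid and a streamline
propagator: gradients with respect to both the sampled point and the grid
values are available (:func:`samp_full`), which is what lets a convolutional
front end be trained end-to-end through the sampling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageGrid",
    "world_to_voxel",
    "voxel_to_world",
    "samp",
    "samp_full",
    "scatter_grid_gradient",
]


@dataclass
class ImageGrid:
    """A 4D (X, Y, Z, C) grid of real-valued channels with a world affine.

    Parameters
    ----------
    data:
        Array of shape (X, Y, Z, C); a 3D array is promoted to C=1.
    affine:
        4x4 invertible voxel-to-world matrix in mm.
    """

    data: np.ndarray
    affine: np.ndarray
    _inv_affine: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ValueError(f"grid data must be 3D or 4D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        try:
            self._inv_affine = np.linalg.inv(self.affine)
        except np.linalg.LinAlgError as e:
            raise ValueError("affine is singular") from e
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_nifti(cls, path) -> "ImageGrid":
        """Load a grid; the affine follows nibabel's precedence (sform
        preferred over qform when both are set), with the dialect logged."""
        import logging

        img = nib.load(str(path))
        hdr = img.header
        try:
            dialect = "sform" if int(hdr["sform_code"]) > 0 else "qform"
        except (KeyError, TypeError):
            dialect = "unknown"
        logging.getLogger("cornn.grids").debug(
            "loaded %s using %s affine", path, dialect
        )
        data = np.asanyarray(img.dataobj).astype(np.float64)
        return cls(data=data, affine=img.affine)

    def to_nifti(self, path) -> None:
        data = self.data[..., 0] if self.n_channels == 1 else self.data
        nib.save(nib.Nifti1Image(np.asarray(data), self.affine), str(path))

    def with_data(self, data: np.ndarray) -> "ImageGrid":
        return ImageGrid(data=data, affine=self.affine.copy())


def world_to_voxel(grid: ImageGrid, points: np.ndarray) -> np.ndarray:
    """Map world-mm point(s) to continuous 0-based voxel coordinates."""
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    v = p @ grid._inv_affine[:3, :3].T + grid._inv_affine[:3, 3]
    return v[0] if np.asarray(points).ndim == 1 else v


def voxel_to_world(grid: ImageGrid, voxels: np.ndarray) -> np.ndarray:
    """Map continuous voxel coordinate(s) to world mm."""
    v = np.atleast_2d(np.asarray(voxels, dtype=np.float64))
    p = v @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return p[0] if np.asarray(voxels).ndim == 1 else p


def _corner_data(grid: ImageGrid, points: np.ndarray):
    """Shared trilinear machinery.

    Returns (corner flat indices (N, 8), weights (N, 8), frac (N, 3),
    lo (N, 3), out_of_bounds (N,)).  Out-of-bounds coordinates are clamped
    to the grid edge and flagged; tracking treats the flag as leaving the
    volume, so sampling itself never raises mid-batch.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    v = pts @ grid._inv_affine[:3, :3].T + grid._inv_affine[:3, 3]
    dims = np.asarray(grid.shape)
    oob = np.any((v < 0) | (v > dims - 1), axis=1)
    v = np.clip(v, 0, dims - 1)
    lo = np.minimum(np.floor(v).astype(np.int64), dims - 2)
    lo = np.maximum(lo, 0)
    frac = v - lo
    # 8 corner offsets in x-fastest order
    offs = np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
    )
    corners = lo[:, None, :] + offs[None, :, :]  # (N, 8, 3)
    w = np.ones((pts.shape[0], 8), dtype=np.float64)
    for ax in range(3):
        f = frac[:, ax][:, None]
        w = w * np.where(offs[None, :, ax] == 1, f, 1.0 - f)
    flat = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), dims
    )
    return flat, w, frac, lo, oob, offs


def samp(grid: ImageGrid, points: np.ndarray):
    """Trilinearly interpolate grid channels at world-mm point(s).

    Returns ``(values, out_of_bounds)``.  For a single 3-vector the value is
    a (C,) vector; for an (N, 3) batch it is (N, C).  Out-of-bounds points
    are clamped to the edge and flagged rather than raising.
    """
    single = np.asarray(points).ndim == 1
    flat, w, _, _, oob, _ = _corner_data(grid, points)
    vals = grid.data.reshape(-1, grid.n_channels)[flat]  # (N, 8, C)
    out = np.einsum("nkc,nk->nc", vals, w)
    if single:
        return out[0], bool(oob[0])
    return out, oob


def samp_full(grid: ImageGrid, points: np.ndarray):
    """SAMP with the pieces needed for differentiation.

    Returns a dict with:

    - ``values`` (N, C): interpolated channels
    - ``oob`` (N,): out-of-bounds flags
    - ``corner_indices`` (N, 8): flat voxel indices into ``data.reshape(-1, C)``
    - ``weights`` (N, 8): trilinear weights (gradient of values w.r.t. the
      corner voxel values — see :func:`scatter_grid_gradient`)
    - ``point_jacobian`` (N, C, 3): d values / d world point (mm^-1)
    """
    flat, w, frac, _, oob, offs = _corner_data(grid, points)
    vals = grid.data.reshape(-1, grid.n_channels)[flat]  # (N, 8, C)
    out = np.einsum("nkc,nk->nc", vals, w)
    # dw/dfrac_ax: replace the ax factor by +/-1
    n = flat.shape[0]
    dvdv = np.empty((n, grid.n_channels, 3))
    for ax in range(3):
        dw = np.ones((n, 8))
        for bx in range(3):
            f = frac[:, bx][:, None]
            if bx == ax:
                dw = dw * np.where(offs[None, :, bx] == 1, 1.0, -1.0)
            else:
                dw = dw * np.where(offs[None, :, bx] == 1, f, 1.0 - f)
        dvdv[:, :, ax] = np.einsum("nkc,nk->nc", vals, dw)
    # chain through voxel = inv_affine @ world
    jac = dvdv @ grid._inv_affine[:3, :3]
    return {
        "values": out,
        "oob": oob,
        "corner_indices": flat,
        "weights": w,
        "point_jacobian": jac,
    }


def scatter_grid_gradient(
    d_values: np.ndarray,
    corner_indices: np.ndarray,
    weights: np.ndarray,
    grid_shape: tuple[int, int, int],
    n_channels: int,
) -> np.ndarray:
    """Backpropagate a gradient w.r.t. sampled values into the grid.

    ``d_values`` is (N, C); the result is a flat (X*Y*Z, C) gradient array
    obtained by scatter-adding ``weights[:, k] * d_values`` at each of the 8
    corners — the exact adjoint of :func:`samp`.
    """
    n_vox = int(np.prod(grid_shape))
    out = np.zeros((n_vox, n_channels), dtype=d_values.dtype)
    contrib = weights[:, :, None] * d_values[:, None, :]  # (N, 8, C)
    np.add.at(out, corner_indices.ravel(), contrib.reshape(-1, n_channels))
    return out
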