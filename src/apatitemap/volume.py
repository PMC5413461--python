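"""Voxelized 3D scalar fields with world geometry.

A :class:`Volume` is the universal image currency of the package: phantom
labels, Hounsfield units, 511-keV attenuation coefficients, SNR maps,
activity images and reconstructions are all carried as volumes with a
``semantics`` tag naming the physical quantity.

Conventions: 0-based voxel indices, voxel-center world coordinates in mm,
axis order (x, y, z) with z the scanner/phantom long axis.  Transaxial
slices are (x, y) planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import ndimage

__all__ = ["Volume", "resample_to", "gaussian_smooth_mm", "centered_grid"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing, origin and value semantics.

    ``origin_mm`` is the world coordinate of the *center* of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semantics: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"Volume requires a 3D grid, got ndim={self.values.ndim}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be positive, got {self.spacing_mm}")
        if any(n < 1 for n in self.values.shape):
            raise ValueError("grid must have at least one voxel per axis")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge-to-edge size of the grid along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the grid center."""
        return np.asarray(self.origin_mm) + (
            (np.asarray(self.shape) - 1) / 2.0
        ) * np.asarray(self.spacing_mm)

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) world-coordinate arrays of voxel centers."""
        x = self.axis_coords_mm(0)[:, None, None]
        y = self.axis_coords_mm(1)[None, :, None]
        z = self.axis_coords_mm(2)[None, None, :]
        return x, y, z

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def like(self, values: np.ndarray, semantics: str | None = None, **meta: Any) -> "Volume":
        """A new volume on this grid carrying different values."""
        out = replace(
            self,
            values=np.asarray(values),
            semantics=self.semantics if semantics is None else semantics,
            meta=dict(self.meta),
        )
        out.meta.update(meta)
        return out


def centered_grid(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    semantics: str = "",
    fill: float = 0.0,
    dtype=np.float64,
) -> Volume:
    """An empty volume whose world origin puts the grid center at (0, 0, 0)."""
    shape = tuple(int(n) for n in shape)
    spacing_mm = tuple(float(s) for s in spacing_mm)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing_mm))
    values = np.full(shape, fill, dtype=dtype)
    return Volume(values, spacing_mm, origin, semantics)


def gaussian_smooth_mm(vol: Volume, fwhm_mm) -> Volume:
    """Gaussian smoothing with a full-width-at-half-maximum given in mm.

    ``fwhm_mm`` may be a scalar (isotropic) or a per-axis triple.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    sigma_vox = fwhm * _FWHM_TO_SIGMA / np.asarray(vol.spacing_mm)
    out = ndimage.gaussian_filter(vol.values.astype(float), sigma=sigma_vox)
    return vol.like(out)


def resample_to(vol: Volume, target: Volume, order: int = 1, cval: float = 0.0) -> Volume:
    """Resample ``vol`` onto the grid of ``target`` by world-coordinate lookup.

    Values outside the source field of view are set to ``cval``.
    """
    coords = [
        (target.axis_coords_mm(a) - vol.origin_mm[a]) / vol.spacing_mm[a]
        for a in range(3)
    ]
    ix = coords[0][:, None, None]
    iy = coords[1][None, :, None]
    iz = coords[2][None, None, :]
    grid = np.broadcast_arrays(ix, iy, iz)
    sampled = ndimage.map_coordinates(
        vol.values.astype(float),
        np.stack([g.ravel() for g in grid]),
        order=order,
        mode="constant",
        cval=cval,
    ).reshape(target.shape)
    out = target.like(sampled, semantics=vol.semantics)
    out.meta = dict(vol.meta)
    return out
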