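"""CT simulation and Hounsfield-to-μ conversion at 511 keV.

CT volumes are simulated in image space: each phantom material receives a
nominal Hounsfield unit, the HU field is blurred to the requested scanner
resolution, resampled onto the CT grid and corrupted with Gaussian noise.
The conversion to 511-keV linear attenuation coefficients uses the standard
bilinear relationship with a water-like branch below a soft-tissue/bone
breakpoint and a shallower bone branch above it, the bone intercept being
fixed by continuity at the breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import bilinear_defaults, defaults
from .volume import Volume, gaussian_smooth_mm, resample_to

__all__ = [
    "BilinearHUmu",
    "simulate_ct",
    "hu_to_mu_511",
    "photoelectric_ratio",
    "material_hu",
]

MU_MAX_CM = 0.3  # upper physical bound enforced on mu-maps (cm^-1)


@dataclass(frozen=True)
class BilinearHUmu:
    """Bilinear HU -> μ(511 keV) model, continuous at the breakpoint.

    Below ``breakpoint_hu``: μ = mu_water_511 * (HU + 1000) / 1000.
    At/above: μ = bone_slope * (HU + 1000) + intercept, with the intercept
    derived from continuity.
    """

    mu_water_511: float
    breakpoint_hu: float
    bone_slope: float

    @classmethod
    def default(cls) -> "BilinearHUmu":
        return cls(*bilinear_defaults())

    @property
    def intercept(self) -> float:
        left = self.mu_water_511 * (self.breakpoint_hu + 1000.0) / 1000.0
        return left - self.bone_slope * (self.breakpoint_hu + 1000.0)

    def __post_init__(self) -> None:
        if self.mu_water_511 <= 0:
            raise ValueError("mu_water_511 must be positive")
        if self.bone_slope < 0:
            raise ValueError("bone_slope must be nonnegative")
        left = self.mu_water_511 * (self.breakpoint_hu + 1000.0) / 1000.0
        right = self.bone_slope * (self.breakpoint_hu + 1000.0) + self.intercept
        assert abs(left - right) < 1e-9

    def mu_of(self, hu) -> np.ndarray:
        """Evaluate the model on an array of Hounsfield units."""
        hu = np.asarray(hu, dtype=float)
        if not np.all(np.isfinite(hu)):
            raise ValueError("non-finite HU values")
        soft = self.mu_water_511 * (hu + 1000.0) / 1000.0
        bone = self.bone_slope * (hu + 1000.0) + self.intercept
        mu = np.where(hu < self.breakpoint_hu, soft, bone)
        return np.clip(mu, 0.0, MU_MAX_CM)


def material_hu() -> dict[str, float]:
    """Nominal Hounsfield units per phantom material name."""
    return {k: float(v) for k, v in defaults()["hounsfield"].items()}


def simulate_ct(
    phantom,
    resolution_mm=(0.86, 0.86, 0.796),
    noise_sd_hu: float = 20.0,
    seed: int = 0,
) -> Volume:
    """Simulate a CT scan of a phantom, returning an HU volume.

    The material-wise HU field is blurred with a Gaussian point spread of
    FWHM ``resolution_mm`` (per axis) on the phantom grid, sampled onto a
    CT grid of that voxel size covering the phantom field of view, and
    Gaussian noise of sd ``noise_sd_hu`` is added.  Values are floored at
    the air HU of -1000.
    """
    from .phantoms import MATERIAL_NAMES  # local import to avoid a cycle

    resolution_mm = tuple(float(r) for r in np.broadcast_to(resolution_mm, (3,)))
    if any(r <= 0 for r in resolution_mm):
        raise ValueError(f"CT resolution must be positive, got {resolution_mm}")

    hu_table = material_hu()
    labels = phantom.labels
    hu_fine = np.full(labels.shape, hu_table["air"], dtype=float)
    codes = labels.values.astype(int)
    for code, name in MATERIAL_NAMES.items():
        if name != "air":
            hu_fine[codes == code] = hu_table[name]
    fine = labels.like(hu_fine, semantics="HU")
    blurred = gaussian_smooth_mm(fine, resolution_mm)

    shape = tuple(
        max(1, int(np.ceil(e / r)))
        for e, r in zip(labels.extent_mm, resolution_mm)
    )
    origin = tuple(
        c - (n - 1) / 2.0 * r
        for c, n, r in zip(labels.center_mm, shape, resolution_mm)
    )
    target = Volume(np.zeros(shape), resolution_mm, origin, semantics="HU")
    ct = resample_to(blurred, target, order=1, cval=hu_table["air"])

    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        ct.values = ct.values + rng.normal(0.0, noise_sd_hu, size=ct.shape)
    ct.values = np.maximum(ct.values, -1000.0)
    ct.semantics = "HU"
    ct.meta = {"resolution_mm": resolution_mm, "noise_sd_hu": noise_sd_hu, "seed": seed}
    return ct


def hu_to_mu_511(hu: Volume, model: BilinearHUmu | None = None) -> Volume:
    """Convert a Hounsfield-unit volume into a 511-keV μ-map (cm⁻¹)."""
    if model is None:
        model = BilinearHUmu.default()
    mu = model.mu_of(hu.values)
    out = hu.like(mu, semantics="mu_cm^-1")
    out.meta["hu_mu_model"] = {
        "mu_water_511": model.mu_water_511,
        "breakpoint_hu": model.breakpoint_hu,
        "bone_slope": model.bone_slope,
    }
    return out


def photoelectric_ratio(z_a: int, z_b: int) -> float:
    """Relative photoelectric attenuation of two elements, (Z_a / Z_b)^4.

    Photon interactions with mineral bone are photoelectric-dominated, for
    which μ scales as Z^4; calcium (Z=20) therefore attenuates ~3x as much
    per atom as phosphorus (Z=15).
    """
    if z_a < 1 or z_b < 1:
        raise ValueError("atomic numbers must be >= 1")
    return float((z_a / z_b) ** 4)
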