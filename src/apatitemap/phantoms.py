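"""Seeded digital phantoms: calibration bone sample and rat head.

Two phantoms drive the synthetic experiments:

* a U-shaped cortical-bone sample resting on a saline-filled tube, with a
  small plastic spacer inside the U — the calibration object;
* a rat head: an ellipsoidal brain with uniform activity, enclosed by a
  thin cortical-bone skull shell, wrapped in a muscle layer, with a
  soft-tissue neck/jaw block attached so the head sits on realistic
  amounts of liquid-state ³¹P-bearing tissue.

Each phantom carries co-registered label, hydroxyapatite-³¹P, mobile-³¹P,
activity and ground-truth μ volumes on one grid.  Labels are assigned by
supersampling each voxel (3³ sub-points, majority-by-priority), which keeps
voxelized volumes within a few percent of the analytic geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .config import defaults
from .ct_mu import BilinearHUmu, material_hu
from .volume import Volume, centered_grid

__all__ = [
    "MATERIALS",
    "MATERIAL_NAMES",
    "PhantomSpec",
    "BoneSampleSpec",
    "RatHeadSpec",
    "Phantom",
    "make_bone_sample_phantom",
    "make_rat_head_phantom",
    "p31_concentration",
]

# Material codes of the label volume.
MATERIALS: dict[str, int] = {
    "air": 0,
    "saline": 1,
    "soft_tissue": 2,
    "muscle": 3,
    "brain": 4,
    "cortical_bone": 5,
    "plastic": 6,
}
MATERIAL_NAMES = {v: k for k, v in MATERIALS.items()}

_SUPERSAMPLE = 3  # sub-points per voxel edge for label assignment


def p31_concentration(
    density_g_per_l: float, molar_mass_g_per_mol: float, n_p_atoms: int
) -> float:
    """³¹P concentration (mol/L) of a mineral from density and molar mass.

    For hydroxyapatite (402 g/mol per three phosphorus atoms, 3800 g/L in
    cortical bone) this gives ~28.4 mol/L, i.e. ~30 mol/L at one significant
    figure — several orders of magnitude above the mmol/L of PCr/ATP.
    """
    if density_g_per_l <= 0 or molar_mass_g_per_mol <= 0 or n_p_atoms <= 0:
        raise ValueError("all arguments must be positive")
    return n_p_atoms * density_g_per_l / molar_mass_g_per_mol


@dataclass
class PhantomSpec:
    """Common grid/composition parameters of a digital phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 0.7
    apatite_p31_mol_per_l: float | None = None  # default from config
    seed: int = 0

    def resolve_apatite(self) -> float:
        if self.apatite_p31_mol_per_l is not None:
            return float(self.apatite_p31_mol_per_l)
        return float(defaults()["composition"]["apatite_p31_mol_per_l"])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"kind": type(self).__name__, **asdict(self)}, fh)

    @staticmethod
    def from_yaml(path) -> "PhantomSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        kind = data.pop("kind", "RatHeadSpec")
        cls = {"BoneSampleSpec": BoneSampleSpec, "RatHeadSpec": RatHeadSpec}[kind]
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        if "head_dims_mm" in data:
            data["head_dims_mm"] = tuple(data["head_dims_mm"])
        return cls(**data)


@dataclass
class BoneSampleSpec(PhantomSpec):
    """Geometry of the U-shaped cortical-bone calibration sample.

    The sample geometry beyond its ~8 mm largest dimension is a modeling
    choice; defaults are recorded here and in the packaged config.  The
    default grid is finer than the rat head's (0.5 mm) so the 1.5 mm limbs
    voxelize exactly.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 0.5
    outer_span_mm: float = 8.0     # U outer width (x) = largest dimension
    height_mm: float = 8.0         # U outer height (y)
    depth_mm: float = 8.0          # U extent along the tube axis (z)
    limb_thickness_mm: float = 1.5
    tube_radius_mm: float = 6.0
    tube_length_mm: float = 30.0
    plastic_spacer: bool = True

    def analytic_bone_volume_mm3(self) -> float:
        """Closed-form volume of the U shell (outer box minus cavity)."""
        t = self.limb_thickness_mm
        outer = self.outer_span_mm * self.height_mm * self.depth_mm
        cavity = (
            max(self.outer_span_mm - 2 * t, 0.0)
            * max(self.height_mm - t, 0.0)
            * self.depth_mm
        )
        return outer - cavity


@dataclass
class RatHeadSpec(PhantomSpec):
    """Geometry/composition of the synthetic rat head.

    The head is an ellipsoid of ``head_dims_mm`` (x, y, z; z is the long
    axis, default 25 mm as the largest skull dimension), containing, from
    the outside in: a muscle layer, the cortical-bone skull shell
    (default 0.7 mm) and the brain.  A soft-tissue neck cylinder and jaw
    block attach the head to the caudal/ventral grid boundary.
    """

    head_dims_mm: tuple[float, float, float] = (20.0, 20.0, 25.0)
    muscle_thickness_mm: float = 2.0
    skull_thickness_mm: float = 0.7
    skull_base_gap_mm: float = 0.0   # >0 opens the ventral skull base
    include_neck: bool = True
    neck_radius_mm: float = 10.0
    neck_end_z_mm: float = -10.0
    include_jaw: bool = True
    brain_activity_per_ml: float = 100.0
    mobile_brain_mmol_per_l: float | None = None
    mobile_muscle_mmol_per_l: float | None = None
    mobile_soft_tissue_mmol_per_l: float | None = None

    def resolve_mobile(self) -> dict[str, float]:
        comp = defaults()["composition"]
        return {
            "brain": float(
                self.mobile_brain_mmol_per_l
                if self.mobile_brain_mmol_per_l is not None
                else comp["mobile_brain_mmol_per_l"]
            ),
            "muscle": float(
                self.mobile_muscle_mmol_per_l
                if self.mobile_muscle_mmol_per_l is not None
                else comp["mobile_muscle_mmol_per_l"]
            ),
            "soft_tissue": float(
                self.mobile_soft_tissue_mmol_per_l
                if self.mobile_soft_tissue_mmol_per_l is not None
                else comp["mobile_soft_tissue_mmol_per_l"]
            ),
        }

    def brain_semi_axes_mm(self) -> tuple[float, float, float]:
        inset = self.muscle_thickness_mm + self.skull_thickness_mm
        return tuple(d / 2.0 - inset for d in self.head_dims_mm)

    def analytic_brain_volume_mm3(self) -> float:
        a, b, c = self.brain_semi_axes_mm()
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class Phantom:
    """Co-registered label, composition, activity and ground-truth μ volumes."""

    labels: Volume                  # material codes (MATERIALS)
    apatite_p31_molar: Volume       # mol/L of ³¹P bound in hydroxyapatite
    mobile_p31_molar: Volume        # mol/L of mobile ³¹P (PCr+ATP+Pi lumped)
    activity: Volume                # activity concentration, arb. units/mL
    mu_true: Volume                 # ground-truth μ at 511 keV, cm⁻¹
    spec: PhantomSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for vol in (self.apatite_p31_molar, self.mobile_p31_molar,
                    self.activity, self.mu_true):
            if not self.labels.same_grid(vol):
                raise ValueError("phantom component grids do not match")

    def mask(self, material: str) -> np.ndarray:
        return self.labels.values.astype(int) == MATERIALS[material]

    def material_volume_mm3(self, material: str) -> float:
        return float(self.mask(material).sum()) * self.labels.voxel_volume_mm3

    def total_apatite_mol(self) -> float:
        return float(self.apatite_p31_molar.values.sum()) * self.labels.voxel_volume_mm3 * 1e-6

    def total_mobile_mol(self) -> float:
        return float(self.mobile_p31_molar.values.sum()) * self.labels.voxel_volume_mm3 * 1e-6

    @property
    def extent_mm(self):
        return self.labels.extent_mm


# ---------------------------------------------------------------------------
# label assignment by supersampling


def _fine_coords(grid: Volume):
    """Supersampled voxel-center coordinates; each voxel -> 3 sub-points/axis."""
    f = _SUPERSAMPLE
    coords = []
    for a in range(3):
        c = grid.axis_coords_mm(a)
        offs = (np.arange(f) - (f - 1) / 2.0) / f * grid.spacing_mm[a]
        coords.append((c[:, None] + offs[None, :]).ravel())
    return coords


def _reduce_fraction(fine_mask: np.ndarray, shape) -> np.ndarray:
    f = _SUPERSAMPLE
    m = fine_mask.reshape(shape[0], f, shape[1], f, shape[2], f)
    return m.mean(axis=(1, 3, 5))


def _mu_table() -> dict[str, float]:
    """Ground-truth μ per material: water-equivalent soft tissues, bone and
    plastic pushed through the default bilinear model for CT consistency."""
    mu_cfg = defaults()["mu_true"]
    model = BilinearHUmu.default()
    hu = material_hu()
    water = float(mu_cfg["water"])
    return {
        "air": float(mu_cfg["air"]),
        "saline": water,
        "soft_tissue": water,
        "muscle": water,
        "brain": water,
        "cortical_bone": float(model.mu_of(hu["cortical_bone"])),
        "plastic": float(model.mu_of(hu["plastic"])),
    }


def _assemble(labels_int: np.ndarray, grid: Volume, spec: PhantomSpec,
              mobile_molar: np.ndarray, activity: np.ndarray) -> Phantom:
    labels = grid.like(labels_int.astype(np.int16), semantics="labels")
    apatite = np.where(
        labels_int == MATERIALS["cortical_bone"], spec.resolve_apatite(), 0.0
    )
    mu_tab = _mu_table()
    mu = np.zeros(grid.shape)
    for code, name in MATERIAL_NAMES.items():
        mu[labels_int == code] = mu_tab[name]
    return Phantom(
        labels=labels,
        apatite_p31_molar=grid.like(apatite, semantics="apatite_p31_mol_per_l"),
        mobile_p31_molar=grid.like(mobile_molar, semantics="mobile_p31_mol_per_l"),
        activity=grid.like(activity, semantics="activity"),
        mu_true=grid.like(mu, semantics="mu_cm^-1"),
        spec=spec,
    )


def make_bone_sample_phantom(spec: BoneSampleSpec | None = None) -> Phantom:
    """The U-shaped cortical-bone sample on a saline-filled tube.

    The inverted U (open side down) sits with its base at y = 0 on top of
    the tube; a plastic spacer occupies the cavity.  Raises if any stated
    dimension does not fit the grid.
    """
    spec = spec or BoneSampleSpec()
    grid = centered_grid(spec.grid_shape, (spec.spacing_mm,) * 3)
    ext = grid.extent_mm
    checks = {
        "outer_span_mm (x)": (spec.outer_span_mm, ext[0]),
        "height_mm + 2*tube_radius_mm (y)": (
            spec.height_mm + 2 * spec.tube_radius_mm, ext[1]),
        "max(depth_mm, tube_length_mm) (z)": (
            max(spec.depth_mm, spec.tube_length_mm), ext[2]),
    }
    for name, (need, have) in checks.items():
        if need > have:
            raise ValueError(
                f"geometry exceeds grid: {name} = {need:.1f} mm "
                f"> grid extent {have:.1f} mm"
            )

    xs, ys, zs = _fine_coords(grid)
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]

    t = spec.limb_thickness_mm
    hx = spec.outer_span_mm / 2.0
    in_outer = (np.abs(x) <= hx) & (y >= 0) & (y <= spec.height_mm) & (
        np.abs(z) <= spec.depth_mm / 2.0
    )
    in_cavity = (np.abs(x) <= max(hx - t, 0.0)) & (y >= 0) & (
        y <= max(spec.height_mm - t, 0.0)
    ) & (np.abs(z) <= spec.depth_mm / 2.0)
    bone = in_outer & ~in_cavity

    r = spec.tube_radius_mm
    tube = (x**2 + (y + r) ** 2 <= r**2) & (np.abs(z) <= spec.tube_length_mm / 2.0)

    plastic = np.zeros_like(bone)
    if spec.plastic_spacer and t > 0:
        plastic = (
            (np.abs(x) <= max(hx - t, 0.0) * 0.6)
            & (y >= 0) & (y <= spec.height_mm * 0.4)
            & (np.abs(z) <= spec.depth_mm / 4.0)
        )

    shape = grid.shape
    labels = np.zeros(shape, dtype=np.int16)
    # priority: bone over plastic over saline
    for name, mask in (("saline", tube), ("plastic", plastic),
                       ("cortical_bone", bone)):
        frac = _reduce_fraction(mask.astype(np.float32), shape)
        labels[frac >= 0.5] = MATERIALS[name]

    mobile = np.zeros(shape)
    activity = np.zeros(shape)
    return _assemble(labels, grid, spec, mobile, activity)


def make_rat_head_phantom(spec: RatHeadSpec | None = None) -> Phantom:
    """The rat-head phantom: brain + skull shell + muscle + neck/jaw.

    A skull shell thinner than the voxel spacing is accepted (partial-volume
    regime) with a recorded warning rather than an error.
    """
    spec = spec or RatHeadSpec()
    grid = centered_grid(spec.grid_shape, (spec.spacing_mm,) * 3)
    ext = grid.extent_mm
    for a, name in enumerate("xyz"):
        if spec.head_dims_mm[a] > ext[a]:
            raise ValueError(
                f"geometry exceeds grid: head_dims_mm[{name}] = "
                f"{spec.head_dims_mm[a]:.1f} mm > grid extent {ext[a]:.1f} mm"
            )
    if spec.skull_thickness_mm < 0 or spec.muscle_thickness_mm < 0:
        raise ValueError("thicknesses must be nonnegative")
    if 0 < spec.skull_thickness_mm < spec.spacing_mm:
        warnings.warn(
            "skull shell thinner than the voxel spacing: partial-volume regime",
            stacklevel=2,
        )

    xs, ys, zs = _fine_coords(grid)
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]

    def ellipsoid(semi):
        a, b, c = (max(s, 1e-9) for s in semi)
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0

    head_semi = tuple(d / 2.0 for d in spec.head_dims_mm)
    skull_semi = tuple(s - spec.muscle_thickness_mm for s in head_semi)
    brain_semi = spec.brain_semi_axes_mm()

    in_head = ellipsoid(head_semi)
    in_skull_outer = ellipsoid(skull_semi)
    in_brain = ellipsoid(brain_semi)

    def frac(mask):
        return _reduce_fraction(mask.astype(np.float32), grid.shape)

    shape = grid.shape
    labels = np.zeros(shape, dtype=np.int16)

    if spec.include_neck:
        neck = (x**2 + y**2 <= spec.neck_radius_mm**2) & (z <= spec.neck_end_z_mm)
        labels[frac(neck) >= 0.5] = MATERIALS["soft_tissue"]
    if spec.include_jaw:
        jaw = (
            (np.abs(x) <= 0.4 * spec.head_dims_mm[0])
            & (y <= -0.3 * spec.head_dims_mm[1])
            & (y >= -0.8 * spec.head_dims_mm[1])
            & (z >= 0.0)
            & (z <= 0.55 * spec.head_dims_mm[2])
        )
        labels[frac(jaw) >= 0.5] = MATERIALS["soft_tissue"]

    labels[frac(in_head) >= 0.5] = MATERIALS["muscle"]
    bone = in_skull_outer & ~in_brain
    if spec.skull_base_gap_mm > 0:
        bone = bone & ~(y <= -(skull_semi[1] - spec.skull_base_gap_mm))
    labels[frac(bone) >= 0.5] = MATERIALS["cortical_bone"]
    labels[frac(in_brain) >= 0.5] = MATERIALS["brain"]

    mobile_mmol = spec.resolve_mobile()
    mobile = np.zeros(shape)
    mobile[labels == MATERIALS["brain"]] = mobile_mmol["brain"] * 1e-3
    mobile[labels == MATERIALS["muscle"]] = mobile_mmol["muscle"] * 1e-3
    mobile[labels == MATERIALS["soft_tissue"]] = mobile_mmol["soft_tissue"] * 1e-3

    activity = np.zeros(shape)
    activity[labels == MATERIALS["brain"]] = spec.brain_activity_per_ml

    return _assemble(labels, grid, spec, mobile, activity)
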