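"""Configuration, NIfTI I/O, and the end-to-end experiment runner.

``run_experiment`` chains the whole protocol: bone-sample calibration
(ZTE + CT -> conversion factor k), in-vivo rat-head simulation (ZTE, CT,
PET), construction of the three attenuation maps (CT-based,
bone-neglecting, ³¹P-based), OSEM reconstruction under each, and the
metric report.  Every stage is seeded from one master seed by a documented
scheme, so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import calibration as cal
from . import ct_mu, metrics, pet_ac, zte_sim
from .config import defaults
from .phantoms import BoneSampleSpec, RatHeadSpec, make_bone_sample_phantom, make_rat_head_phantom
from .volume import Volume, resample_to

__all__ = [
    "ExperimentConfig",
    "read_volume",
    "write_volume",
    "run_experiment",
    "make_figures",
    "stage_seed",
]

log = logging.getLogger("apatitemap")


# ---------------------------------------------------------------------------
# volumetric I/O


def write_volume(vol: Volume, path) -> None:
    """Write a volume as NIfTI (float64) with a JSON sidecar for metadata."""
    path = Path(path)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing_mm
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), affine)
    nib.save(img, path)
    # the sidecar carries the exact grid geometry: NIfTI stores the affine
    # in float32, which would round the spacings
    sidecar = {
        "semantics": vol.semantics,
        "spacing_mm": list(vol.spacing_mm),
        "origin_mm": list(vol.origin_mm),
        "meta": _jsonable(vol.meta),
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_volume(path) -> Volume:
    """Read a NIfTI volume written by :func:`write_volume` (or compatible)."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise ValueError(f"cannot read volume file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim} dimensions"
        )
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing in affine")
    origin = tuple(float(affine[i, 3]) for i in range(3))
    semantics = ""
    meta: dict = {}
    sidecar = path.with_suffix("").with_suffix(".json")
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        semantics = payload.get("semantics", "")
        meta = payload.get("meta", {})
        if "spacing_mm" in payload:
            spacing = tuple(float(s) for s in payload["spacing_mm"])
        if "origin_mm" in payload:
            origin = tuple(float(o) for o in payload["origin_mm"])
    return Volume(data, spacing, origin, semantics, meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ExperimentConfig:
    """All parameters of the end-to-end experiment, YAML-serializable."""

    bone_sample: BoneSampleSpec = field(default_factory=BoneSampleSpec)
    rat_head: RatHeadSpec = field(default_factory=RatHeadSpec)
    zte_calibration: zte_sim.ZTEParams = field(
        default_factory=lambda: zte_sim.ZTEParams(n_averages=96)
    )
    zte_invivo: zte_sim.ZTEParams = field(
        default_factory=lambda: zte_sim.ZTEParams(n_averages=16)
    )
    ct_resolution_mm: tuple[float, float, float] = (0.86, 0.86, 0.796)
    ct_noise_sd_hu: float = 20.0
    ct_bone_threshold_hu: float = 300.0
    pet_total_counts: int = 2_000_000
    n_angles: int = 96
    n_subsets: int = 4
    n_iterations: int = 8
    snr_floor_calibration: float = 3.0
    snr_floor_mu31p: float = 5.0
    rim_voxels: int = 2
    master_seed: int = 1

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_subsets < 1 or self.n_angles % self.n_subsets != 0:
            raise ValueError("n_subsets must divide n_angles")
        if self.pet_total_counts <= 0:
            raise ValueError("pet_total_counts must be positive")
        if self.rim_voxels < 1:
            raise ValueError("rim_voxels must be >= 1")
        if any(r <= 0 for r in self.ct_resolution_mm):
            raise ValueError("ct_resolution_mm must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        kwargs = dict(data)
        if "bone_sample" in kwargs:
            kwargs["bone_sample"] = BoneSampleSpec(**_tupled(kwargs["bone_sample"]))
        if "rat_head" in kwargs:
            kwargs["rat_head"] = RatHeadSpec(**_tupled(kwargs["rat_head"]))
        for key in ("zte_calibration", "zte_invivo"):
            if key in kwargs:
                kwargs[key] = zte_sim.ZTEParams(**kwargs[key])
        if "ct_resolution_mm" in kwargs:
            kwargs["ct_resolution_mm"] = tuple(kwargs["ct_resolution_mm"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        text = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return f"{zlib.crc32(text.encode()):08x}"


def _tupled(d: dict) -> dict:
    out = dict(d)
    for key in ("grid_shape", "head_dims_mm"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: crc32 of the stage name folded with the master seed,
    reduced below 2^31."""
    return int((master_seed * 100003 + zlib.crc32(stage.encode())) % (2**31 - 1))


# ---------------------------------------------------------------------------
# experiment runner


def _save(outdir: Path | None, name: str, vol: Volume) -> None:
    if outdir is not None:
        write_volume(vol, outdir / f"{name}.nii.gz")


def run_experiment(
    config: ExperimentConfig | None = None,
    outdir=None,
    keep_volumes: bool = False,
):
    """Run the full synthetic protocol and return a ComparisonReport.

    When ``outdir`` is given, all intermediates (NIfTI volumes, calibration
    JSON, config snapshot, report) are written as they are produced, so a
    failed stage leaves its partial outputs behind.  With ``keep_volumes``
    the function returns ``(report, volumes)`` where ``volumes`` maps stage
    names to in-memory results (used for figure generation).
    """
    config = config or ExperimentConfig()
    config.validate()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    seed = config.master_seed
    volumes: dict[str, object] = {}

    stage = "calibration"
    try:
        log.info("stage %s", stage)
        bone_ph = make_bone_sample_phantom(config.bone_sample)
        target = float(defaults()["snr_targets"]["bone_sample"])
        params = dataclasses.replace(
            config.zte_calibration,
            noise_sd=zte_sim.calibrate_noise_sd(bone_ph, config.zte_calibration, target),
            seed=stage_seed(seed, "zte_calibration"),
        )
        zte_cal = zte_sim.simulate_zte(bone_ph, params)
        snr_cal = cal.snr_map(zte_cal, zte_sim.default_noise_roi(zte_cal))
        ct_cal = ct_mu.simulate_ct(
            bone_ph, config.ct_resolution_mm, config.ct_noise_sd_hu,
            seed=stage_seed(seed, "ct_calibration"),
        )
        mu_cal = ct_mu.hu_to_mu_511(ct_cal)
        # calibration runs on the CT grid: native-resolution μ, smooth SNR
        # field interpolated up; registration ground truth is identity
        snr_on_ct, _ = cal.rigid_register(snr_cal.vol, ct_cal, cal.RigidTransform())
        snr_on_ct = cal.SNRVolume(
            snr_on_ct, snr_cal.noise_sd, snr_cal.noise_roi_voxels,
            snr_cal.acquisition_time_s,
        )
        bone_mask = ct_cal.values > config.ct_bone_threshold_hu
        calib = cal.estimate_conversion_factor(
            mu_cal, snr_on_ct, bone_mask, snr_floor=config.snr_floor_calibration
        )
        _save(outdir, "calib_zte", zte_cal)
        _save(outdir, "calib_ct", ct_cal)
        _save(outdir, "calib_mu_ct", mu_cal)
        if outdir is not None:
            (outdir / "calibration.json").write_text(json.dumps({
                "k": calib.k, "k_sd": calib.k_sd, "n_voxels": calib.n_voxels,
                "t_ref_s": calib.t_ref_s, "provenance": calib.provenance,
            }, indent=2))
        volumes.update({"calib_zte": zte_cal, "calib_ct": ct_cal,
                        "calibration": calib, "bone_phantom": bone_ph})
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    stage = "invivo_imaging"
    try:
        log.info("stage %s", stage)
        head_ph = make_rat_head_phantom(config.rat_head)
        target = float(defaults()["snr_targets"]["rat_head_skull"])
        params_viv = dataclasses.replace(
            config.zte_invivo,
            noise_sd=zte_sim.calibrate_noise_sd(head_ph, config.zte_invivo, target),
            seed=stage_seed(seed, "zte_invivo"),
        )
        zte_viv = zte_sim.simulate_zte(head_ph, params_viv)
        snr_viv = cal.snr_map(zte_viv, zte_sim.default_noise_roi(zte_viv))
        ct_viv = ct_mu.simulate_ct(
            head_ph, config.ct_resolution_mm, config.ct_noise_sd_hu,
            seed=stage_seed(seed, "ct_invivo"),
        )
        _save(outdir, "invivo_zte", zte_viv)
        _save(outdir, "invivo_ct", ct_viv)
        volumes.update({"head_phantom": head_ph, "invivo_zte": zte_viv,
                        "invivo_snr": snr_viv, "invivo_ct": ct_viv})
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    stage = "mu_maps"
    try:
        log.info("stage %s", stage)
        grid = head_ph.labels
        mu_ct_viv = ct_mu.hu_to_mu_511(ct_viv)
        ct_ac, _ = cal.rigid_register(mu_ct_viv, grid, cal.RigidTransform())
        ct_ac.values[ct_ac.values < 0.005] = 0.0  # clamp air noise
        ct_ac.semantics = "mu_cm^-1"
        nobone = cal.nobone_mu_map(head_ph.labels)
        mu31 = cal.p31_mu_map(snr_viv, calib, snr_floor=config.snr_floor_mu31p)
        mu31_on_grid = resample_to(mu31, grid, order=1)
        p31_ac = cal.p31_ac_mu_map(nobone, mu31_on_grid)
        _save(outdir, "mu_ct_ac", ct_ac)
        _save(outdir, "mu_nobone_ac", nobone)
        _save(outdir, "mu_31p", mu31_on_grid)
        _save(outdir, "mu_31p_ac", p31_ac)
        volumes.update({"mu_ct_ac": ct_ac, "mu_nobone_ac": nobone,
                        "mu_31p": mu31_on_grid, "mu_31p_ac": p31_ac})
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    stage = "pet_reconstruction"
    try:
        log.info("stage %s", stage)
        geometry = pet_ac.ProjGeometry(
            n_angles=config.n_angles,
            n_bins=head_ph.labels.shape[0],
            bin_spacing_mm=head_ph.labels.spacing_mm[0],
        )
        prompts = pet_ac.simulate_pet_counts(
            head_ph.activity, head_ph.mu_true, geometry,
            config.pet_total_counts, seed=stage_seed(seed, "pet_counts"),
        )
        recons = {}
        for name, mu_map in (("CT-AC", ct_ac), ("NoBone-AC", nobone),
                             ("31P-AC", p31_ac)):
            acf = pet_ac.attenuation_factors(mu_map, geometry)
            recons[name] = pet_ac.osem2d(
                prompts, acf, geometry,
                n_subsets=config.n_subsets, n_iterations=config.n_iterations,
            )
            _save(outdir, f"recon_{name.replace('-', '_')}", recons[name])
        volumes["recons"] = recons
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    stage = "metrics"
    try:
        log.info("stage %s", stage)
        roi = metrics.peripheral_brain_roi(head_ph, config.rim_voxels)
        dice_res = metrics.skull_dice_experiment(snr_viv, ct_viv)
        report = metrics.compare_ac_methods(
            recons, roi,
            skull_masks=(dice_res["mask_zte"], dice_res["mask_ct"]),
            provenance={
                "config_hash": config.config_hash(),
                "master_seed": seed,
                "k": calib.k,
                "k_sd": calib.k_sd,
                "calibration": dict(calib.provenance, n_voxels=calib.n_voxels),
                "dice_rule": dice_res["rule"],
            },
        )
        if outdir is not None:
            report.to_json(outdir / "report.json")
            report.summary_table().to_csv(outdir / "summary.tsv", sep="\t", index=False)
        volumes["dice"] = dice_res
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    if keep_volumes:
        return report, volumes
    return report


# ---------------------------------------------------------------------------
# figures


def make_figures(report, volumes: dict, outdir) -> list[Path]:
    """Render overlay, three-panel PET and ROI bar-chart figures.

    Missing volumes skip their panel with a logged warning rather than
    failing the run.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def central_slice(vol: Volume, axis: int = 2) -> np.ndarray:
        k = vol.shape[axis] // 2
        return np.take(vol.values, k, axis=axis).T

    def fusion(name, anat_key, p31_key, title):
        if anat_key not in volumes or p31_key not in volumes:
            log.warning("figure %s skipped: missing %s/%s", name, anat_key, p31_key)
            return
        anat = volumes[anat_key]
        p31 = volumes[p31_key]
        p31_res = resample_to(p31.vol if hasattr(p31, "vol") else p31, anat)
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(central_slice(anat), cmap="gray", origin="lower")
        overlay = central_slice(p31_res)
        ax.imshow(np.ma.masked_less(overlay, 0.3 * overlay.max() + 1e-12),
                  cmap="hot", alpha=0.6, origin="lower")
        ax.set_title(title)
        ax.axis("off")
        p = outdir / f"{name}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    fusion("fusion_bone_sample", "calib_ct", "calib_zte",
           "bone sample: CT + ³¹P-ZTE")
    fusion("fusion_rat_head", "invivo_ct", "invivo_zte",
           "rat head: CT + ³¹P-ZTE")

    recons = volumes.get("recons", {})
    if recons:
        fig, axes = plt.subplots(1, len(recons), figsize=(4 * len(recons), 4))
        vmax = max(float(v.values.max()) for v in recons.values())
        for ax, (name, vol) in zip(np.atleast_1d(axes), recons.items()):
            ax.imshow(central_slice(vol), cmap="magma", vmin=0, vmax=vmax,
                      origin="lower")
            ax.set_title(name)
            ax.axis("off")
        p = outdir / "pet_three_panel.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    else:
        log.warning("figure pet_three_panel skipped: no reconstructions")

    if report is not None and report.roi_stats:
        names = list(report.roi_stats)
        means = [report.roi_stats[n]["mean"] for n in names]
        sds = [report.roi_stats[n]["sd"] for n in names]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(names, means, yerr=sds, color=["#777", "#59c", "#c55"][: len(names)])
        for i, n in enumerate(names):
            p_val = report.t_tests.get(n, {}).get("p")
            if p_val is not None and p_val < 0.001:
                ax.text(i, means[i] + sds[i], "*", ha="center", fontsize=16)
        ax.set_ylabel("peripheral-brain ROI activity (arb/mL)")
        p = outdir / "roi_barchart.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    return written
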