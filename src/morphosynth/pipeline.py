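"""End-to-end orchestration: phantom -> map fitting -> synthesis ->
contrast -> morphometry -> cohort GLM, reproducibly from one config + seed.

Every stage writes its artifacts under the output directory and registers
them in a manifest with SHA-256 checksums; re-running with the same config
and seed reproduces the manifest bit-for-bit. A stage failure raises
:class:`StageError` naming the stage, after writing the partial manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import contrast as contrast_mod
from . import glm as glm_mod
from .map_estimation import estimate_maps, MultiEchoFlashSet
from .morphometry import classify_and_measure, measure_slab_thickness
from .mprage import synthesize, synthesize_set
from .nifti_io import save_json, save_volume, sha256_of
from .phantom import (
    CohortSpec,
    DEFAULT_TISSUES,
    PhantomGeometry,
    TissueParameterTable,
    build_phantom,
    generate_cohort,
    make_b1_field,
    simulate_flash,
)
from .protocols import DEFAULT_MPRAGE, PDW_FLASH, T1W_FLASH, MprageProtocol

logger = logging.getLogger("morphosynth")

__all__ = ["RunConfig", "StageError", "run_all", "cohort_modality_volumes"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Resolved configuration of one full run."""

    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    tissues: TissueParameterTable = field(default_factory=lambda: DEFAULT_TISSUES)
    mprage: MprageProtocol = field(default_factory=lambda: DEFAULT_MPRAGE)
    noise_sigma: float = 0.0
    b1_amplitude: float = 0.0
    heterogeneity_sigma: float = 0.0
    smooth_fwhm_mm: float = 2.0
    n_subjects: int = 12
    pd_age_slope: float = 0.0
    out_dir: Path = Path("morphosynth_run")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(raw)
        kw.update(overrides)
        if "shape" in kw:
            kw["shape"] = tuple(int(v) for v in kw["shape"])
        if "tissues" in kw and isinstance(kw["tissues"], Mapping):
            kw["tissues"] = TissueParameterTable.from_dict(kw["tissues"])
        if "mprage" in kw and isinstance(kw["mprage"], Mapping):
            kw["mprage"] = MprageProtocol(**kw["mprage"])
        if "out_dir" in kw:
            kw["out_dir"] = Path(kw["out_dir"])
        return cls(**kw)

    def resolved_dict(self) -> dict:
        return {
            "seed": self.seed,
            "shape": list(self.shape),
            "voxel_size_mm": self.voxel_size_mm,
            "tissues": self.tissues.to_dict(),
            "mprage": self.mprage.to_dict(),
            "noise_sigma": self.noise_sigma,
            "b1_amplitude": self.b1_amplitude,
            "heterogeneity_sigma": self.heterogeneity_sigma,
            "smooth_fwhm_mm": self.smooth_fwhm_mm,
            "n_subjects": self.n_subjects,
            "pd_age_slope": self.pd_age_slope,
            "out_dir": str(self.out_dir),
        }


def cohort_modality_volumes(
    subjects,
    geometry: PhantomGeometry,
    protocol: MprageProtocol,
    modalities=("r1", "r1pd"),
    smooth_fwhm_mm: float = 2.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Apparent GM volume per subject and image type.

    For each subject and each requested image type, synthesise the image
    from the subject's ground-truth maps, segment it with the mixture
    proxy (intensity pre-smoothed), and record the apparent GM volume and
    mean slab thickness. Returns a tidy frame with one row per
    (subject, modality).
    """
    from .mprage import parse_modality

    rows = []
    voxel_vol = geometry.voxel_size_mm**3
    for subj in subjects:
        for tag in modalities:
            img = synthesize(subj.maps, protocol, parse_modality(tag))
            report = classify_and_measure(
                img, subj.maps.mask, k=3, voxel_volume_mm3=voxel_vol,
                smooth_fwhm_mm=smooth_fwhm_mm, voxel_size_mm=geometry.voxel_size_mm,
                rng_seed=rng_seed,
            )
            thickness, _ = measure_slab_thickness(report.label_volume, geometry)
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "age": subj.age,
                    "sex": subj.sex,
                    "modality": tag,
                    "gm_volume_mm3": report.gm_volume_mm3,
                    "mean_thickness_mm": float(np.nanmean(thickness)),
                }
            )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.resolved_dict(), "artifacts": {}}
    vx = config.voxel_size_mm

    def register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": sha256_of(path),
        }

    save_json(out / "config.json", config.resolved_dict())
    register("config", out / "config.json")

    stage = "phantom"
    try:
        logger.info("stage %s", stage)
        geometry = PhantomGeometry.create(config.shape, voxel_size_mm=vx)
        truth_maps, labels = build_phantom(
            geometry, config.tissues, rng_seed=config.seed,
            heterogeneity_sigma=config.heterogeneity_sigma,
        )
        b1 = make_b1_field(geometry, config.b1_amplitude, rng_seed=config.seed + 1)
        register("labels", save_volume(out / "labels.nii", labels, vx))
        for name in ("r1", "pd", "r2s"):
            register(f"truth_{name}",
                     save_volume(out / f"truth_{name}.nii", getattr(truth_maps, name), vx))
        register("b1", save_volume(out / "b1.nii", b1.relative_flip_factor, vx))

        stage = "fit-maps"
        logger.info("stage %s", stage)
        pdw = simulate_flash(truth_maps, PDW_FLASH, b1, config.noise_sigma, config.seed + 2)
        t1w = simulate_flash(truth_maps, T1W_FLASH, b1, config.noise_sigma, config.seed + 3)
        flash = MultiEchoFlashSet(pdw, t1w, PDW_FLASH, T1W_FLASH, truth_maps.mask)
        est_maps, qc = estimate_maps(flash, b1)
        for name in ("r1", "pd", "r2s"):
            register(f"map_{name}",
                     save_volume(out / f"map_{name}.nii", getattr(est_maps, name), vx))
        register("qc", save_json(out / "qc.json", qc.to_dict()))

        stage = "synthesize"
        logger.info("stage %s", stage)
        images = synthesize_set(est_maps, config.mprage)
        for tag, img in images.items():
            register(f"t1w_{tag}", save_volume(out / f"t1w_{tag}.nii", img.intensity, vx))
            register(f"t1w_{tag}_sidecar",
                     save_json(out / f"t1w_{tag}.json",
                               {"modality": sorted(img.modality),
                                "protocol": config.mprage.to_dict()}))

        stage = "contrast"
        logger.info("stage %s", stage)
        tables = []
        for tag, img in images.items():
            samples, n_skipped = contrast_mod.sample_boundary(img, labels, geometry)
            for s in samples:
                tables.append(
                    {"site_id": s.location_id, "wm_int": s.wm_intensity,
                     "gm_int": s.gm_intensity,
                     "contrast": contrast_mod.compute_contrast(s), "modality": tag}
                )
        contrast_df = pd.DataFrame(tables)
        contrast_path = out / "contrast.csv"
        contrast_df.to_csv(contrast_path, index=False)
        register("contrast", contrast_path)

        stage = "morphometry"
        logger.info("stage %s", stage)
        morpho = {}
        for tag, img in images.items():
            report = classify_and_measure(
                img, est_maps.mask, k=3, voxel_volume_mm3=vx**3,
                smooth_fwhm_mm=config.smooth_fwhm_mm, voxel_size_mm=vx,
                rng_seed=config.seed,
            )
            thickness, n_missing = measure_slab_thickness(report.label_volume, geometry)
            entry = report.to_dict()
            entry["n_thickness_missing"] = n_missing
            morpho[tag] = entry
        register("morphometry", save_json(out / "morphometry.json", morpho))

        stage = "glm"
        logger.info("stage %s", stage)
        slopes = (
            {"cortical_gm": {"pd": config.pd_age_slope},
             "sensorimotor_gm": {"pd": config.pd_age_slope}}
            if config.pd_age_slope
            else {}
        )
        spec = CohortSpec(n_subjects=config.n_subjects, linear_slopes=slopes,
                          rng_seed=config.seed + 10)
        subjects, truth = generate_cohort(spec, geometry, config.tissues)
        volumes = cohort_modality_volumes(
            subjects, geometry, config.mprage,
            smooth_fwhm_mm=config.smooth_fwhm_mm, rng_seed=config.seed,
        )
        volumes_path = out / "cohort_volumes.csv"
        volumes.to_csv(volumes_path, index=False)
        register("cohort_volumes", volumes_path)

        design = glm_mod.build_design(volumes, ("modality", "age", "modality:age"))
        result = glm_mod.fit_glm(
            design, volumes["gm_volume_mm3"].to_numpy()[None, :],
            {"modality[r1pd]:age_c": -1.0},
        )
        register(
            "glm",
            save_json(out / "glm.json",
                      {"columns": list(design.columns),
                       "beta": result.beta[0].tolist(),
                       "t_interaction": float(result.t[0]),
                       "p_one_tailed": float(result.p_one_tailed[0]),
                       "dof": result.dof}),
        )
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        save_json(out / "manifest.json", manifest)
        raise StageError(stage, exc) from exc

    save_json(out / "manifest.json", manifest)
    register_path = out / "manifest.json"
    logger.info("run complete: %d artifacts in %s", len(manifest["artifacts"]), register_path)
    return manifest
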