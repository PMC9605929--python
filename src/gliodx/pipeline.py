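"""End-to-end orchestration: configuration, stage sequencing, manifest.

A run is described by a YAML config (paths, acquisition constants, perfusion
settings, lesion thresholds, diagnostics options, seed).  ``run_end_to_end``
executes relaxometry -> perfusion -> lesion metrics -> outcome ->
diagnostics, writing NIfTI maps, the lesion table, a diagnostics report and
a manifest recording the package version, config hash and seed; reruns with
an identical config reproduce identical outputs.  ``simulate_phantom_inputs``
materialises a complete synthetic input directory (with truth) so the whole
chain can run without patient data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .cohort import CohortSpec, simulate_cohort
from .diagnostics import (
    ClassificationRule,
    concordance_matrix,
    diagnostic_report,
    youden_cutoff,
)
from .kinetics import AifParams, Hematocrit, TissueParams, make_aif
from .lesions import VoiMask, compute_lesion_metrics, delineate_bv_volume, delineate_fet_volume
from .outcomes import NON_EVALUABLE, PROGRESSIVE, adjudicate_table
from .perfusion import PerfusionFitSettings, compute_parameter_maps
from .phantoms import (
    MrAcquisition,
    PetLesionSpec,
    lesion_phantom,
    make_pet_phantom,
    synthesize_mr_signals,
)
from .relaxometry import VfaStack, fit_t1_vfa, signal_to_concentration

log = logging.getLogger("gliodx")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained for debugging."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (see ``from_yaml`` for the schema)."""

    raw: dict
    path: Path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        cfg = cls(raw=raw, path=path)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        inputs = self.raw.get("inputs", {})
        base = self.path.parent
        for key, val in inputs.items():
            if key == "lesions":
                for les in val:
                    for mkey in ("ce_mask", "seed_mask"):
                        p = les.get(mkey)
                        if p and not (base / p).exists():
                            raise FileNotFoundError(f"lesion input missing: {p}")
            elif isinstance(val, str):
                if not (base / val).exists():
                    raise FileNotFoundError(f"input missing: {val}")
            elif isinstance(val, list):
                for p in val:
                    if isinstance(p, str) and not (base / p).exists():
                        raise FileNotFoundError(f"input missing: {p}")

    def resolve(self, rel: str) -> Path:
        return self.path.parent / rel

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def hematocrit(self) -> Hematocrit:
        h = self.raw.get("hematocrit", {})
        return Hematocrit(large=h.get("large", 0.45), small=h.get("small", 0.25))

    @property
    def perfusion_settings(self) -> PerfusionFitSettings:
        p = dict(self.raw.get("perfusion", {}))
        if "lambda_grid" in p:
            p["lambda_grid"] = tuple(p["lambda_grid"])
        return PerfusionFitSettings(**p)

    def sha256(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(canonical).hexdigest()


def _diagnostics_stage(lesions: pd.DataFrame, diag_cfg: dict, outdir: Path) -> dict:
    params = diag_cfg.get("parameters", ["tbr_max", "bv_max", "nbv_max"])
    params = [p for p in params if p in lesions.columns]
    evaluable = lesions[lesions["outcome"] != NON_EVALUABLE]
    summary: dict = {"n_lesions": int(len(lesions)), "parameters": params}
    classes = set(evaluable["outcome"])
    if len(classes) < 2 or len(evaluable) < 4:
        log.warning("diagnostics skipped: need both outcome classes and >= 4 lesions")
        summary["skipped"] = "insufficient outcome variation"
        return summary

    report = diagnostic_report(evaluable, params)
    report.to_csv(outdir / "roc_table.csv", index=False)
    summary["roc_table"] = "roc_table.csv"

    if {"tbr_max", "bv_max"} <= set(params):
        y = evaluable["outcome"].eq(PROGRESSIVE).to_numpy()
        cut_fet, _ = youden_cutoff(evaluable["tbr_max"].to_numpy(), y)
        cut_bv, _ = youden_cutoff(evaluable["bv_max"].to_numpy(), y)
        conc = concordance_matrix(
            evaluable,
            ClassificationRule("tbr_max", cut_fet),
            ClassificationRule("bv_max", cut_bv),
        )
        conc.to_csv(outdir / "concordance.csv", index=False)
        summary["concordance"] = "concordance.csv"
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def run_end_to_end(config: RunConfig, output_dir=None) -> Path:
    """Execute the full pipeline described by ``config``.

    Returns the output directory containing parameter maps, lesions.csv, the
    diagnostics report and manifest.json.  Any stage failure raises
    :class:`StageError` with the stage name; outputs written so far remain.
    """
    t_start = time.time()
    outdir = Path(output_dir or config.resolve(config.raw.get("output_dir", "out")))
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    inputs = config.raw.get("inputs", {})
    acq = config.raw.get("acquisition", {})
    vsz = tuple(config.raw.get("voxel_size_mm", (2.0, 2.0, 2.0)))
    hct = config.hematocrit

    lesions_df = None
    if "lesion_table" in inputs:
        lesions_df = pd.read_csv(config.resolve(inputs["lesion_table"]))
    else:
        # ---- relaxometry -------------------------------------------------
        t0 = time.time()
        try:
            vols = [gio.load_nifti(config.resolve(p))[0] for p in inputs["vfa"]]
            stack = VfaStack(
                np.stack(vols), np.asarray(acq["flip_angles_deg"], dtype=float),
                float(acq["tr_ms"]),
            )
            maps_t1 = fit_t1_vfa(stack)
            dyn, _ = gio.load_nifti(config.resolve(inputs["dynamic"]))
            conc, _sat = signal_to_concentration(
                dyn, maps_t1, r1=float(acq.get("r1", 3.6)), tr_ms=float(acq["tr_ms"]),
                flip_deg=float(acq.get("dynamic_flip_deg", 15.0)),
                n_baseline_frames=int(acq.get("n_baseline_frames", 5)),
            )
            gio.save_nifti(maps_t1.t1_ms, outdir / "t1.nii.gz", vsz)
        except Exception as exc:  # noqa: BLE001 — stage attribution
            raise StageError("relaxometry", exc) from exc
        timings["relaxometry_s"] = round(time.time() - t0, 2)

        # ---- perfusion ---------------------------------------------------
        t0 = time.time()
        try:
            aif = gio.load_aif_csv(config.resolve(inputs["aif"]))
            mask, _ = gio.load_nifti(config.resolve(inputs["brain_mask"]))
            maps = compute_parameter_maps(
                conc, aif, mask.astype(bool), config.perfusion_settings, hct
            )
            for name in ("f", "bv", "ki", "ve"):
                gio.save_nifti(getattr(maps, name), outdir / f"{name}.nii.gz", vsz)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("perfusion", exc) from exc
        timings["perfusion_s"] = round(time.time() - t0, 2)

        # ---- lesion metrics ----------------------------------------------
        t0 = time.time()
        try:
            pet, _ = gio.load_nifti(config.resolve(inputs["pet"]))
            bg, _ = gio.load_nifti(config.resolve(inputs["background_voi"]))
            nawm, _ = gio.load_nifti(config.resolve(inputs["nawm_voi"]))
            thr = config.raw.get("lesion_thresholds", {})
            vvol = float(np.prod(vsz)) / 1000.0
            nawm_bv = float(np.nanmean(maps.bv[nawm.astype(bool)]))
            records = []
            for les in inputs.get("lesions", []):
                seed_mask = (
                    gio.load_nifti(config.resolve(les["seed_mask"]))[0].astype(bool)
                    if les.get("seed_mask")
                    else None
                )
                ce = None
                if les.get("ce_mask"):
                    ce = VoiMask(
                        gio.load_nifti(config.resolve(les["ce_mask"]))[0].astype(bool), vvol
                    )
                vol_fet = delineate_fet_volume(
                    pet, bg.astype(bool), vvol,
                    threshold_ratio=float(thr.get("fet_ratio", 1.6)), seed=seed_mask,
                )
                vol_bv = delineate_bv_volume(
                    maps.bv, nawm_bv, vvol, vessel_mask=None,
                    threshold_factor=float(thr.get("bv_factor", 2.0)), seed=seed_mask,
                )
                records.append(
                    compute_lesion_metrics(
                        pet, maps, ce, vol_fet, vol_bv, bg.astype(bool),
                        nawm.astype(bool), enhancing=bool(les.get("enhancing", True)),
                        flair_centre=les.get("flair_centre"), voxel_size_mm=vsz,
                        patient_id=str(les.get("patient_id", "")),
                        lesion_id=str(les.get("lesion_id", "")),
                    )
                )
            lesions_df = gio.lesion_records_to_frame(records)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("lesion_metrics", exc) from exc
        timings["lesion_metrics_s"] = round(time.time() - t0, 2)

    # ---- outcome ---------------------------------------------------------
    t0 = time.time()
    try:
        if "followup" in inputs:
            fu = pd.read_csv(config.resolve(inputs["followup"]))
            adj = adjudicate_table(fu)
            lesions_df = lesions_df.drop(columns=["outcome"], errors="ignore").merge(
                adj[["lesion_id", "outcome"]], on="lesion_id", how="left"
            )
            lesions_df["outcome"] = lesions_df["outcome"].fillna("unknown")
        if "reference_basis" not in lesions_df.columns:
            lesions_df["reference_basis"] = ""
        for col in gio.LESION_COLUMNS:
            if col not in lesions_df.columns:
                lesions_df[col] = np.nan
        gio.write_lesion_table(lesions_df, outdir / "lesions.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("outcome", exc) from exc
    timings["outcome_s"] = round(time.time() - t0, 2)

    # ---- diagnostics -----------------------------------------------------
    t0 = time.time()
    try:
        summary = _diagnostics_stage(lesions_df, config.raw.get("diagnostics", {}), outdir)
    except Exception as exc:  # noqa: BLE001
        raise StageError("diagnostics", exc) from exc
    timings["diagnostics_s"] = round(time.time() - t0, 2)

    manifest = {
        "package": "gliodx",
        "version": __import__("gliodx").__version__,
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "timings": timings,
        "total_s": round(time.time() - t_start, 2),
        "diagnostics": summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("run complete in %.1f s -> %s", manifest["total_s"], outdir)
    return outdir


# --------------------------------------------------------------------------
# Synthetic input directories
# --------------------------------------------------------------------------

NAWM_PARAMS = TissueParams(F=20.0, BV=1.5, Ki=0.0, Ve=20.0)
TUMOUR_PARAMS = TissueParams(F=60.0, BV=4.0, Ki=6.0, Ve=20.0)


def simulate_phantom_inputs(
    outdir,
    seed: int = 0,
    noise_sd: float = 0.0,
    shape=(16, 16, 8),
    n_frames: int = 180,
    voxel_size_mm=(2.0, 2.0, 2.0),
) -> Path:
    """Write a complete, self-consistent synthetic input directory.

    One tumour-like lesion (elevated F/BV/Ki, PET-avid) in white-matter-like
    background; VFA stack, dynamic series, AIF, PET volume, masks, follow-up
    table and a ready-to-run config.yaml.  Truth parameters are stored in
    truth.json for recovery checks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    centre = tuple(s // 2 for s in shape)
    truth = lesion_phantom(
        NAWM_PARAMS, [(centre, 6.0, TUMOUR_PARAMS)], shape=shape,
        voxel_size_mm=voxel_size_mm,
    )
    times = np.arange(n_frames, dtype=float)
    aif = make_aif(AifParams(), times)
    acq = MrAcquisition(noise_sd=noise_sd, seed=seed)
    data = synthesize_mr_signals(truth, aif, acq)

    vfa_paths = []
    for i, ang in enumerate(acq.flip_angles_deg):
        p = f"vfa_{i}.nii.gz"
        gio.save_nifti(data.vfa.signals[i], outdir / p, voxel_size_mm)
        vfa_paths.append(p)
    gio.save_nifti(data.dynamic, outdir / "dynamic.nii.gz", voxel_size_mm)
    gio.save_aif_csv(aif, outdir / "aif.csv")

    lesion_mask = truth.lesion_masks["lesion0"]
    # keep the fitted region small: lesion plus a NAWM slab
    nawm_box = np.zeros(shape, dtype=bool)
    nawm_box[1:4, 1:4, 1:4] = True
    brain = lesion_mask | nawm_box
    gio.save_nifti(brain.astype(float), outdir / "brain_mask.nii.gz", voxel_size_mm)
    gio.save_nifti(lesion_mask.astype(float), outdir / "seed_mask.nii.gz", voxel_size_mm)
    gio.save_nifti(lesion_mask.astype(float), outdir / "ce_mask.nii.gz", voxel_size_mm)
    gio.save_nifti(nawm_box.astype(float), outdir / "nawm_voi.nii.gz", voxel_size_mm)

    pet, _masks = make_pet_phantom(
        background=1000.0, lesions=[PetLesionSpec(centre, 8.0, 2.8)],
        shape=shape, voxel_size_mm=voxel_size_mm, noise_sd=noise_sd, seed=seed + 1,
    )
    gio.save_nifti(pet, outdir / "pet.nii.gz", voxel_size_mm)
    bg_box = np.zeros(shape, dtype=bool)
    bg_box[-4:-1, -4:-1, 1:4] = True
    gio.save_nifti(bg_box.astype(float), outdir / "background_voi.nii.gz", voxel_size_mm)

    pd.DataFrame(
        [{"lesion_id": "L000", "histology": "tumour", "histology_day": 14}]
    ).to_csv(outdir / "followup.csv", index=False)

    cfg = {
        "seed": seed,
        "voxel_size_mm": list(voxel_size_mm),
        "acquisition": {
            "flip_angles_deg": list(acq.flip_angles_deg),
            "dynamic_flip_deg": acq.dynamic_flip_deg,
            "tr_ms": acq.tr_ms,
            "r1": acq.r1,
            "n_baseline_frames": 5,
        },
        "hematocrit": {"large": 0.45, "small": 0.25},
        "perfusion": {"lambda_strategy": "discrepancy"},
        "lesion_thresholds": {"fet_ratio": 1.6, "bv_factor": 2.0},
        "diagnostics": {"parameters": ["tbr_max", "bv_max", "nbv_max"]},
        "inputs": {
            "vfa": vfa_paths,
            "dynamic": "dynamic.nii.gz",
            "aif": "aif.csv",
            "brain_mask": "brain_mask.nii.gz",
            "pet": "pet.nii.gz",
            "background_voi": "background_voi.nii.gz",
            "nawm_voi": "nawm_voi.nii.gz",
            "followup": "followup.csv",
            "lesions": [
                {
                    "patient_id": "P000",
                    "lesion_id": "L000",
                    "enhancing": True,
                    "ce_mask": "ce_mask.nii.gz",
                    "seed_mask": "seed_mask.nii.gz",
                    "flair_centre": list(centre),
                }
            ],
        },
        "output_dir": "out",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "background": dataclasses.asdict(NAWM_PARAMS),
                "lesion0": dataclasses.asdict(TUMOUR_PARAMS),
                "t1_ms": 1200.0,
                "pet_ratio": 2.8,
            },
            fh,
            indent=2,
        )
    return outdir


def simulate_cohort_csv(path, seed: int = 0, spec: CohortSpec | None = None) -> Path:
    """Write a simulated lesion cohort to CSV (CLI backend)."""
    spec = spec or CohortSpec(seed=seed)
    if spec.seed != seed:
        spec = dataclasses.replace(spec, seed=seed)
    df = simulate_cohort(spec)
    df.to_csv(path, index=False)
    return Path(path)
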