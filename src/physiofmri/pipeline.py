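"""End-to-end orchestration: simulate -> preprocess -> correct -> analyze.

A single :class:`PipelineConfig` drives the run; every stage writes its
outputs under the configured output directory and records itself in a
machine-readable manifest.  Stage order is fixed: physiological noise
correction happens on the raw (unsmoothed) series before any statistical
modelling, tSNR is compared on unsmoothed corrected/uncorrected data, and
smoothing is applied only on the GLM path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm as glm_mod
from . import nuisance, quality, responses, synthetic
from .core import BoldImage, EventDesign
from .physio import (
    N_DISCARD_VOLUMES,
    preprocess_pupil,
    preprocess_sc,
    read_physio_tsv,
    read_pupil_tsv,
    sync_to_scan,
    write_physio_tsv,
    write_pupil_tsv,
)

logger = logging.getLogger("physiofmri")

STAGES = ("simulate", "physio", "correct", "tsnr", "responses", "glm", "report")


@dataclass
class PipelineConfig:
    """Structured configuration for a full pipeline run.

    Unknown keys in a config file are rejected; referenced input files
    must exist at validation time.  ``simulate=True`` generates a
    synthetic session in place of external inputs.
    """

    out_dir: str = "physiofmri_out"
    simulate: bool = True
    seed: int = 0
    # external inputs (used when simulate is False)
    bold_path: str | None = None
    physio_path: str | None = None
    pupil_path: str | None = None
    events_path: str | None = None
    motion_path: str | None = None
    mask_path: str | None = None
    atlas_mask_path: str | None = None
    slice_times_path: str | None = None
    # acquisition / analysis parameters
    n_volumes: int = synthetic.N_VOLUMES
    tr_s: float = synthetic.TR_S
    n_per_condition: int = synthetic.N_PER_CONDITION
    jitter_sd_s: float = synthetic.JITTER_SD_S
    n_discard: int = N_DISCARD_VOLUMES
    grid: tuple[int, int, int] = synthetic.DEFAULT_GRID
    retroicor_order: int = nuisance.DEFAULT_RETROICOR_ORDER
    rvt_lags: tuple[float, ...] = nuisance.DEFAULT_RVT_LAGS
    slice_axis: int = 2
    hp_cutoff_s: float = glm_mod.DEFAULT_HP_CUTOFF_S
    fwhm_mm: float = glm_mod.DEFAULT_FWHM_MM
    smooth: bool = True
    voxel_p: float = glm_mod.DEFAULT_VOXEL_P
    extent: int | str = 1
    model: int = 1
    modulator: str = "none"   # none | scr | pdr
    stick: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid", "rvt_lags"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        """Fail fast on an inconsistent configuration."""
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1, 2 or 3")
        expected_mod = {1: "none", 2: "scr", 3: "pdr"}[self.model]
        if self.modulator == "none" and self.model in (2, 3):
            self.modulator = expected_mod
        if self.model in (2, 3) and self.modulator != expected_mod:
            raise ValueError(
                f"model {self.model} uses the {expected_mod} modulator, "
                f"got {self.modulator!r}")
        if self.model == 1 and self.modulator != "none":
            raise ValueError("model 1 takes no parametric modulator")
        if not self.simulate:
            required = {"bold_path": self.bold_path, "physio_path": self.physio_path,
                        "events_path": self.events_path}
            if self.model == 3 or self.modulator == "pdr":
                required["pupil_path"] = self.pupil_path
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ValueError(f"config missing required inputs: {missing}")
            for k, v in required.items():
                if v is not None and not Path(v).exists():
                    raise FileNotFoundError(f"{k}: {v} does not exist")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest dictionary.

    Deterministic given the config seed; any stage failure raises with the
    stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "parameters": dataclasses.asdict(config),
                      "inputs": {}}
    stage = "simulate"
    try:
        # --- stage 1: obtain the session -----------------------------------
        if config.simulate:
            truth = synthetic.GroundTruth.for_grid(tuple(config.grid),
                                                   seed=config.seed)
            session = synthetic.generate_session(
                truth, n_volumes=config.n_volumes, tr_s=config.tr_s,
                grid=tuple(config.grid),
                n_per_condition=config.n_per_condition,
                jitter_sd_s=config.jitter_sd_s)
            paths = synthetic.write_session(session, out / "session")
            manifest["inputs"] = {k: str(p) for k, p in paths.items()}
            bold, physio, pupil = session.bold, session.physio, session.pupil
            events, motion = session.events, session.motion
        else:
            slice_times = (np.loadtxt(config.slice_times_path)
                           if config.slice_times_path else None)
            bold = BoldImage.load(config.bold_path, slice_times=slice_times,
                                  slice_axis=config.slice_axis)
            physio = read_physio_tsv(config.physio_path)
            pupil = read_pupil_tsv(config.pupil_path) if config.pupil_path else None
            events = EventDesign.read_tsv(config.events_path)
            motion = (pd.read_csv(config.motion_path, sep="\t")
                      if config.motion_path else None)
            for k in ("bold_path", "physio_path", "pupil_path", "events_path",
                      "motion_path"):
                v = getattr(config, k)
                if v:
                    manifest["inputs"][k] = {"path": v, "sha256": _digest(Path(v))}
        manifest["stages"].append(stage)

        # --- stage 2: synchronize + preprocess peripheral signals ----------
        stage = "physio"
        n_keep = bold.n_volumes - config.n_discard
        physio_sync = sync_to_scan(physio, bold.n_volumes, bold.tr_s,
                                   n_discard=config.n_discard)
        physio_sync.channels["sc"] = preprocess_sc(
            physio_sync.channels["sc"], physio_sync.fs)
        write_physio_tsv(physio_sync, out / "physio_clean.tsv")
        pupil_clean = None
        if pupil is not None:
            pupil_sync = sync_to_scan(pupil, bold.n_volumes, bold.tr_s,
                                      n_discard=config.n_discard)
            pupil_clean = preprocess_pupil(pupil_sync)
            write_pupil_tsv(pupil_clean, out / "pupil_clean.tsv")
        bold_trim = bold.discard_initial(config.n_discard)
        events_trim = events.shifted(-config.n_discard * bold.tr_s)
        manifest["stages"].append(stage)

        # --- stage 3: physiological noise correction -----------------------
        stage = "correct"
        slice_times = (bold.slice_times if bold.slice_times is not None
                       else np.zeros(bold_trim.data.shape[config.slice_axis]))
        nuis = nuisance.build_slicewise_nuisance(
            physio_sync, slice_times, n_keep, bold.tr_s,
            order=config.retroicor_order, rvt_lags=list(config.rvt_lags))
        nuis.write_tsv(out / "nuisance")
        corrected = nuisance.residualize(bold_trim, nuis)
        corrected.save(out / "bold_corrected.nii")
        manifest["stages"].append(stage)

        # --- stage 4: tSNR -------------------------------------------------
        stage = "tsnr"
        tsnr_pre = quality.tsnr_map(bold_trim, provenance="uncorrected")
        tsnr_post = quality.tsnr_map(corrected, provenance="corrected")
        change = quality.tsnr_change(tsnr_post, tsnr_pre)
        from .core import save_map
        save_map(tsnr_pre.values, bold.affine, out / "tsnr_uncorrected.nii")
        save_map(tsnr_post.values, bold.affine, out / "tsnr_corrected.nii")
        save_map(change, bold.affine, out / "tsnr_change.nii")
        mean_pre, sd_pre, n_vox = quality.mask_summary(tsnr_pre)
        mean_post, sd_post, _ = quality.mask_summary(tsnr_post)
        pd.DataFrame([
            {"provenance": "uncorrected", "mean": mean_pre, "sd": sd_pre, "n": n_vox},
            {"provenance": "corrected", "mean": mean_post, "sd": sd_post, "n": n_vox},
        ]).to_csv(out / "tsnr_summary.tsv", sep="\t", index=False)
        manifest["tsnr"] = {"uncorrected_mean": mean_pre, "corrected_mean": mean_post}
        manifest["stages"].append(stage)

        # --- stage 5: event-related autonomic responses --------------------
        stage = "responses"
        trial_measures: dict[str, np.ndarray] = {}
        sc_resp, _ = responses.extract_trial_responses(
            physio_sync.channels["sc"], physio_sync.fs, events_trim, "sc")
        trial_measures["scr"] = _trial_measure_vector(sc_resp, len(events_trim))
        _write_trial_table(sc_resp, out / "sc_trials.tsv")
        if pupil_clean is not None and not pupil_clean.rejected:
            pd_resp, _ = responses.extract_trial_responses(
                pupil_clean.pd, pupil_clean.fs, events_trim, "pupil")
            trial_measures["pdr"] = _trial_measure_vector(pd_resp, len(events_trim))
            _write_trial_table(pd_resp, out / "pupil_trials.tsv")
        manifest["stages"].append(stage)

        # --- stage 6: GLM ---------------------------------------------------
        stage = "glm"
        modulator = None
        if config.model in (2, 3):
            key = {2: "scr", 3: "pdr"}[config.model]
            if key not in trial_measures:
                raise ValueError(f"model {config.model} requires the {key} channel")
            modulator = trial_measures[key]
        motion_trim = (motion.iloc[config.n_discard:].reset_index(drop=True)
                       if motion is not None else None)
        design = glm_mod.build_design(
            events_trim, n_keep, bold.tr_s, model=config.model,
            modulator=modulator, motion=motion_trim,
            hp_cutoff_s=config.hp_cutoff_s, stick=config.stick)
        design.to_frame().to_csv(out / "design.tsv", sep="\t", index=False)
        glm_input = (glm_mod.gaussian_smooth(corrected, config.fwhm_mm)
                     if config.smooth else corrected)
        result = glm_mod.fit_first_level(glm_input, design, model=config.model)
        con, tmap = glm_mod.interference_contrast(result)
        save_map(con, bold.affine, out / "contrast_interference.nii")
        save_map(tmap, bold.affine, out / "tmap_interference.nii")
        table = glm_mod.cluster_threshold(
            tmap, result.df, voxel_p=config.voxel_p,
            extent=config.extent if config.extent != "auto" else 1,
            affine=bold.affine)
        table.rows.to_csv(out / "clusters.csv", index=False)
        manifest["glm"] = {"model": config.model, "ar1_rho": result.ar1_rho,
                           "df": result.df, "n_clusters": len(table)}
        if config.atlas_mask_path and len(table):
            from .core import load_mask
            import nibabel as nib
            atlas_img = nib.load(config.atlas_mask_path)
            atlas = load_mask(config.atlas_mask_path)
            overlaps = []
            for _, row in table.rows.iterrows():
                count, frac = glm_mod.atlas_overlap(
                    table.cluster_mask(int(row["label"])), atlas,
                    cluster_affine=bold.affine, atlas_affine=atlas_img.affine)
                overlaps.append({"label": int(row["label"]),
                                 "overlap_voxels": count,
                                 "overlap_fraction": frac})
            pd.DataFrame(overlaps).to_csv(out / "atlas_overlap.tsv",
                                          sep="\t", index=False)
            manifest["glm"]["atlas_overlap"] = overlaps
        manifest["stages"].append(stage)

        # --- stage 7: report -----------------------------------------------
        stage = "report"
        import physiofmri
        manifest["version"] = physiofmri.__version__
        manifest["stages"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest


def _trial_measure_vector(resp: list[responses.TrialResponse], n_trials: int
                          ) -> np.ndarray:
    """Per-trial AUC vector aligned to the design (excluded trials get the
    condition mean so modulated regressors stay defined)."""
    out = np.full(n_trials, np.nan)
    for r in resp:
        out[r.trial_index] = r.auc
    if np.any(np.isnan(out)):
        out[np.isnan(out)] = np.nanmean(out)
    return out


def _write_trial_table(resp: list[responses.TrialResponse], path: Path) -> None:
    pd.DataFrame([{
        "trial_index": r.trial_index, "condition": r.condition,
        "baseline": r.baseline, "auc": r.auc, "auc_samples": r.auc_samples,
        "peak": r.peak, "peak_latency": r.peak_latency,
    } for r in resp]).to_csv(path, sep="\t", index=False)
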