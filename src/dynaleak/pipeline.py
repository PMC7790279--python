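"""End-to-end orchestration: phantom -> TACs -> perfusion -> endoleak report
-> reader statistics, with a reproducibility manifest.

Output layout::

    out_dir/
      manifest.json
      phantom/    dynamic.nii, dynamic_times.csv, masks.nii, config.yaml
      tacs/       curves.csv
      perfusion/  bf.nii, bf_params.json, bf_slices/*.png
      endoleaks/  report.csv, lesions.nii
      stats/      summary.json

Checksums in the manifest cover the deterministic text/NIfTI artifacts; PNG
renderings are listed but not checksummed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .endoleak import detect_endoleaks, report_to_csv
from .perfusion import bf_map, reduce_noise_4d, save_perfusion_map
from .phantom import (GroundTruth, PhantomConfig, _affine, generate_phantom,
                      preset_config, save_dynamic_volume, save_masks)
from .stats import (consensus_counts, effective_dose, kappa_ci,
                    load_dose_table, load_reader_table, weighted_kappa)
from .tac import curves_to_csv, extract_tac, peak_difference, time_to_peak

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_fixtures"]


@dataclass(frozen=True)
class RunConfig:
    preset: str = "paper-calibrated"
    noise_sd: float = 10.0
    seed: int = 0
    upslope_window: int = 3
    smoothing: bool = True
    k_sd: float = 4.0
    min_voxels: int = 4
    out_dir: str = "dynaleak_run"
    n_boot: int = 2000
    save_pngs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)       # stage -> {paths, seconds}
    checksums: dict = field(default_factory=dict)    # path -> sha256
    log: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    error: dict | None = None

    def save(self, path: str | Path) -> None:
        payload = {"config": self.config, "version": self.version,
                   "stages": self.stages, "checksums": self.checksums,
                   "log": self.log, "summary": self.summary, "error": self.error}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage in order; deterministic for a fixed config (seed
    included).  A stage failure is recorded in the manifest (stage name and
    cause) and re-raised."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    stage = "init"

    def log(msg: str) -> None:
        manifest.log.append(f"[{stage}] {msg}")

    def finish_stage(paths: dict, t0: float) -> None:
        manifest.stages[stage] = {"paths": {k: str(v) for k, v in paths.items()},
                                  "seconds": round(time.perf_counter() - t0, 3)}
        for p in paths.values():
            p = Path(p)
            if p.is_file() and p.suffix in {".nii", ".csv", ".json", ".yaml"}:
                manifest.checksums[str(p)] = _sha256(p)

    try:
        # -- phantom -------------------------------------------------------
        stage = "phantom"
        t0 = time.perf_counter()
        pdir = out / "phantom"
        pdir.mkdir(exist_ok=True)
        pconf = preset_config(config.preset, noise_sd=config.noise_sd,
                              rng_seed=config.seed)
        volume, truth = generate_phantom(pconf)
        log(f"preset={config.preset} noise_sd={config.noise_sd} seed={config.seed} "
            f"grid={pconf.shape} frames={volume.n_frames}")
        save_dynamic_volume(volume, pdir / "dynamic.nii", pdir / "dynamic_times.csv")
        save_masks(truth, pconf.spacing, pdir / "masks.nii")
        config.to_yaml(pdir / "config.yaml")
        finish_stage({"volume": pdir / "dynamic.nii",
                      "times": pdir / "dynamic_times.csv",
                      "masks": pdir / "masks.nii",
                      "config": pdir / "config.yaml"}, t0)

        # -- TACs ----------------------------------------------------------
        stage = "tacs"
        t0 = time.perf_counter()
        tdir = out / "tacs"
        tdir.mkdir(exist_ok=True)
        # AIF: aortic lumen cranial to the graft (top slices of the lumen)
        aif_mask = truth.lumen_mask.copy()
        aif_mask[4:] = False
        aif = extract_tac(volume, aif_mask, "aortic_lumen", role="AIF")
        curves = [aif, extract_tac(volume, truth.sac_mask, "aneurysm_sac")]
        for i, m in enumerate(truth.endoleak_masks):
            curves.append(extract_tac(volume, m, f"endoleak_{i}"))
        curves_to_csv(curves, tdir / "curves.csv")
        log(f"extracted {len(curves)} curves (AIF + sac + {len(truth.endoleak_masks)} lesions)")
        finish_stage({"curves": tdir / "curves.csv"}, t0)

        # -- perfusion -----------------------------------------------------
        stage = "perfusion"
        t0 = time.perf_counter()
        fdir = out / "perfusion"
        search = truth.anatomical_sac
        vol_s = reduce_noise_4d(volume) if config.smoothing else volume
        pmap = bf_map(vol_s, aif, search, window=config.upslope_window)
        paths = save_perfusion_map(pmap, pconf.spacing, fdir) if config.save_pngs else {}
        if not config.save_pngs:
            fdir.mkdir(exist_ok=True)
            nib.save(nib.Nifti1Image(np.transpose(pmap.bf, (2, 1, 0)).astype(np.float32),
                                     _affine(pconf.spacing)), str(fdir / "bf.nii"))
            paths = {"nifti": fdir / "bf.nii"}
        log(f"smoothing={config.smoothing} window={config.upslope_window} "
            f"aif_max={pmap.aif_max:.1f} HU")
        finish_stage({"bf": paths["nifti"]}, t0)

        # -- endoleaks -----------------------------------------------------
        stage = "endoleaks"
        t0 = time.perf_counter()
        edir = out / "endoleaks"
        edir.mkdir(exist_ok=True)
        report = detect_endoleaks(pmap, search, k_sd=config.k_sd,
                                  min_voxels=config.min_voxels,
                                  volume=vol_s, aif=aif,
                                  window=config.upslope_window)
        report_to_csv(report, edir / "report.csv")
        labels = np.zeros(search.shape, dtype=np.int16)
        for l in report.lesions:
            labels[l.mask] = l.label
        nib.save(nib.Nifti1Image(np.transpose(labels, (2, 1, 0)), _affine(pconf.spacing)),
                 str(edir / "lesions.nii"))
        log(f"count={report.count} confidence={report.confidence} "
            f"threshold={report.threshold_bf:.1f}")
        finish_stage({"report": edir / "report.csv", "lesions": edir / "lesions.nii"}, t0)

        # -- statistics ----------------------------------------------------
        stage = "stats"
        t0 = time.perf_counter()
        sdir = out / "stats"
        sdir.mkdir(exist_ok=True)
        summary = summarize(volume, truth, aif, report, config)
        summary["reader_agreement"] = reader_statistics(config.seed, config.n_boot)
        with open(sdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        log("summary written")
        finish_stage({"summary": sdir / "summary.json"}, t0)
        manifest.summary = summary
    except Exception as exc:
        manifest.error = {"stage": stage, "cause": f"{type(exc).__name__}: {exc}"}
        manifest.save(out / "manifest.json")
        raise
    manifest.save(out / "manifest.json")
    return manifest


def summarize(volume, truth: GroundTruth, aif, report, config: RunConfig) -> dict:
    """Scalar pipeline outcomes: detection count, indices, kinetic timings,
    dichotomized confidence."""
    arterial = time_to_peak(aif)
    lesions = []
    for l in report.lesions:
        lesions.append({
            "label": l.label, "voxels": l.stats.voxel_count,
            "mean_hu": l.stats.mean_hu, "mean_bf": l.stats.mean_bf,
            "time_to_peak_s": l.kinetics.time_to_peak if l.kinetics else None,
            "peak_difference_s": peak_difference(arterial, l.kinetics) if l.kinetics else None,
            "index_hu": l.index_hu, "index_bf": l.index_bf,
        })
    from .endoleak import dichotomize_confidence
    return {
        "preset": config.preset,
        "true_count": len(truth.endoleak_masks),
        "detected_count": report.count,
        "confidence": report.confidence,
        "confidence_dichotomized": dichotomize_confidence(report.confidence),
        "aortic_time_to_peak_s": arterial.time_to_peak,
        "index_hu": report.index_hu,
        "index_bf": report.index_bf,
        "sac_bf": report.sac_stats.mean_bf if report.sac_stats else None,
        "sac_hu": report.sac_stats.mean_hu if report.sac_stats else None,
        "lesions": lesions,
    }


def reader_statistics(seed: int = 0, n_boot: int = 2000) -> dict:
    """Kappa agreement, consensus totals and dose conversions from the
    packaged reader-count and DLP tables."""
    table = load_reader_table()
    out: dict = {}
    for tech in ("dCTA", "dCTP"):
        a1 = table.ratings(tech, "A", 1)
        a2 = table.ratings(tech, "A", 2)
        b1 = table.ratings(tech, "B", 1)
        b2 = table.ratings(tech, "B", 2)
        per_patient, total = consensus_counts(table, tech)
        out[tech] = {
            "kappa_inter_first_read": weighted_kappa(a1, b1),
            "kappa_inter_second_read": weighted_kappa(a2, b2),
            "kappa_intra_observer_A": weighted_kappa(a1, a2),
            "kappa_intra_observer_B": weighted_kappa(b1, b2),
            "kappa_inter_first_read_ci": kappa_ci(a1, b1, n_boot=n_boot, seed=seed),
            "consensus_total": total,
        }
    out["triphasic_total"] = int(table.reference().sum())
    dose = load_dose_table()
    out["effective_dose_msv"] = {
        row["scan_phase"]: effective_dose(row["dlp_mgycm"])
        for _, row in dose.iterrows()
    }
    return out


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the packaged reader/dose CSVs and three small phantoms (no-leak,
    single-leak, two-feeder) with ground-truth masks into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    load_reader_table().to_csv(out / "reader_counts.csv")
    load_dose_table().to_csv(out / "dose_dlp.csv", index=False)
    paths["reader_counts"] = str(out / "reader_counts.csv")
    paths["dose_dlp"] = str(out / "dose_dlp.csv")
    small = dict(shape=(24, 32, 32), spacing=(5.0, 3.0, 3.0))
    for preset in ("no-leak", "single-leak", "two-feeder"):
        conf = preset_config(preset, noise_sd=5.0, rng_seed=seed)
        conf = replace(conf, **small, lumen_radius_mm=9.0, sac_radius_mm=27.0,
                       sac_z_range_mm=(20.0, 100.0))
        if preset == "single-leak":
            conf = replace(conf, blobs=(replace(conf.blobs[0], center_mm=(60.0, 18.0, 0.0)),))
        elif preset == "two-feeder":
            conf = replace(conf, blobs=(
                replace(conf.blobs[0], center_mm=(45.0, 18.0, 0.0)),
                replace(conf.blobs[1], center_mm=(80.0, -18.0, 0.0)),
            ))
        volume, truth = generate_phantom(conf)
        stem = preset.replace("-", "_")
        save_dynamic_volume(volume, out / f"{stem}.nii", out / f"{stem}_times.csv")
        save_masks(truth, conf.spacing, out / f"{stem}_masks.nii")
        paths[preset] = str(out / f"{stem}.nii")
    return paths
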