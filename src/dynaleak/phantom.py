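"""Synthetic 4D dynamic-CT phantom of a post-EVAR abdominal aorta.

The phantom emulates a shuttle-mode dynamic CT angiography acquisition of an
aortic stent-graft surrounded by a thrombosed aneurysm sac, with optional
endoleak lesions perfused by gamma-variate contrast kinetics.  Geometry is a
concentric-cylinder model (patent lumen inside the sac) with spherical
endoleak blobs; every voxel of a region carries that region's kinetic curve
sampled on the acquisition schedule, plus additive Gaussian noise in HU.

Array convention: 4D data is ordered ``(time, z, y, x)``; spatial masks share
the ``(z, y, x)`` grid; indices are 0-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionSchedule",
    "KineticParams",
    "SphereBlob",
    "PhantomConfig",
    "DynamicVolume",
    "GroundTruth",
    "default_schedule",
    "gamma_variate",
    "generate_phantom",
    "preset_config",
    "PRESETS",
    "save_dynamic_volume",
    "load_dynamic_volume",
    "save_masks",
    "load_masks",
]


class PhantomConfigError(ValueError):
    """Raised for geometrically or kinetically invalid phantom configurations."""


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Scan times in seconds since the start of contrast injection."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("schedule needs at least one acquisition time")
        if np.any(t < 0):
            raise ValueError("acquisition times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    def __len__(self) -> int:
        return len(self.times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


def default_schedule() -> AcquisitionSchedule:
    """Shuttle-mode schedule: first scan 2 s post-injection, then every 4 s
    for 12 scans total, then three more scans at 10 s intervals (15 frames)."""
    fast = [2.0 + 4.0 * k for k in range(12)]
    slow = [fast[-1] + 10.0 * (k + 1) for k in range(3)]
    return AcquisitionSchedule(tuple(fast + slow))


@dataclass(frozen=True)
class KineticParams:
    """Gamma-variate bolus kinetics for one tissue region.

    The enhancement curve is ``baseline_hu`` until contrast arrival at
    ``onset``; it then follows a gamma-variate
    ``A * x**alpha * exp(alpha * (1 - x))`` with ``x = (t - onset) /
    (time_to_peak - onset)``, reaching ``baseline_hu + peak_amplitude``
    exactly at ``time_to_peak``.  After the peak the curve decays toward
    ``baseline_hu + recirculation_fraction * peak_amplitude``; a large
    ``shape_alpha`` gives the rapid washout typical of arterially fed
    endoleaks, ``recirculation_fraction > 0`` models the contrast that
    recirculates and plateaus instead of washing out completely.
    """

    baseline_hu: float
    onset: float
    time_to_peak: float
    peak_amplitude: float
    shape_alpha: float = 3.0
    recirculation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.onset < self.time_to_peak:
            raise PhantomConfigError(
                f"onset ({self.onset}) must precede time_to_peak ({self.time_to_peak})"
            )
        if self.peak_amplitude < 0:
            raise PhantomConfigError("peak_amplitude must be >= 0")
        if self.shape_alpha <= 0:
            raise PhantomConfigError("shape_alpha must be > 0")
        if not 0.0 <= self.recirculation_fraction <= 1.0:
            raise PhantomConfigError("recirculation_fraction must lie in [0, 1]")


def gamma_variate(t: float | np.ndarray, params: KineticParams) -> float | np.ndarray:
    """Evaluate a region's attenuation (HU) at time(s) ``t`` seconds.

    Continuous in t; equals ``baseline_hu`` for ``t <= onset`` and
    ``baseline_hu + peak_amplitude`` at ``t == time_to_peak``.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)

    x = (t_arr - params.onset) / (params.time_to_peak - params.onset)
    g = np.zeros_like(t_arr)
    rising = x > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g[rising] = np.exp(
            params.shape_alpha * (np.log(x[rising]) + 1.0 - x[rising])
        )
    # Past the peak the washout settles on the recirculation plateau:
    # enhancement = A * (r + (1 - r) * g), continuous at the peak where g = 1.
    r = params.recirculation_fraction
    enh = np.where(x > 1.0, r + (1.0 - r) * g, g) * params.peak_amplitude
    out = params.baseline_hu + enh
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SphereBlob:
    """Spherical endoleak lesion: centre in mm (z, y, x from grid origin),
    radius in mm, and its kinetic parameters."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    kinetics: KineticParams

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise PhantomConfigError("blob radius must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (48, 64, 64)          # (z, y, x) voxels
    spacing: tuple[float, float, float] = (5.0, 1.5, 1.5)  # mm per axis
    lumen_radius_mm: float = 9.0
    sac_radius_mm: float = 27.0
    sac_z_range_mm: tuple[float, float] = (40.0, 200.0)
    blobs: tuple[SphereBlob, ...] = ()
    lumen_kinetics: KineticParams = field(
        default_factory=lambda: KineticParams(40.0, 10.0, 24.0, 250.0, 3.0, 0.3)
    )
    sac_kinetics: KineticParams = field(
        default_factory=lambda: KineticParams(47.0, 25.0, 60.0, 8.0, 2.0, 0.5)
    )
    background_hu: float = 30.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    schedule: AcquisitionSchedule = field(default_factory=default_schedule)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be >= 0")
        if self.lumen_radius_mm >= self.sac_radius_mm:
            raise PhantomConfigError("lumen radius must be smaller than sac radius")


@dataclass
class DynamicVolume:
    """4D HU series ordered (time, z, y, x) with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    times: AcquisitionSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("DynamicVolume.data must be 4D (time, z, y, x)")
        if self.data.shape[0] != len(self.times):
            raise ValueError(
                f"time axis length {self.data.shape[0]} != schedule length {len(self.times)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU values must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class GroundTruth:
    lumen_mask: np.ndarray
    sac_mask: np.ndarray
    endoleak_masks: list[np.ndarray]
    true_kinetics: dict[str, KineticParams]

    def __post_init__(self) -> None:
        masks = [self.lumen_mask, self.sac_mask, *self.endoleak_masks]
        total = np.zeros(self.lumen_mask.shape, dtype=np.int32)
        for m in masks:
            if m.shape != self.lumen_mask.shape:
                raise ValueError("all masks must share one spatial grid")
            total += m.astype(np.int32)
        if np.any(total > 1):
            raise ValueError("ground-truth masks must be pairwise disjoint")
        for i, m in enumerate(self.endoleak_masks):
            if not m.any():
                raise ValueError(f"endoleak mask {i} is empty")

    @property
    def anatomical_sac(self) -> np.ndarray:
        """Thrombus plus lesions: the full sac volume a reader would search."""
        out = self.sac_mask.copy()
        for m in self.endoleak_masks:
            out |= m
        return out


def _region_masks(config: PhantomConfig):
    nz, ny, nx = config.shape
    dz, dy, dx = config.spacing
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    cy, cx = (ny - 1) / 2.0 * dy, (nx - 1) / 2.0 * dx
    rho = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)  # in-plane distance to axis

    lumen = np.broadcast_to(rho <= config.lumen_radius_mm, (nz, ny, nx)).copy()
    z0, z1 = config.sac_z_range_mm
    in_sac_z = (z >= z0) & (z <= z1)
    annulus = (rho > config.lumen_radius_mm) & (rho <= config.sac_radius_mm)
    sac = annulus & in_sac_z

    blob_masks = []
    for blob in config.blobs:
        bz, by, bx = blob.center_mm
        dist2 = (z - bz) ** 2 + (y - cy - by) ** 2 + (x - cx - bx) ** 2
        m = dist2 <= blob.radius_mm**2
        if not m.any():
            raise PhantomConfigError("endoleak blob contains no voxels on this grid")
        if (m & lumen).any():
            raise PhantomConfigError("endoleak blob overlaps the graft lumen")
        if (m & ~sac).any():
            raise PhantomConfigError("endoleak blob extends outside the aneurysm sac")
        blob_masks.append(m)
    for i, a in enumerate(blob_masks):
        for b in blob_masks[i + 1 :]:
            if (a & b).any():
                raise PhantomConfigError("endoleak blobs overlap each other")
    for m in blob_masks:
        sac = sac & ~m
    return lumen, sac, blob_masks


def generate_phantom(config: PhantomConfig) -> tuple[DynamicVolume, GroundTruth]:
    """Render the 4D phantom and its ground truth.

    Each voxel's time series is its region's kinetic curve sampled at the
    schedule times plus independent zero-mean Gaussian noise of sd
    ``noise_sd``; identical configs (seed included) give bit-identical output.
    """
    lumen, sac, blob_masks = _region_masks(config)
    t = config.schedule.as_array()
    nt = t.size

    data = np.full((nt, *config.shape), config.background_hu, dtype=np.float64)
    regions: list[tuple[np.ndarray, KineticParams]] = [
        (lumen, config.lumen_kinetics),
        (sac, config.sac_kinetics),
    ]
    for blob, m in zip(config.blobs, blob_masks):
        regions.append((m, blob.kinetics))
    for mask, kin in regions:
        curve = gamma_variate(t, kin)
        data[:, mask] = curve[:, None]

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.rng_seed)
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    volume = DynamicVolume(data.astype(np.float32), config.spacing, config.schedule)
    kinetics = {"aortic_lumen": config.lumen_kinetics, "aneurysm_sac": config.sac_kinetics}
    for i, blob in enumerate(config.blobs):
        kinetics[f"endoleak_{i}"] = blob.kinetics
    truth = GroundTruth(lumen, sac, blob_masks, kinetics)
    return volume, truth


# ---------------------------------------------------------------------------
# Presets
#
# The paper-calibrated preset targets the cohort's reported enhancement:
# endoleak peak ~194 HU absolute (sac baseline 47 HU + 147 HU amplitude) with
# wash-in starting after 20 s and a peak at 36 s followed by rapid washout;
# aortic time-to-peak 24 s; a near-flat thrombosed sac around 47 HU.  The
# two-feeder preset models a single type II endoleak fed cranially by a lumbar
# artery (peak 38 s) and caudally by the inferior mesenteric artery (peak 48 s)
# as two disjoint blobs.

_LEAK_KINETICS = KineticParams(
    baseline_hu=47.0, onset=20.0, time_to_peak=36.0, peak_amplitude=147.0,
    shape_alpha=5.0, recirculation_fraction=0.0,
)
_FEEDER_CRANIAL = KineticParams(
    baseline_hu=47.0, onset=24.0, time_to_peak=38.0, peak_amplitude=160.0,
    shape_alpha=8.0, recirculation_fraction=0.0,
)
_FEEDER_CAUDAL = KineticParams(
    baseline_hu=47.0, onset=40.0, time_to_peak=48.0, peak_amplitude=140.0,
    shape_alpha=3.0, recirculation_fraction=0.0,
)


def preset_config(name: str, *, noise_sd: float = 0.0, rng_seed: int = 0) -> PhantomConfig:
    """Return a named phantom configuration.

    Presets: ``no-leak``, ``single-leak`` / ``paper-calibrated`` (one lesion,
    peak 36 s), ``two-feeder`` (two disjoint blobs peaking at 38 s and 48 s).
    """
    base = PhantomConfig(noise_sd=noise_sd, rng_seed=rng_seed)
    if name == "no-leak":
        return base
    if name in ("single-leak", "paper-calibrated"):
        blob = SphereBlob(center_mm=(120.0, 18.0, 0.0), radius_mm=6.0, kinetics=_LEAK_KINETICS)
        return replace(base, blobs=(blob,))
    if name == "two-feeder":
        blobs = (
            SphereBlob(center_mm=(100.0, 18.0, 0.0), radius_mm=6.0, kinetics=_FEEDER_CRANIAL),
            SphereBlob(center_mm=(150.0, -18.0, 0.0), radius_mm=6.0, kinetics=_FEEDER_CAUDAL),
        )
        return replace(base, blobs=blobs)
    raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


PRESETS = ("no-leak", "single-leak", "paper-calibrated", "two-feeder")


# ---------------------------------------------------------------------------
# I/O — 4D NIfTI with a sidecar CSV of acquisition times

def _affine(spacing: Sequence[float]) -> np.ndarray:
    # NIfTI axis order is (x, y, z); our arrays are (z, y, x).
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def save_dynamic_volume(volume: DynamicVolume, nifti_path: str | Path,
                        times_csv: str | Path | None = None) -> None:
    """Write the series as 4D NIfTI (time last, per convention) plus a
    sidecar table ``frame_index,time_s``."""
    nifti_path = Path(nifti_path)
    arr = np.transpose(volume.data, (3, 2, 1, 0))  # (x, y, z, t)
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(volume.spacing))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(nifti_path))
    if times_csv is None:
        times_csv = nifti_path.with_suffix("").with_suffix("")  # strip .nii[.gz]
        times_csv = Path(str(times_csv) + "_times.csv")
    with open(times_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "time_s"])
        for i, ti in enumerate(volume.times.times):
            w.writerow([i, ti])


def load_dynamic_volume(nifti_path: str | Path, times_csv: str | Path) -> DynamicVolume:
    img = nib.load(str(nifti_path))
    arr = np.transpose(np.asarray(img.dataobj, dtype=np.float32), (3, 2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    with open(times_csv, newline="") as fh:
        rows = list(csv.DictReader(fh))
    times = AcquisitionSchedule(tuple(float(r["time_s"]) for r in rows))
    return DynamicVolume(arr, spacing, times)


def save_masks(truth: GroundTruth, spacing: Sequence[float], path: str | Path) -> None:
    """Write masks as one labelled 3D NIfTI: 1 = lumen, 2 = sac thrombus,
    3.. = endoleak lesions."""
    labels = np.zeros(truth.lumen_mask.shape, dtype=np.int16)
    labels[truth.lumen_mask] = 1
    labels[truth.sac_mask] = 2
    for i, m in enumerate(truth.endoleak_masks):
        labels[m] = 3 + i
    arr = np.transpose(labels, (2, 1, 0))
    nib.save(nib.Nifti1Image(arr, _affine(spacing)), str(path))


def load_masks(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    img = nib.load(str(path))
    labels = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
    lumen = labels == 1
    sac = labels == 2
    lesions = [labels == v for v in range(3, int(labels.max()) + 1)]
    return lumen, sac, lesions
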