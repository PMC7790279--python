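"""Maximum-upslope blood-flow estimation and color-coded perfusion maps.

Blood flow is estimated by the classic maximum-slope method:

    BF = max upslope of the tissue TAC / peak arterial enhancement

with the tissue upslope in HU/s and the arterial input function (AIF) peak in
HU above its baseline, so the quotient has units 1/s.  The conventional
factor 6000 converts 1/s to mL/100 mL/min (100 mL x 60 s).  Absolute values
depend on sampling rate and the upslope estimator and are not calibrated
against any scanner console; ratios and orderings are the quantities of
interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .phantom import DynamicVolume, save_dynamic_volume  # noqa: F401  (re-export convenience)
from .phantom import _affine
from .tac import AttenuationCurve

__all__ = [
    "PerfusionMap",
    "MAX_SLOPE_SCALE",
    "reduce_noise_4d",
    "motion_correct",
    "max_upslope",
    "blood_flow",
    "bf_map",
    "save_perfusion_map",
]

#: (HU/s)/HU -> mL/100 mL/min under the standard max-slope normalization.
MAX_SLOPE_SCALE = 6000.0


class InvalidInputFunction(ValueError):
    """AIF has no positive enhancement above baseline; BF is undefined."""


@dataclass
class PerfusionMap:
    """Per-voxel blood flow in mL/100 mL/min inside ``valid_mask``."""

    bf: np.ndarray
    valid_mask: np.ndarray
    aif_max: float                       # peak AIF enhancement above baseline, HU
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.bf[self.valid_mask]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("BF must be finite and >= 0 wherever valid")


def reduce_noise_4d(volume: DynamicVolume, window: int = 5, polyorder: int = 2) -> DynamicVolume:
    """Temporal Savitzky-Golay denoising of the 4D series.

    Filters each voxel's time series in frame-index domain (the schedule tail
    is non-uniform; the induced bias there is small relative to noise and is
    shared by all voxels).  Constant series pass through unchanged; white
    noise is attenuated.  Spatial axes are left untouched so that voxel noise
    stays independent — relevant for threshold-based lesion detection.
    """
    n = volume.n_frames
    if n < 3:
        raise ValueError("need at least 3 frames for noise reduction")
    win = min(window, n if n % 2 == 1 else n - 1)
    if win < 3:
        win = 3
    poly = min(polyorder, win - 2)
    smoothed = savgol_filter(volume.data.astype(np.float64), win, poly,
                             axis=0, mode="nearest")
    return DynamicVolume(smoothed.astype(volume.data.dtype, copy=False),
                         volume.spacing, volume.times)


def motion_correct(volume: DynamicVolume, transforms=None) -> DynamicVolume:
    """Frame-alignment hook. Phantoms are generated aligned, so the default is
    the identity; ``transforms`` (one rigid transform per frame) is accepted
    for interface compatibility and must be None or all-identity here."""
    if transforms is not None:
        raise NotImplementedError("only identity motion correction is provided")
    return volume


def _window_weights(times: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope weights for every window of consecutive samples.

    Returns (n_windows, window) such that ``weights[k] @ y[k:k+window]`` is
    the LS slope of y against the actual acquisition times in that window.
    """
    n = times.size
    n_win = n - window + 1
    w = np.empty((n_win, window))
    for k in range(n_win):
        t = times[k : k + window]
        tc = t - t.mean()
        w[k] = tc / np.sum(tc * tc)
    return w


def max_upslope(curve: AttenuationCurve, window: int = 3) -> float:
    """Maximum least-squares slope (HU/s) over sliding windows of ``window``
    consecutive samples; negative maxima clamp to 0."""
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    if len(curve) < window:
        raise ValueError(f"curve has {len(curve)} samples, need >= {window}")
    w = _window_weights(curve.times, window)
    # centre each window so a constant signal yields exactly zero slope
    slopes = np.array([wk @ (curve.values[k : k + window]
                             - curve.values[k : k + window].mean())
                       for k, wk in enumerate(w)])
    return float(max(slopes.max(), 0.0))


def _aif_peak_enhancement(aif: AttenuationCurve) -> float:
    base = aif.values[0]
    peak = float(np.max(aif.values) - base)
    if peak <= 0:
        raise InvalidInputFunction("AIF shows no enhancement above baseline")
    return peak


def blood_flow(tac: AttenuationCurve, aif: AttenuationCurve, window: int = 3) -> float:
    """Max-slope blood flow of one region, mL/100 mL/min."""
    return MAX_SLOPE_SCALE * max_upslope(tac, window) / _aif_peak_enhancement(aif)


def bf_map(volume: DynamicVolume, aif: AttenuationCurve, roi: np.ndarray,
           window: int = 3) -> PerfusionMap:
    """Per-voxel max-slope blood flow over every voxel's own time series
    inside ``roi``. Deterministic; voxels outside the ROI hold 0 and are
    flagged invalid."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != volume.grid_shape:
        raise ValueError("ROI shape does not match the volume grid")
    if not roi.any():
        raise ValueError("ROI is empty")
    aif_max = _aif_peak_enhancement(aif)
    times = volume.times.as_array()
    if volume.n_frames < window:
        raise ValueError("too few frames for the requested upslope window")
    y = volume.data[:, roi].astype(np.float64)          # (T, N)
    w = _window_weights(times, window)                   # (K, window)
    n_win = w.shape[0]
    slopes = np.empty((n_win, y.shape[1]))
    for k in range(n_win):
        yw = y[k : k + window]
        slopes[k] = w[k] @ (yw - yw.mean(axis=0))
    up = np.clip(slopes.max(axis=0), 0.0, None)
    bf = np.zeros(volume.grid_shape)
    bf[roi] = MAX_SLOPE_SCALE * up / aif_max
    return PerfusionMap(bf, roi, aif_max,
                        params={"window": window, "scale": MAX_SLOPE_SCALE})


def save_perfusion_map(pmap: PerfusionMap, spacing, out_dir: str | Path,
                       stem: str = "bf", vmax: float = 250.0) -> dict:
    """Write the BF map as 3D NIfTI, one color-coded PNG per axial slice
    (viridis, display window [0, vmax] mL/100 mL/min) and a JSON parameter
    sidecar. Returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nifti = out_dir / f"{stem}.nii"
    nib.save(nib.Nifti1Image(np.transpose(pmap.bf, (2, 1, 0)).astype(np.float32),
                             _affine(spacing)), str(nifti))
    png_dir = out_dir / f"{stem}_slices"
    png_dir.mkdir(exist_ok=True)
    pngs = []
    for z in range(pmap.bf.shape[0]):
        if not pmap.valid_mask[z].any():
            continue
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.imshow(pmap.bf[z], cmap="viridis", vmin=0.0, vmax=vmax, origin="lower")
        ax.set_axis_off()
        p = png_dir / f"{stem}_z{z:03d}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        pngs.append(str(p))
    sidecar = out_dir / f"{stem}_params.json"
    with open(sidecar, "w") as fh:
        json.dump({**pmap.params, "aif_max_hu": pmap.aif_max, "vmax": vmax}, fh, indent=2)
    return {"nifti": str(nifti), "pngs": pngs, "params": str(sidecar)}
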