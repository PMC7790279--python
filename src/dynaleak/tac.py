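"""Time-attenuation curves (TAC) and arterial input functions (AIF).

A TAC is the mean HU of a region of interest over the acquisition frames; the
AIF is the TAC of the supplying artery (here, the aortic lumen cranial to the
stent-graft) and normalizes the perfusion computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import DynamicVolume

__all__ = [
    "AttenuationCurve",
    "KineticSummary",
    "extract_tac",
    "time_to_peak",
    "peak_difference",
    "standard_roi",
    "curves_to_csv",
    "curves_from_csv",
]


@dataclass(frozen=True)
class AttenuationCurve:
    """(time, HU) samples for one region. ``role`` is "TAC" or "AIF"."""

    times: np.ndarray
    values: np.ndarray
    region_label: str = ""
    role: str = "TAC"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KineticSummary:
    time_to_peak: float   # s, on the sampled grid (earliest frame at the max)
    peak_value: float     # HU
    baseline: float       # HU, first-frame value
    washout_observed: bool


def extract_tac(volume: DynamicVolume, mask: np.ndarray, label: str = "",
                role: str = "TAC") -> AttenuationCurve:
    """Mean HU over the masked voxels, frame by frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.grid_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume grid {volume.grid_shape}"
        )
    if not mask.any():
        raise ValueError("mask is empty")
    values = volume.data[:, mask].mean(axis=1)
    return AttenuationCurve(volume.times.as_array(), values, label, role)


def time_to_peak(curve: AttenuationCurve, washout_fraction: float = 0.2,
                 refine: str | None = None) -> KineticSummary:
    """Locate the enhancement peak on the sampled grid.

    Ties at the maximum go to the earliest frame.  ``washout_observed`` is
    true when some post-peak value drops below the peak by more than
    ``washout_fraction`` of (peak - baseline).  ``refine="parabolic"`` fits a
    parabola through the peak sample and its neighbours for a sub-sample peak
    time; by default the sampled frame time is reported.
    """
    if len(curve) < 2:
        raise ValueError("need at least two samples to locate a peak")
    v, t = curve.values, curve.times
    i = int(np.argmax(v))
    peak, baseline = float(v[i]), float(v[0])
    tp = float(t[i])
    if refine == "parabolic" and 0 < i < len(curve) - 1:
        y0, y1, y2 = float(v[i - 1]), float(v[i]), float(v[i + 1])
        if y0 - 2 * y1 + y2 < 0:  # proper local max
            # vertex of the parabola through three (possibly uneven) samples
            x0, x1, x2 = (float(x) for x in t[i - 1 : i + 2])
            a = y0 * (x1 - x2) + y1 * (x2 - x0) + y2 * (x0 - x1)
            b = y0 * (x2**2 - x1**2) + y1 * (x0**2 - x2**2) + y2 * (x1**2 - x0**2)
            if a != 0:
                tp = float(-b / (2 * a))
    washout = False
    if i < len(curve) - 1 and peak > baseline:
        washout = bool(np.any(v[i + 1 :] < peak - washout_fraction * (peak - baseline)))
    return KineticSummary(tp, peak, baseline, washout)


def peak_difference(arterial: KineticSummary, lesion: KineticSummary) -> float:
    """Lesion time-to-peak minus arterial time-to-peak, sign preserved (s)."""
    return lesion.time_to_peak - arterial.time_to_peak


def standard_roi(mask: np.ndarray, spacing: tuple[float, float, float],
                 area_mm2: float = 100.0) -> np.ndarray:
    """Pick a standardized ~1 cm^2 in-plane ROI inside ``mask``.

    Whole voxels on the mask's centroid slice, nearest the in-plane centroid,
    whose footprint totals closest to ``area_mm2``; a region smaller than the
    target area is returned whole (free-hand ROI around the entire lesion).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    dz, dy, dx = spacing
    voxel_area = dy * dx
    n_target = max(1, round(area_mm2 / voxel_area))
    if mask.sum() <= n_target:
        return mask.copy()
    zz, yy, xx = np.nonzero(mask)
    z_slice = int(np.round(zz.mean()))
    if not mask[z_slice].any():
        z_slice = int(np.bincount(zz).argmax())
    ys, xs = np.nonzero(mask[z_slice])
    if ys.size <= n_target:
        sel_y, sel_x = ys, xs
    else:
        cy, cx = ys.mean(), xs.mean()
        order = np.argsort((ys - cy) ** 2 + (xs - cx) ** 2, kind="stable")[:n_target]
        sel_y, sel_x = ys[order], xs[order]
    out = np.zeros_like(mask)
    out[z_slice, sel_y, sel_x] = True
    return out


def curves_to_csv(curves: list[AttenuationCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "time_s": c.times, "hu": c.values,
            "region_label": c.region_label, "role": c.role,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def curves_from_csv(path: str | Path) -> list[AttenuationCurve]:
    df = pd.read_csv(path)
    out = []
    for (label, role), grp in df.groupby(["region_label", "role"], sort=False):
        grp = grp.sort_values("time_s")
        out.append(AttenuationCurve(grp["time_s"].to_numpy(),
                                    grp["hu"].to_numpy(), str(label), str(role)))
    return out
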