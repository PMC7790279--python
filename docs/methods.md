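# Methods

## The phantom: what it emulates and what it does not

The synthetic 4D series stands in for a shuttle-mode dynamic CT acquisition
of a post-EVAR abdominal aorta. Geometry is deliberately simple: a patent
graft lumen (cylinder, radius 9 mm) running through a thrombosed aneurysm
sac (annulus to radius 27 mm over a 160 mm craniocaudal extent), with
endoleak lesions as spheres (radius 6 mm ≈ 0.9 mL) inside the sac. The
default grid is 64×64 in-plane voxels at 1.5 mm over 48 slices of 5 mm,
matching the 5 mm dynamic section thickness; everything outside the
vessel/sac is constant soft tissue (30 HU).

Contrast kinetics follow a gamma-variate bolus model per region,

```
C(t) = B + A · x^α · exp(α (1 − x)),   x = (t − t0)/(tp − t0),  t > t0,
```

with baseline `B` (HU), arrival `t0` (s), peak time `tp` (s), amplitude `A`
(HU) and shape `α` (unitless; larger α → sharper wash-in and faster
wash-out). Past the peak the curve relaxes toward
`B + r·A` where `r ∈ [0,1]` is a recirculation fraction, continuous at the
peak. The gamma-variate is the standard first-pass bolus model and is the
package's own choice; only the qualitative TAC features (wash-in after 20 s,
endoleak peak near 36 s, rapid wash-out; aortic peak near 24 s) are imposed
as calibration targets.

Default ("paper-calibrated") kinetics:

| region        | B (HU) | t0 (s) | tp (s) | A (HU) | α | r |
|---------------|-------:|-------:|-------:|-------:|--:|--:|
| aortic lumen  | 40     | 10     | 24     | 250    | 3 | 0.3 |
| aneurysm sac  | 47     | 25     | 60     | 8      | 2 | 0.5 |
| endoleak      | 47     | 20     | 36     | 147    | 5 | 0 |

so the lesion peaks at 47 + 147 = 194 HU absolute and the thrombosed sac sits
near 47 HU — the cohort-median enhancement levels. The two-feeder preset
models one type II endoleak fed by two vessels as two disjoint blobs with
component peaks at 38 s (cranial, lumbar artery; α = 8, rapid wash-out) and
48 s (caudal, inferior mesenteric artery; α = 3).

The acquisition schedule is 2 + 4k s for k = 0..11 followed by three scans at
10 s intervals (15 frames; last at 76 s). Noise is additive, zero-mean,
homoscedastic Gaussian in HU, independent across voxels and frames, with a
single integer seed controlling all randomness. Default study noise is
10 HU.

Not emulated: beam hardening, scatter, metal artifacts from the stent-graft,
dual-energy blending, partial-volume mixing at region boundaries, patient
motion (frames are generated aligned; `motion_correct` is an identity hook
accepting per-frame transforms), spatially correlated reconstruction noise,
and thrombus heterogeneity. Passing tests therefore show the estimators are
correct and robust to white noise at clinical amplitude — not that the
pipeline survives motion, artifacts, or textured thrombus on real scans.

## TAC extraction and kinetics

A TAC is the frame-wise mean HU over a boolean region mask; the AIF is the
lumen TAC restricted to the cranial-most lumen slices (automatic AIF
placement is out of scope — the mask is an input). `standard_roi` mimics a
standardized 1 cm² measurement ROI: whole voxels nearest the in-plane
centroid on the centroid slice totalling ≈100 mm², with regions smaller than
the target returned whole (free-hand ROI around the entire lesion).

`time_to_peak` reports the earliest sampled frame attaining the curve
maximum (ties → earliest; no interpolation by default, so the error against
the continuous peak is at most one sampling interval of the segment
containing it). An optional parabolic vertex refinement through the peak and
its neighbours is available but off by default. The baseline is the
first-frame value — on the default schedule only the 2 s frame is guaranteed
pre-arrival. Washout is flagged when any post-peak value drops below the
peak by more than 20% (configurable) of peak − baseline.

## Maximum-upslope blood flow

`BF = 6000 · max_upslope(TAC) / max(AIF − AIF_baseline)`. The upslope is the
maximum over sliding windows of `window` consecutive samples (default 3) of
the least-squares slope of HU against the *actual* acquisition times;
negative maxima clamp to 0. Window 2 reduces to finite differences. The AIF
denominator is peak enhancement above baseline so that unenhanced-tissue HU
does not bias BF; the factor 6000 converts 1/s to mL/100 mL/min. With 4 s
sampling and windowed fitting the upslope of a fast bolus is underestimated
and absolute BF is not calibrated against any scanner console — ratios
(endoleak/sac) and orderings are the reliable outputs, and no absolute-BF
claim is made anywhere.

Region BF values reported per lesion/sac (`BF_EN`, `BF_AS`) are computed
from the *region-mean TAC* (average first, then max slope), as an ROI
measurement would be. The per-voxel map deliberately does not average first;
taking the mean of per-voxel map values would inherit the upward bias of a
max statistic over noisy slopes and inflate sac BF several-fold.

4D noise reduction is a temporal Savitzky–Golay filter (window 5,
order 2) applied per voxel in frame-index domain; constants pass through
unchanged and white noise SD drops by ≈30%. Edge frames use "nearest"
padding: polynomial edge extrapolation ("interp" mode) inflates
first/last-frame noise variance, which the max-upslope statistic then
preferentially selects. Spatial axes are left untouched on purpose — spatial
smoothing correlates noise between neighbouring voxels and directly inflates
false connected components at the detection threshold.

## Endoleak detection and indices

Detection operates on the BF map inside the anatomical sac (thrombus plus
any lesions): candidate voxels exceed `median(sac BF) + k_sd · robust SD`,
with robust SD = 1.4826·MAD so that the lesion itself does not lift the
threshold; 26-connected components of at least `min_voxels = 4` voxels
become lesions. Indices and statistics are computed against the residual
(non-lesion) sac. `HU_EN`/`HU_AS` are taken at each region's
peak-enhancement frame, sac noise as the HU SD there.

**Threshold calibration (`k_sd = 4`, a deliberate choice).** The per-voxel
max-upslope BF is an extreme-value statistic: under pure noise its
distribution is the maximum of ~11 near-independent window slopes, whose
right tail above `median + 3·robust SD` is ≈0.9% *independently of the noise
amplitude* (the rule is scale-free). In a ~21 000-voxel sac that yields
~200 candidate voxels and a ≥4-voxel false cluster in roughly half of all
runs. At `k_sd = 4` the measured null tail is 0.13% and 20-seed count
recovery is 100% for all presets (no-leak, single-leak, two-feeder) at 10 HU
noise with lesion Dice ≥ 0.98. Both parameters remain exposed in the config.

The report's 5-point diagnostic confidence is a heuristic mapping from the
automated result (no lesion → 1; dominant BF index ≥ 10 → 5, ≥ 3 → 4,
else 3), dichotomized as 1–2 = absent, 3–5 = present. It stands in for a
human Likert rating and is not a model of reader behaviour. Endoleak type
(I–IV) is carried as an optional annotation only; anatomical typing needs
feeder-vessel anatomy beyond the phantom.

## Reader and dose statistics

Weighted kappa uses linear weights `w_ij = 1 − |i−j|/(k−1)` on the ordinal
category set 0..max(count observed across both raters) — the count scale,
so a single patient rated 3 creates a 4-level scale. κ = 1 is returned when
chance agreement saturates (both raters constant and equal). On the packaged
19-patient count table the dCTP first-read inter-observer pair and the
observer-B intra-observer pair both give κ = 0.93, the second read and
observer A give exactly 1.0, and the dCTA session columns (identical) give
1.0. The 95% interval is a percentile bootstrap over patients (2000
resamples, seeded) — a stated convention, since interval methods for κ vary.

Wilcoxon signed-rank (zeros dropped) and Mann–Whitney U are exact for small
tie-free samples via scipy, exact via full sign-flip enumeration for tied
samples up to n = 14, and otherwise use the tie-corrected normal
approximation without continuity correction (so identical groups give
p = 1 exactly). Two-sided p is twice the smaller tail, capped at 1.
Quartiles use linear interpolation between order statistics.

Consensus lesion totals take the per-patient majority across the four
reading sessions, breaking ties toward the reference count and then toward
the lower count; on the packaged table this yields 10 (dCTA) and 11 (dCTP)
against 9 reference lesions. Effective dose is DLP × 0.015 mSv·mGy⁻¹·cm⁻¹.
Note the converted median DLPs are 15.957 and 12.435 mSv — the study-style
one-decimal figures (15.9, 12.4) are medians of per-patient doses, so
agreement is asserted to within one unit in the last printed digit.

## Pipeline, determinism, problem sizes

`run_pipeline` executes phantom → TACs → perfusion → detection → statistics,
writing NIfTI volumes, CSV curves/reports and a JSON manifest with SHA-256
checksums of all deterministic artifacts (PNG renderings are listed but not
checksummed; image encoders are not byte-stable). Identical configs and
seeds reproduce identical checksums. A full default-grid run completes in a
few seconds on one CPU.

The test suite and `scripts/acceptance.py` use the full 64×64×48 grid for
the seeded recovery studies (20 replicates per preset, ~12 s total) and a
24×32×32 grid with identical kinetics for unit tests. Degenerate inputs are
defined rather than fatal where a value exists (flat curve → zero upslope
and first-frame peak; all-zero paired differences → p = 1 with a flag) and
errors otherwise (empty masks, non-enhancing AIF, zero sac noise,
out-of-range confidence scores, overlapping phantom geometry).

## Known limitations

- Absolute BF depends on sampling rate, window length and smoothing; only
  ratios/orderings are validated.
- The homogeneous sac makes detection easier than textured real thrombus;
  the measured false-positive calibration holds for white noise only.
- The two-compartment deconvolution used by vendor consoles is not
  implemented; this package implements the printed max-slope relation.
- Kappa/consensus statistics reproduce table-level numbers; per-patient
  cohort medians and p-values that require the raw patient images are out of
  scope and only reproduced directionally on phantoms.
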