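# dynaleak

Quantitative analysis of dynamic CT angiography (dCTA) and dynamic CT
perfusion (dCTP) for the detection of **endoleaks** after endovascular repair
of abdominal aortic aneurysms (EVAR), packaged as a tested, reproducible
pipeline with a synthetic 4D phantom in place of patient scans.

After EVAR, persistent flow inside the aneurysm sac but outside the
stent-graft (an endoleak, most often type II via lumbar or inferior
mesenteric arteries) must be monitored. A shuttle-mode dynamic CT
acquisition — one scan 2 s after contrast injection, then every 4 s for 12
scans, then every 10 s for 3 more — yields a time-attenuation curve (TAC)
for every voxel. From these, blood flow is estimated by the maximum-slope
method:

```
BF = max upslope(TAC) / max enhancement(AIF)        [mL/100 mL/min]
```

where the arterial input function (AIF) is the TAC of the aorta cranial to
the graft, the upslope is a sliding-window least-squares slope in HU/s, the
AIF peak is measured above its baseline in HU, and the factor 6000 converts
1/s to mL/100 mL/min. Lesion conspicuity is quantified by two dimensionless
indices against the thrombosed sac — `HU_EN / HU_AS` (attenuation) and
`BF_EN / BF_AS` (perfusion) — and image quality by the contrast-to-noise
ratio `CNR = (HU_target − HU_sac) / noise_sac`. Reader agreement on
per-patient endoleak counts uses linearly weighted Cohen's kappa, and
radiation burden converts dose-length product to effective dose with the
abdominal factor 0.015 mSv·mGy⁻¹·cm⁻¹.

The package is aimed at researchers prototyping quantitative endoleak
analyses: it provides the phantom generator (`dynaleak.phantom`), TAC/AIF
extraction and kinetics (`dynaleak.tac`), max-upslope BF maps
(`dynaleak.perfusion`), automated lesion detection and indices
(`dynaleak.endoleak`), the reader/dose statistics (`dynaleak.stats`), and an
end-to-end pipeline with CLI (`dynaleak.pipeline`, `dynaleak` command).

## Worked example

```python
from dynaleak import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(preset="paper-calibrated", noise_sd=10.0,
                                  seed=3, out_dir="demo_run", save_pngs=False))
s = manifest.summary
print(s["detected_count"], s["true_count"])
print(round(s["index_hu"], 2), round(s["index_bf"], 1))
print(s["aortic_time_to_peak_s"], s["lesions"][0]["time_to_peak_s"])
```

prints

```
1 1
3.35 34.1
26.0 38.0
```

— the single simulated endoleak is recovered; the perfusion index (34.1) far
exceeds the attenuation index (3.35), mirroring the clinical observation
that BF maps separate endoleak from thrombus much more sharply than raw HU;
and the lesion peaks 12 s after the aorta (38 s vs 26 s on the sampled
schedule, for continuous peak times of 36 s and 24 s). The same run via the
CLI: `dynaleak run --preset paper-calibrated --seed 3 --out-dir demo_run`.
Every run writes a `manifest.json` with per-stage outputs and SHA-256
checksums; identical configs reproduce identical checksums.

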