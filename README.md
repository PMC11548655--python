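# flarekit

Quantitative image analysis for **single-color homotransfer FRET biosensors**
read out by fluorescence anisotropy, plus the two-color (heterotransfer)
ratio pipeline, a command-line interface and a fully seeded synthetic
polarization-microscopy generator for validation.

## Science background

A homotransfer FRET biosensor uses two copies of the *same* fluorophore.
Energy transfer between them cannot be detected as a color change; instead it
depolarizes the emission. Imaging through a dual-view polarization splitter
yields, for every cell, the intensity parallel (`P`) and perpendicular (`S`)
to the excitation polarization, and the fluorescence anisotropy

```
R = (P − g·S) / (P + 2·g·S)
```

where `g` corrects the detection sensitivity of the perpendicular channel.
Biosensor activation increases homotransfer and therefore *lowers* `R`; the
package reports responses as `−R`, the baseline-subtracted change `−ΔR`, and
the normalized ratio `R/R₀`, so that activation reads as a positive deflection
or a drop of `R/R₀` below 1. For conventional two-color sensors the analogous
readout is the bleedthrough-corrected ratio `(Y − b·C)/C`.

The pipeline covers: dual-view splitting, sub-pixel channel registration
(windowed phase correlation), background subtraction, `g`/`b` calibration
from reference scenes, ROI time courses (noise-optimal summed-intensity
estimator), per-cell response summaries, two-group *t*-tests, normalized
0–100 Hill dose–response fits, per-pixel activity maps, and line-ROI
kymographs.

## Worked example (library)

```python
import flarekit as fk

# simulate a 13-min drug-addition time course (6 baseline + 20 response frames)
scene = fk.make_scene(n_cells=3, seed=7)
stack, truth = fk.simulate_timecourse(scene, dose=12.0)

# split the dual view, register the perpendicular channel, extract one cell
channels = fk.register_stack(fk.split_dual_view(stack))
roi = fk.inscribed_square_roi(scene.cell_masks, 1)
trace = fk.roi_anisotropy(channels, roi, fk.BackgroundModel("percentile"), g=1.0)

# baseline-subtracted response and peak R/R0 change
neg_dr = fk.delta_over_baseline(fk.smooth_trace(trace, 3))
ratio = fk.ratio_over_t0(fk.smooth_trace(trace, 3))
peak = fk.peak_response(ratio, (0.0, ratio.t[-1]))

print(f"baseline -R: {neg_dr.meta['baseline_negR']:.4f}")
print(f"mean -dR over 2-10 min: {fk.summarize_mean_response(neg_dr, (2, 10)):.5f}")
print(f"peak R/R0 change: {peak['percent_change']:.2f}% at t = {peak['t_peak']:.1f} min")
print(f"true cell-1 response amplitude: {truth.r_true[1][-1] - truth.r_true[1][0]:.5f}")
```

Output (deterministic for `seed=7`):

```
baseline -R: -0.2964
mean -dR over 2-10 min: 0.01494
peak R/R0 change: -5.28% at t = 9.0 min
true cell-1 response amplitude: -0.01641
```

The measured mean `−ΔR` of 0.0149 tracks the injected ground-truth amplitude
of 0.0164 (the 2–10 min mean undershoots the plateau of an exponential rise),
and activation pushes `R/R₀` ≈ 5% below 1.

## Worked example (CLI)

```sh
flarekit simulate --out-dir run1 --seed 7 --dose 12
# build square ROIs from the saved cell masks
python - <<'PY'
import json, numpy as np
from flarekit import inscribed_square_roi
masks = np.loadtxt('run1/cell_masks.csv', dtype=int, delimiter=',')
regions = {f'cell_{k}': {'polygon': inscribed_square_roi(masks, int(k)), 'role': 'cell'}
           for k in np.unique(masks) if k}
open('rois.json', 'w').write(json.dumps({'regions': regions, 'lines': {}}))
PY
flarekit analyze --input run1/stack.tif --rois rois.json --out-dir analysis
head -4 analysis/summaries.csv
```

```
cell_id,mean_negdR,integrated_negdR
cell_1,0.014575735135570127,0.07060232729755382
cell_2,0.010909660096601683,0.053337411932455336
cell_3,0.014199703780235568,0.06806136243792266
```

Other subcommands: `split`, `register`, `calibrate-g`, `calibrate-b`,
`trace`, `dose-response`, `compare`, `map`, `kymograph`, `report`. Every run
writes a JSON log echoing the full merged configuration, including defaulted
fields, next to its outputs.

## Package layout

| module | contents |
|---|---|
| `flarekit.synth` | cell fields, kinetics, noise model, dual-view renderer, truth sidecars |
| `flarekit.stackio` | TIFF + sidecar I/O, dual-view splitting, ROI and trace serialization |
| `flarekit.registration` | windowed phase-correlation shift estimation and application |
| `flarekit.anisotropy` | anisotropy equation, backgrounds, `g`/`b` calibration, ROI estimators |
| `flarekit.timecourse` | smoothing, baselining, summaries, *t*-tests, Hill fits |
| `flarekit.mapping` | per-pixel activity maps, rendering, line profiles, kymographs |
| `flarekit.cli` | `flarekit` command-line entry point |

See `docs/methods.md` for the image-formation model, estimator choices and
limitations.
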