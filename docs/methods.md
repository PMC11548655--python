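# Methods note

This note documents the models and numerical choices behind `flarekit`:
what the synthetic generator simulates, how each estimator works, and where
the approach is known to break down. Every empirical statement here is
computed by the test suite (`tests/`) or by `scripts/acceptance.py`.

## 1. Readout model

### Homotransfer (single-color) mode

The observable is the fluorescence anisotropy of a dual-view polarization
image pair,

```
R = (P − g·S) / (P + 2·g·S),          R ∈ [−0.5, 1]
```

with `P` and `S` the background-corrected parallel and perpendicular channel
intensities and `g` the perpendicular-channel sensitivity correction.
Because homotransfer FRET depolarizes emission, sensor activation lowers `R`;
all user-facing time courses carry `−R` (`value_kind="negR"`), the
baseline-subtracted change `−ΔR` (`"negdR"`, baseline = mean of `−R` over
t ∈ [−3, 0) min), and the normalized ratio `R/R₀` (`"R_over_R0"`, anchored at
the frame nearest t = 0). For `R/R₀` the "peak" is the extremal deviation
from 1 inside the analysis window, because activation drives the ratio
*below* 1; reporting a plain maximum would always return the t = 0 value.

### Heterotransfer (two-color) mode

For a conventional donor/acceptor sensor the channels are donor `C` and
acceptor `Y`, and the readout is the bleedthrough-corrected ratio
`(Y − b·C)/C` with `b` the donor bleedthrough fraction. If a fraction `f` of
the emission appears in the FRET channel (`C = I(1−f)`,
`Y = I·f + b·C`), the corrected ratio equals `f/(1−f)` exactly.

## 2. Synthetic generator

The generator is built to be *invertible by construction*: with noise
disabled, the analysis pipeline must return the injected ground truth to
floating-point precision. Image formation per pixel of total emission `I`:

```
P      = I·(1 + 2r)/3 + background
S_true = I·(1 − r)/3 + background
S_det  = S_true / g                      (sensitivity attenuation)
```

so that the anisotropy equation applied to noise-free, background-corrected
`(P, S_det)` with the true `g` returns `r` identically (verified to 1e−12 in
`tests/test_synth.py` and ≤ 5e−16 end-to-end through ROI extraction in
`tests/test_acceptance.py`). The perpendicular half-view is additionally
translated by a configurable sub-pixel `channel_shift` (bilinear) before
side-by-side composition, emulating dual-view misalignment.

Noise is applied in physical order: Poisson shot noise on expected photon
counts, then Gaussian read noise, then a constant camera offset. The
per-pixel photon budget is specified as the brighter (parallel) channel's
baseline counts.

Kinetics follow a saturable drug response: `r(t) = r_base` before drug
addition and `r_base + A(dose)·(1 − exp(−t/τ))` after, with
`A(dose) = Δr_max · dose^h / (EC50^h + dose^h)` and a per-cell amplitude
factor drawn from `Normal(1, cell_sd)`. Defaults (`r_base = 0.30`,
`Δr_max = −0.02`, `τ = 2 min`, `EC50 = 3`, `h = 1`, `cell_sd = 0.1`, 30-s
cadence, 6 pre-drug + 20 post-drug frames of a 256×256 half-view) represent
a realistic live-cell biosensor experiment: a few-percent anisotropy change
developing over minutes on a 0.30 baseline. Cells are non-overlapping
ellipses with a 2-px moat; the geometry is deliberately simple, since the
generator validates estimators, not segmentation.

All randomness descends from one root seed through fixed
`SeedSequence([seed, stream])` substreams (cells, per-cell factors, one
stream per frame), so any subset of frames re-renders identically.

### Realism limits

The generator omits photobleaching, focus drift, cell motion and
morphology change, spatially varying background, detector nonlinearity, and
rotational-diffusion contributions to anisotropy. Registration is a pure
translation, matching dual-view optics but not chromatic warping. These
choices keep every pipeline stage exactly invertible, which is what the
validation needs.

## 3. Estimators and numerical choices

**Background.** Either the mean over a user background ROI or a low
percentile (default 5th) of the frame. The percentile form needs no ROI but
is biased low on noisy frames by roughly the background noise sd times a
percentile factor; the bias propagates into `R` as a multiplicative error of
order `3δ/(P+2S)`. The noise-ladder acceptance test therefore uses a
background ROI; the trade-off is documented rather than hidden.

**ROI anisotropy.** Channel intensities are background-corrected and *summed
over the ROI* before applying the anisotropy equation. Summing first is the
photon-statistics-optimal order: the ratio of sums has O(1/N_photons) bias,
whereas the mean of per-pixel ratios inherits the full per-pixel ratio bias.
Measured bias is < 2e−3 at ≥ 1e5 ROI photons/frame, and the empirical sd
halves per 4× photon increase (acceptance suite), consistent with shot-noise
scaling.

**Registration.** One translation per time course (dual-view geometry is
fixed), estimated on the first frame pair (or time-mean) by phase
correlation with mean subtraction and a 2-D Hann window
(`normalization=None`, upsampling 20). The windowing step matters: on
smooth, non-periodic cell images, unwindowed phase correlation is biased by
several tenths of a pixel; windowed, the recovered shift is within 0.1 px at
1e4 photons/pixel (acceptance suite). Shifted-in border pixels are filled
with a low percentile and excluded via a validity mask.

**Calibration.** `g` from a reference scene of known anisotropy via the
algebraic inverse `g = P(1−r_ref)/(S(1+2r_ref))`, median-aggregated over
bright pixels; `b` as the median of `Y/C` over a donor-only scene. Medians
suppress outlier pixels; both recover truth with median relative error
≈ 0.1% at 1e4 photons/pixel (bound: 2%).

**Time-course statistics.** Moving-average smoothing with odd windows
(ends shrink symmetrically); trapezoidal integration with endpoint
interpolation and explicit coverage checks; Student (pooled-variance) or
Welch two-sample *t*-tests via SciPy, validated against a textbook oracle.

**Dose–response.** Per-dose responses are normalized to 0–100 anchored on
the per-dose means of the extreme doses, then fit with a four-parameter
logistic constrained to bottom 0 / top 100, parameterized as
`(log10 EC50, h)` and solved by least squares from 5 multi-starts. Note the
anchoring makes noise-free rescaled data only approximately Hill-shaped;
exact recovery (EC50 and h to 1e−6, r² = 1) holds for data already in Hill
form, and the normalized pipeline recovers EC50 with ≈ 9% median relative
error under 10%-of-span noise (bound: 15%).

**Maps and kymographs.** Per-pixel maps background-correct each channel,
mask pixels below an intensity floor (background mean + 3 sd), Gaussian-smooth
the *channel intensities* (not the ratio — smoothing before the division
prevents small denominators from amplifying noise), then apply the
anisotropy equation and negate. Rendering uses the perceptually uniform
`inferno` colormap with invalid pixels black. Kymographs stack bilinear line
profiles (optional perpendicular width averaging) row per frame; a scripted
moving band is localized within 1 px per row.

## 4. Determinism

Identical configuration and seed reproduce byte-identical TIFFs, CSVs and
rendered images (verified in the acceptance suite). Analysis is fully
deterministic; only the generator and the Monte-Carlo studies consume
randomness, always through named substreams of the root seed.

## 5. Limitations

* Anisotropy values are reported without rotational-diffusion or NA
  depolarization corrections; `R` is an *apparent* anisotropy, as is standard
  for relative biosensor readouts.
* The percentile background estimator biases `R` on dim scenes (see above);
  use a background ROI when absolute accuracy below ~5e−3 matters.
* Registration assumes a single rigid translation; rotation, scaling, or
  field-dependent warping are out of scope.
* The Hill fit fixes bottom/top at 0/100 by design; data that do not
  saturate across the tested dose range will push EC50 toward the range edge
  and should be interpreted cautiously.
* ROI geometry is static over a time course; moving cells require external
  tracking before trace extraction.
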