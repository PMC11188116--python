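# Methods

## The measurement model

A recording is a two-channel movie: a vessel-lumen dye channel (static
over the timescales analyzed) and a Ca²⁺ indicator channel. The analysis
is built around a user-supplied capillary centerline (an ordered polyline
in pixel coordinates with a diameter in µm) and a stimulus event (onset
frame, duration, delivery site). Two quantities are produced.

**ROI ΔF/F.** Pixels within a perpendicular distance of the centerline —
three vessel diameters per side by default, or a fixed 10 µm
(`roi_mode`/`roi_extent`) — are averaged per frame. F₀ is the mean of the
`baseline_frames` (default 9, protocol range 8–10) frames ending at
onset − 1, and ΔF/F(t) = (F(t) − F₀)/F₀. No background subtraction or
bleach correction is applied: the measure is invariant to multiplicative
gain and deliberately sensitive to additive offsets. The response peak is
the maximum over frames ≥ onset, ties broken to the earliest frame; a
manually chosen peak frame can be supplied instead (peaks in the original
workflow were picked by eye).

**Sheath peak z.** The vessel-centric chain:

1. *Frame averaging.* Pixelwise means over the baseline window (as above)
   and over `peak_frames` (default 9) frames centered on the peak frame.
   If the centered window does not fit the stack it is shifted inward with
   a logged warning.
2. *Baseline subtraction.* ΔF = peak average − baseline average,
   negatives retained.
3. *Stalk mask.* Müller stalk cross-sections are the brightest objects in
   the averaged **peak** image (not the subtracted image). Pixels strictly
   above the (100 − `stalk_percentile`)-th percentile (default 3, range
   2–4) are binarized and dilated `dilation_iters` times (default 2, range
   2–3) with a 3×3 cross. Vessel-lumen pixels — found by Otsu's threshold
   on the averaged dye channel — are excluded from the percentile
   computation so the bright vessel cannot drag the threshold up. Masked
   pixels become NaN and are excluded from everything downstream. A
   constant field yields an empty mask (strict inequality) with a warning.
4. *Straightening.* The field is resampled along centerline normals: the
   polyline is re-parameterized by arclength at one-pixel steps, tangents
   come from central differences, and each normal is sampled at one-pixel
   offsets out to ±(`profile_halfwidth_um` + vessel radius), default
   20 µm + r, by bilinear interpolation. A sample is NaN if any source
   pixel with *nonzero* bilinear weight is NaN or out of bounds — so for a
   straight, axis-aligned vessel the operation is an exact identity on the
   band, masked pixels included.
5. *Collapse.* NaN-ignoring mean along the vessel axis per signed-distance
   bin; the number of valid samples per bin is recorded, empty bins are
   NaN.
6. *z-scoring.* z(d) = (raw(d) − μ_bg)/σ_bg, where μ_bg and σ_bg are the
   mean and SD (ddof = 1) of the profile over the background window
   |d| ≥ `background_min_um` (default 15 µm), pooled over both sides.
   At least 10 valid background bins are required; σ_bg = 0 is an error.
7. *Peak statistic.* Per side, the maximum z within
   (radius, radius + `sheath_search_um`] (default 10 µm); the reported
   statistic is the mean of the two sides. If one side is entirely NaN the
   statistic is flagged one-sided and carries the valid side's value.

For display, the vessel-channel profile is rescaled so its maximum equals
`vessel_display_z` (default 5); the profile is divided by its peak before
multiplying so the maximum is *exactly* the display constant. This never
feeds the statistic.

### Design choices that were genuinely open

- *z-score reference.* Which pixels define the z scale is not fixed by
  the procedure's description; we use the per-profile background
  |d| ≥ 15 µm, pooled over both sides, on the grounds that it is far from
  both vessel and sheath while still sampled under identical conditions.
  It is configurable and logged. A global-image reference would couple the
  statistic to field-of-view composition.
- *Search window.* "Both sides of the vessel" needs a bound; sheaths hug
  the wall, so we search 10 µm beyond the radius (configurable).
- *Baseline for ΔF/F.* The 8–10-frame convention from the profile
  analysis is reused for F₀, for consistency.
- *t-test flavor.* Welch (unequal variances) by default, switchable to
  pooled; when Jarque–Bera rejects normality a warning is logged and an
  optional Mann–Whitney fallback (labeled as beyond the original
  protocol) can be requested.
- *Percent of control.* Default is each treated value over the control
  group mean (unpaired experiments); a paired elementwise mode exists.

## The synthetic-recording simulator

The simulator exists so every stage above can be tested against hidden
truth. The noiseless indicator channel is an exact component sum

    F(t, y, x) = F0(y, x) + stalk(y, x)
                 + σ_ref · max(A_sheath · ring(y, x), A_wave · wave(y, x)) · act(t, y, x)

- `F0`: uniform baseline (default 100 a.u.), dimmed to 30% inside the
  vessel lumen (the indicator loads glia, not plasma).
- `stalk`: uniform bright disks (default 36 disks of radius 3 µm at
  20 σ_ref above baseline on a 192×192 µm field ≈ 3% of pixels), static
  across frames, kept clear of the lumen and the sheath ring. Stalk
  density is matched to the 2–4% masking percentile on purpose: that is
  what makes the percentile rule meaningful, as it is in real fields
  where stalks are the top-intensity pixels.
- `ring`: Gaussian annulus centered `offset_um` (default 1 µm) beyond the
  vessel edge with SD `width_um` (default 1.5 µm); zero inside the lumen.
- `wave`: diffuse parenchymal activity decaying exponentially
  (`decay_um` = 40 µm) with distance from the puff origin — the puff
  agonist dilutes with distance. The max() combination keeps the ring the
  unambiguous intensity winner at the wall so closed forms stay exact.
- `act`: a smoothstep front (exactly 0 before arrival, exactly 1 after
  `rise_s` = 1 s) arriving at each pixel at onset + distance/speed
  (default 25 µm/s from the retinal surface).
- Amplitudes are multiples of σ_ref = √(shot_scale·F0 + read_sd²), the
  background noise SD implied by the configured noise parameters
  (defaults shot_scale 1, read_sd 2 → σ_ref ≈ 10.2), computed whether or
  not noise is enabled so "amplitude" keeps its meaning in noiseless
  runs. Applied noise is Gaussian with variance shot_scale·mean +
  read_sd², the usual confocal shot + read model; absolute fluorescence
  scales and SNR are not published for such recordings, so these defaults
  are nominal and documented as such.

Ground truth returned with each dataset: the stalk pixel set, the lumen
mask, the asymptotic activity map, σ_ref, and the analytic peak ΔF/F
(A_sheath·σ_ref/F0, exact at the ring crest because the vessel center row
sits on the pixel grid).

**Condition presets** rescale amplitudes only (geometry untouched, except
the degeneration preset): `apb` scales surface-puff responses to 6% of
control (IP₃R blockade) and leaves direct-puff responses intact;
`apb_suramin` scales responses by a further 26% (purinergic blockade);
`rd10_dvp` triples the ring width, lowers its amplitude to 45%, and adds
a smooth ±2 µm along-vessel wobble of the ring center (diffuse,
irregular deep-layer sheaths). The multipliers are emulation inputs taken
from reported effect sizes, not reproduced results. Note the rd10 preset
approximately conserves total ring fluorescence (0.45 × 3 = 1.35× the
control integral) — it redistributes signal rather than removing it, so
control-vs-rd10 discrimination tests the statistic's locality, not its
brightness sensitivity.

**What the simulator does not emulate** — and therefore what passing
tests do *not* establish about real data: motion and drift (no
registration is implemented), bleaching, indicator saturation and
buffering kinetics, heterogeneous dye loading, depth-dependent scattering,
vessel diameter dynamics, temporally correlated physiological noise, and
3D geometry (a single optical section is assumed). Recovery results here
bound algorithmic correctness, not biological effect sizes; the z values
on the default synthetic field (~40 for the control preset) are far above
live-tissue values because the collapse averages hundreds of clean
samples per bin.

## Numerical choices

- Percentile: linear interpolation (numpy default); threshold comparison
  is strict (`>`), so a constant field masks nothing.
- Bilinear interpolation: zero-weight stencil neighbors do not
  contaminate; any nonzero-weight NaN or out-of-bounds neighbor does.
- SDs use ddof = 1 throughout (background z-scale, group summaries,
  baseline trace SD).
- Peak/tie-breaks: earliest frame wins; per-side profile maxima take the
  first bin at the maximum.
- Degenerate inputs fail loudly with named keys: non-positive pixel size
  or frame interval, <2 distinct centerline points, centerline steps
  ≥ 5 px, onset too early for a full baseline window, F₀ ≤ 0, σ_bg = 0,
  all-NaN search windows.
- Integer TIFF stacks round-trip bit-exactly; float stacks are written as
  float32.

## Problem sizes

Synthetic study conditions are desk-scale by design: 192×192 px at
1 µm/px, 40 frames at 0.5 s/frame, puff onset at frame 10 (the test suite
also uses 64×64 fields with the stalk count scaled to keep ~3% coverage).
A full generate-and-analyze cycle takes well under a second, so the
recovery and discrimination suites run tens of seeded replicates.

## Known limitations

- The straightening resampler is a centerline-normal bilinear scheme;
  it matches the intent of interactive straightening tools but not any
  specific kernel, and self-intersecting normals of very curly vessels
  (radius of curvature below the profile halfwidth) will double-sample
  pixels.
- The stalk mask assumes stalks are the brightest indicator structures;
  fields dominated by other bright debris would need the percentile
  adjusted.
- Null recordings show that the pipeline's extreme-value statistics are
  not conservative at round-number thresholds: across 50 seeded null
  runs, the ROI ΔF/F peak stays within 3× the baseline-trace SD in ~82%
  of runs (the peak is a maximum over ~30 frames, the SD is estimated
  from 9), and |sheath peak z| ≤ 2 in ~82% (a mean of two maxima over
  ~10 bins each). Users screening for "no response" should calibrate
  null thresholds per protocol (frame counts, bin counts) rather than
  reusing 3×SD or z = 2.
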