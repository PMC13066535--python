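# Methods

gastroflow quantifies two aspects of stomach function from dynamic MRI
data: **peristaltic motility** from per-slice antral cross-sectional
area-time curves, and **gastric emptying** from content-volume series.
Because clinical scanner data and trained segmentation networks are not
shippable, the package includes a synthetic phantom generator whose
ground truth exercises every analysis path.

## Motility model

The antrum contracts rhythmically at 2-4 cycles per minute (cpm); each
contraction is a ring of circular-muscle activity that travels aborally
toward the pylorus at roughly 1.5-2.5 mm/s, narrowing the lumen as it
passes. A three-slice sagittal real-time acquisition (5 mm slices,
distance factor DF setting the edge-to-edge gap as DF x thickness,
effective 6.24 frames/s) samples the lumen cross-section at three
positions along this path; segmentation reduces each slice to an
area-time signal a_i(t) in mm^2.

### Dominant frequency

The one-sided FFT amplitude spectrum of the mean-removed **raw** signal
is searched inside the contraction band 0.03-0.07 Hz (1.8-4.2 cpm).
The peak is accepted only when its *dominance factor* — peak amplitude
over the mean amplitude of all in-band bins, peak included — reaches
2.0. Detrending is mean removal only; for records of 90 s or more, DC
leakage into a band starting at 0.03 Hz is negligible, and anything more
aggressive would touch the signal the metric is defined on. No
zero-padding or peak interpolation is applied: the reported frequency is
a spectral grid point, with resolution 1/duration (0.33 cpm at 180 s,
0.67 cpm at 90 s). Equal peak amplitudes resolve to the lower frequency
(deterministic tie-break). Records shorter than 30 s are rejected.

A timepoint-level mean frequency is the unweighted arithmetic mean over
slices with a valid peak, reported only when at least two of three
slices are valid (the two-of-three rule); the apparent speed inherits
this gating.

### Band-pass and display smoothing

The band is applied literally as an ideal spectral mask (out-of-band DFT
bins zeroed, DC included), which is exactly idempotent and exactly
rejects respiratory interference (0.15-0.30 Hz). Savitzky-Golay
smoothing (window 59 frames, order 1) exists for display only and never
feeds spectral analysis; series shorter than the window get the largest
odd window that fits, with a logged warning. Its only tested contract is
interior-point behavior (boundary handling follows scipy's default).

### Occlusion

Occlusion is the relative lumen narrowing against a relaxed reference:

    occlusion% = 100 x (1 - area / reference),   clipped below at 0

with the reference the **median of the ceil(0.10 N) largest areas** of
the record (midpoint rule for even counts). Negative values are clipped
because the lumen cannot be more open than its relaxed state; complete
closure is 100%. The mean over frames summarizes contractile strength.
Occlusion and frequency are invariant under rescaling of all areas, so
pixel-size calibration errors do not bias them.

### Propagation distance and apparent speed

For the three-slice stack the effective sampled span is

    distance = 3 x thickness + 2 x gap        (mm)

the outer-edge extent from slice 1 to slice 3 (DF 1.5-3.5 with 5 mm
slices gives 30-50 mm). Note this is deliberately the outer-edge span,
not the slice-center separation 2 x (thickness + gap); the distinction
matters below. The apparent propagation speed assumes one wave traverses
that span per contraction cycle:

    speed = frequency[cpm] / 60 x distance    (mm/s)

It is *apparent* rather than a true phase speed — the contraction spans
several slices and has no sharp spatial peak.

### Cross-correlation speed (independent check)

The band-passed outer-slice signals are cross-correlated (normalized by
full-signal norms, lags quantized to the frame interval) within +/- one
dominant period — the delay of a periodic wave is only defined modulo
its period. Two lags are reported:

* the unrestricted optimum (diagnostic; reversing the slice order
  negates it);
* the best **strictly positive** lag, used for the speed. This encodes
  the anatomical prior that the wave travels along increasing slice
  index (toward the pylorus). Without it the estimate is ill-posed: any
  true delay beyond half a period aliases to a negative lag, and for
  in-band frequencies the outer-slice delay always exceeds half a
  period.

Speed = propagation distance / delay; the result is absent (with a
logged reason) when the best forward delay is within one frame interval,
e.g. for identical signals. Because the numerator is the outer-edge span
while the wave physically covers the center-to-center span, the
cross-correlation speed systematically exceeds the true speed by
(3T + 2g)/(2T + 2g) — between 1.11 (DF 3.5) and 1.2 (DF 1.5) — a bias
shared with the apparent speed and reported, not hidden.

## Emptying model

Gastric content volume (mL) is foreground voxel count times voxel volume
on segmented static volumes. Only T1-bright (manganese-labeled) content
is counted, so the baseline reflects absence of labeled content, not
true fasting volume. Over an **explicit** fit window (no automatic
changepoint detection):

* emptying rate = negated OLS slope of V on t (mL/min);
* first-order fit: OLS of ln V on t, c0 = exp(intercept), k = -slope,
  t_1/2 = ln(2)/k. Log-linear OLS is exact in the noiseless case and
  deterministic; nonlinear refinement is out of scope. Non-positive
  in-window volumes raise an error suggesting window truncation.
* zero-order fit: OLS of V on t, c0 = intercept, k = -slope,
  t_1/2 = c0/(2k). The **fitted intercept**, not the observed peak,
  enters the half-life, keeping the fit internally consistent.

## Synthetic phantoms

The signal phantom generates, per slice,

    a_i(t) = A0 (1 - d w(t - tau_i)) (1 + b sin(2 pi f_b t)) + eps

* `w` is a raised-cosine pulse train `((1 + cos 2 pi f t)/2)^m` with
  sharpness m = 3 by default: nonnegative, unit peak, pulsatile. The
  true shape of antral area waveforms is not established; this is an
  explicit stand-in chosen so the occlusion depth `d` maps exactly to
  the peak relative area reduction and the fundamental remains the
  strongest spectral line.
* `tau_i = i x (thickness + gap) / wave_speed`: adjacent slice centers
  are one thickness-plus-gap apart, so farther slices contract later —
  the phase-ordering invariant.
* breathing is multiplicative at f_b (default 0.25 Hz, amplitude 0.05
  of baseline area), noise is white Gaussian per frame (area phantom) or
  per voxel (image phantom); one seeded generator per call, no global
  state.

Defaults emulate a healthy postprandial recording: 3 cpm, 1.7 mm/s,
occlusion depth 0.5, 20 mm relaxed lumen, 180 s at 6.24 fps (the study
protocol also used 90 s records; both lengths are handled identically
with coarser resolution at 90 s).

The image phantom rasterizes each area sample as a centered bright
ellipse (aspect ratio 1.6, voxel-center rule) on a dark background, so
threshold segmentation closes the loop exactly in the noiseless case and
within the pixelization bound 2 x perimeter x pixel / area otherwise.
The static phantom rasterizes a sphere of the requested volume; with
~1 mm voxels the voxel-count volume is within a fraction of a percent of
analytic. Segmentation is a relative-intensity threshold (0.5 of the
per-frame maximum) with component-size filtering — a deterministic
intensity-based delineation for bright-lumen images; learned
segmentation and human-in-the-loop editing are out of scope, and real
masks can be injected mid-pipeline instead.

What the phantoms do **not** emulate: MR physics (k-space sampling,
coils, fat saturation), through-plane motion, lumen shape change beyond
area scaling, gastric wall signal, and correlated segmentation errors.
Passing tests therefore demonstrate correctness of the quantification
given faithful area signals, not robustness to every clinical artifact.

## Numerical choices and degenerate inputs

* Spectrum normalization: amplitude a_k = 2|X_k|/N (Nyquist and DC not
  doubled), so a grid sinusoid of amplitude A reads A at its bin and
  Parseval holds as var = sum a_k^2 / 2 (+ Nyquist term).
* All-constant frames segment to empty masks (not an error); all-zero
  area series raise a degenerate-reference error for occlusion.
* A band too narrow for the spectral resolution raises an error naming
  both quantities.
* Protocol helper: elemental Mn2+ dose uses conventional atomic masses
  (Mn 54.938, C 12.011, H 1.008, O 15.999) for
  Mn(C6H11O7)2 * n H2O.
* Problem sizes in the test and acceptance suites: 180 s signal phantoms
  (1123 frames) for frequency/occlusion/speed properties; 10-60 s
  renders on 64-96 pixel grids for image-closure and pipeline runs;
  200-seed Monte-Carlo for the emptying-rate bias; these sizes keep the
  suites fast while leaving every estimate's error far from its
  tolerance.

## Known limitations

* The apparent and cross-correlation speeds share the outer-edge-span
  distance convention and its systematic ~11-20% overestimate of the
  true phase speed; treat absolute speeds accordingly, trends are
  unaffected.
* Frequency is a grid point; a 90 s record cannot distinguish 2.8 from
  3.0 cpm.
* The occlusion reference assumes the record contains relaxed frames;
  continuous tonic contraction would bias occlusion downward.
* First-order fits weight late (small-volume) points more after the log
  transform; with volume-proportional noise this is optimal, with
  additive noise it mildly inflates variance (bias stays well under a
  percent at the tested noise level).
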