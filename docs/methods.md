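# Methods

## Imaging model

A near-focused camera (focal plane between the measured surface and the
lens) converts a surface tilt α into a translation of the imaged laser
speckle pattern.  We parameterize the conversion by a single magnification
`K` (metres of speckle shift per unit tan α), derived from the optical
distances as `K = L1·L2/F` with defaults L1 = 0.8 m, L2 = 0.4 m,
F = 0.05 m.  Only the ratio `K / pixel_pitch` (pixels per unit tan α)
enters the pipeline; `K` is a configuration key so any alternative grouping
of the optical constants is a one-line change, shared consistently by the
simulator and the registration stage.  The pixel pitch defaults to 5.86 µm,
the pitch of the 2.35 MP CMOS sensor class the geometry models.  At these
defaults one pixel of speckle shift corresponds to tan α ≈ 9.2·10⁻⁷.

Axial and transversal surface motion leave the speckle distribution
unchanged in this regime; tilt is the signal.  The pipeline therefore treats
the video as a rigidly translating pattern and estimates per-frame-pair
displacement.

## Registration

`register_pair` estimates the translation mapping one frame onto the next
with upsampled cross-correlation: the coarse peak of the FFT
cross-correlation (exact for integer circular shifts), refined by a
localized upsampled DFT in a 1.5×1.5 px neighbourhood.  The default
up-sampling factor is 100, i.e. 0.01 px resolution.  The implementation is
backed by `skimage.registration.phase_cross_correlation` with
`normalization=None` (plain cross-correlation, not phase correlation).
Convention: `(dx, dy)` are (column, row) shifts, positive when the pattern
moves toward increasing index, and describe the motion from the reference
frame to the moving frame.  Frames are registered pairwise
(frame k vs k+1); element k of the trace carries the time of frame k.
No window is applied by default — simulated frames are periodic; a Hann
window can be worthwhile on real video edges but changes nothing on the
synthetic data, so it is left to downstream users.

The two-axis trace is reduced to the orientation-independent series **Dr**
by projecting each raw (dx, dy) vector onto the first principal axis of the
centered scatter.  The global sign is fixed by requiring non-negative
covariance with dx (falling back to dy when dx is degenerate).  The
projection was chosen over the magnitude √(dx²+dy²) deliberately: the
magnitude rectifies the waveform and destroys polarity, which the beat
detector and ensemble averaging rely on.  This is the main interpretation
risk of the reduction step, and the rotation-invariance property (Dr
unchanged up to one global sign under any common rotation of the shift
vectors) is enforced by test.

## Beat detection

**SV.** The *principal signal* is computed as: optional band-pass of Dr to
the 10–40 Hz cardiac-vibration band (default on — real displacement traces
are respiration-dominated), Hilbert-transform envelope, band-pass to
0.5–3 Hz.  All filters are 4th-order Butterworth applied forward–backward
(zero phase), so detected peak times are not biased by group delay.  Peaks
are strict 3-point local maxima accepted by an adaptive threshold evaluated
over 5 s non-overlapping windows: the threshold is 0.25 of a running
signal-peak level, and every accepted peak updates the level as
`0.125·amplitude + 0.875·level`.  The level is initialized from the first
window's maximum, which makes detection exactly invariant under positive
rescaling of the input.  Peaks closer than a 0.33 s refractory interval
(the period of the 3 Hz band edge) keep the larger amplitude.  All
constants are configuration keys.

**ECG.** An Engelse–Zeelenberg detector: differentiate as
`y[n] = x[n] − x[n−4]`, smooth with a [1,4,6,4,1]/16 FIR kernel, and scan
for positive crossings of an adaptive threshold that are followed by a
negative crossing within 160 ms (the biphasic signature of a QRS).  Each
qualifying crossing opens a search window in which the R peak is located as
the maximum of the raw signal.  The threshold is 0.48 of a running level
updated from each detection's differentiated amplitude
(0.125/0.875 exponential update), halved whenever 3 s pass without a beat
so the detector cannot lock out; detections within 200 ms of the previous
beat are suppressed.  Records not sampled near 300 Hz are polyphase
resampled for detection, but reported peak indices always refer to the
original record.  The detector assumes a dominant positive R wave.

## Matching and IBI selection

For each detected R peak an acceptance interval is built from 0.4 of the
distance to the neighbouring R peaks (0.5 would be the half-distance; 0.4
is deliberately narrower).  The first peak's interval starts at 0; the last
ends at the peak itself.  Bounds are inclusive on both ends (the pseudocode
reading "in interval"; boundary hits are measure-zero on real data but must
be fixed for testing).  The SV peak nearest to the R peak inside the
interval is paired; an equidistant tie keeps the earlier peak
(deterministic).  If no SV peak lies inside, the R peak is discarded.  The
printed procedure also discards an R peak whose nearest candidate was
already claimed, with no fallback to the second-nearest; we keep that
literal rule even though a fallback would raise recall.  Note that for
strictly increasing inputs consecutive intervals are disjoint
(m_j + 0.4δ < m_{j+1} − 0.4δ), so the already-claimed branch is actually
unreachable — it is retained as written for fidelity and as a defensive
guard.

Consecutive differences of the matched lists form paired IBIs; any pair
whose ECG interval strictly spans an originally detected but discarded R
peak is a *false interval* and is removed from both modalities — such an
interval merges two true beats and would flatter the agreement statistics.

## Agreement and group statistics

IHR = 60/IBI in bpm.  Bland–Altman differences are oriented **ECG − SV**,
so an SV overestimate produces a negative bias (matching the sign language
used when SV slightly overestimates IHR); bias is the mean difference, SD
the sample standard deviation (n−1), and the limits of agreement
bias ± 1.96·SD (the standard 95 % multiplier).  Group comparisons operate
on per-measurement summaries (mean absolute IHR difference): Shapiro–Wilk
per group as the normality gate at p = 0.05, Kruskal–Wallis across groups
(no normality assumption), and Welch's t with Welch–Satterthwaite degrees
of freedom for two groups of unequal size.  The grouping itself is supplied
by the caller, so the tests apply equally to pooled or per-participant
differences.

Ensemble averaging windows the displacement waveform by one median IBI
centered on each beat, drops windows crossing the record bounds, averages,
and min–max normalizes both axes (arbitrary units).

## Synthetic recordings

The generator emulates one 5 min measurement (300 frames/s video, 300 Hz
single-lead ECG) in four steps, all driven by one seed through independent
spawned generators (so changing, e.g., the ECG noise level does not perturb
the video):

1. **RR intervals** — `RR_k = (60/HR)·(1 + a·sin(2π f_r t_k)) + ε_k` with
   respiratory sinus arrhythmia depth `a`, respiratory rate `f_r` and
   Gaussian beat-to-beat variability ε of scale SDNN, clipped to ≥ 0.3 s.
2. **Tilt waveform** — a respiratory sinusoid plus one biphasic cardiac
   pulse (derivative-of-Gaussian, fixed 120 ms width) per beat, scaled by a
   damping factor in (0, 1] that stands in for textile attenuation.  The
   pulse anchors are exported as ground-truth SV beat times.  A biphasic
   template was chosen over a multi-peak ballistocardiographic complex: the
   detector needs one dominant deflection per beat and no published
   waveform model constrains the rest.
3. **Video** — a fully developed speckle frame (complex circular-Gaussian
   field, Gaussian low-pass to correlation length `grain_px`, intensity =
   squared magnitude normalized to mean 1 — exponential intensity
   statistics, contrast 1, hold exactly for any linear filter) is shifted
   by `K·tan α/pixel_pitch` pixels along a fixed axis with exact spectral
   phase ramps (periodic boundary: no new content enters the frame, so
   registration accuracy can be validated to its resolution limit), plus
   additive Gaussian sensor noise.  Frames are stored float32.
4. **ECG** — a fixed PQRST-like template (narrow dominant R) at each
   cumulative RR time on a flat baseline with small Gaussian noise; exact R
   sample indices are exported.

Default conditions: 70 bpm, SDNN 30 ms, RSA depth 0.05 at 0.25 Hz — an
ordinary resting adult; cardiac tilt amplitude 2·10⁻⁶ rad and respiratory
tilt 1·10⁻⁵ rad, giving ≈ 2.2 px cardiac and ≈ 11 px respiratory speckle
excursions at the default geometry — cardiac deflections two orders of
magnitude above the 0.01 px registration resolution, with the slow
respiratory baseline an order of magnitude larger, as on a breathing chest;
sensor noise SD 0.02 of the mean intensity.  Test and validation runs use
64×64 frames and 8–60 s durations; the registration accuracy sweep uses a
256×256 frame with 4 px grain.  These sizes keep a full run to tens of
seconds while leaving dozens of beats for the statistics.

**What the simulator does not model** — and hence what passing tests do not
show about real data: speckle decorrelation (boiling), non-rigid and
multi-spot motion, gross body-movement artifacts, optical blur from
textiles (attenuation is a scalar), baseline wander and electrode artifacts
in the ECG, and arrhythmic rhythms.  End-to-end numbers on synthetic
recordings are upper bounds on clean-signal performance, not predictions of
clinical agreement.

## Numerical conventions and degenerate inputs

- Peak times are integer sample indices internally and seconds at module
  boundaries; matching operates on exact values in either unit.
- Readers reject: frame stacks with fewer than 2 frames or unequal shapes;
  signals with non-monotonic time or more than 1 % deviation from uniform
  sampling (the rate is the reciprocal median step).
- Timestamp alignment crops both records to the overlapping window,
  resolved to the nearest sample of each; it is idempotent.  Sub-sample
  synchronization offsets are not modelled.
- Constant frames make the correlation peak undefined and raise; a
  zero-variance displacement scatter yields Dr = 0 with a warning; a flat
  ECG yields an empty beat series with a warning.
- Recall/precision with zero detected peaks, Bland–Altman with fewer than
  two pairs, and Shapiro–Wilk with fewer than three values per group are
  errors rather than NaNs.
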