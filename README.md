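# svheart — speckle-vibrometry instantaneous heart rate

`svheart` implements a contact-free cardiac monitoring pipeline based on
**speckle vibrometry (SV)**: a laser spot on the chest (or on the bedding
covering it) is imaged by a *near-focused* camera, whose focal plane lies
between the surface and the lens.  In that configuration a tiny tilt α of
the illuminated surface translates the imaged speckle pattern by

```
d = K · tan α,          K = L1·L2 / F
```

metres on the sensor (L1: surface→focal-plane distance, L2:
focal-plane→lens distance, F: focal length; defaults 0.8 m, 0.4 m, 0.05 m).
Heartbeats tilt the body surface by microradians, which the geometry
magnifies into speckle shifts of order a pixel — large enough to track with
sub-pixel image registration and extract **instantaneous heart rate (IHR)**
beat by beat, through textile layers, without skin contact.  The intended
users are researchers in contact-free vital-sign monitoring and sleep
physiology who need a reference implementation of the full chain plus a
simulator to validate it.

## Pipeline

1. **Registration** (`svheart.registration`) — consecutive video frames are
   registered by upsampled cross-correlation (coarse FFT correlation peak
   refined by a localized upsampled DFT, up-sampling 100 → 0.01 px
   resolution), giving per-frame-pair shifts (dx, dy).  These are reduced to
   one orientation-independent series **Dr** by projection onto the first
   principal axis of the (dx, dy) scatter.
2. **Beat detection** (`svheart.detect`) — the *principal signal* is the
   0.5–3 Hz band-passed Hilbert envelope of Dr (optionally pre-filtered to
   the 10–40 Hz cardiac-vibration band); peaks are accepted by adaptive
   thresholding over 5 s non-overlapping windows.  ECG R peaks come from an
   Engelse–Zeelenberg detector with an adaptive threshold and 200 ms
   refractory period.
3. **Matching** (`svheart.match`) — each R peak m_j gets an acceptance
   interval spanning 0.4 of the distance to its neighbours
   `[m_j − 0.4(m_j − m_{j−1}), m_j + 0.4(m_{j+1} − m_j)]`; the nearest SV
   peak inside it is paired one-to-one, otherwise the R peak is discarded.
   recall = |Mvalid|/N_ECG and precision = |Nvalid|/N_SV quantify detection.
   Inter-beat intervals (IBIs) spanning a discarded R peak ("false
   intervals") are excluded from both modalities.
4. **Evaluation** (`svheart.evaluate`) — IHR = 60/IBI (bpm); agreement is
   summarized Bland–Altman style (bias = mean(ECG − SV), SD, limits of
   agreement bias ± 1.96·SD), with Shapiro–Wilk / Kruskal–Wallis / Welch
   tests for group comparisons and ensemble averaging of the beat waveform.
5. **Simulation** (`svheart.simulate`) — since clinical recordings are not
   redistributable, a physics-based generator produces paired inputs: a
   fully developed speckle pattern (exponential intensity, contrast 1)
   translating under a cardiac + respiratory tilt waveform with known beat
   times, and a matching ECG with exact R-peak indices.

## Worked example

Simulate a 30 s recording (300 frames/s video of a 64×64 speckle pattern,
70 bpm with 30 ms beat-to-beat variability, 300 Hz ECG) and run every stage:

```
$ cat example.toml
[simulation]
duration_s = 30.0
seed = 11

$ svheart run-all --config example.toml --out-dir demo
[svheart] simulating 30 s recording (seed 11)
[svheart] running pipeline on 9000 frames
[svheart] recall 1.000 precision 1.000; results -> demo/results.json

$ cat demo/results.json
{
  "recall": 1.0,
  "precision": 1.0,
  "n_ibi": 34,
  "bias": 0.0037371916208996936,
  "sd": 0.22408898149342343,
  "loa_low": -0.4354772121062102,
  "loa_high": 0.4429515953480096,
  "n": 34
}
```

Every simulated beat was detected in the video and paired with its ECG R
peak (recall and precision 1.0).  The 34 surviving IBI pairs agree to a mean
bias of 0.004 bpm with limits of agreement of ±0.44 bpm — the agreement
achievable when the only disturbances are sensor noise and the detector's
own timing jitter.  The stages can also be run separately
(`simulate`, `extract`, `detect-sv`, `detect-ecg`, `match`, `evaluate`);
intermediate artifacts are plain CSV/NPY/TIFF.

Library use mirrors the CLI:

```python
from svheart import SimConfig, simulate_recording, run_pipeline

rec = simulate_recording(SimConfig(duration_s=30.0, seed=11))
res = run_pipeline(rec.video, rec.ecg)
print(res["recall"], res["bland_altman"].bias)
```

## Limitations

The simulator drives a rigid translation of an ideal speckle pattern;
real recordings add decorrelation, body movement artifacts, and
textile-dependent attenuation that are only coarsely modelled (a scalar
damping factor and additive noise).  See `docs/methods.md` for the model
details, parameter choices and numerical conventions.
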