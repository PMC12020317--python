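# emgstim

Analysis toolkit for **bidirectional somatosensory neuroprostheses** — implanted
systems that both record intramuscular EMG for myoelectric prosthesis control
and stimulate peripheral-nerve cuff electrodes to evoke touch sensations.
It is written for neural-engineering groups who need the full bench pipeline
around such a system: signal-quality audits of chronically implanted EMG
channels, spectral detection of stimulation artifact, psychophysical threshold
and electrode-health analytics, a proportional multi-DOF neural-network
controller, and a virtual posture-matching task to evaluate it — all testable
against ground-truthed synthetic data, since human-subject recordings from such
implants are rarely shareable.

## What it computes

**EMG features.** Raw 1 kHz EMG is bandpass filtered (15–350 Hz, zero-phase
Butterworth) and summarized per 100 ms window by waveform length and mean
absolute value,

&nbsp;&nbsp;WFL = Σᵢ |xᵢ₊₁ − xᵢ| / N,&nbsp;&nbsp;&nbsp;MAV = Σᵢ |xᵢ| / N,

both in μV. A channel is *noise-only* when its WFL series has variance < 0.02,
at most three WFL peaks above 3× the rest-period baseline, and ≥ 90 % of MAV
windows below 17 μV. Crosstalk between channels is the zero-lag Pearson
correlation of their WFL series.

**Stimulation artifact.** From 500 ms STFT spectrograms of paired
stimulation-on/off recordings, φ_f is the ratio of excess power at the
stimulation frequency (and each harmonic ≤ 500 Hz) over its neighbor bands
(±5–10 Hz), and φ_overall is the broadband median-power ratio excluding ±5 Hz
around every harmonic. With a threshold of 15 on both ratios, channels are
assigned one of five categories: unaffected, increased overall power,
intermittent artifact, consistent artifact, or unresponsive.

**Stimulation dose and safety.** Charge per phase Q = I·t (mA × μs = nC); the
safe ceiling follows the Shannon criterion log₁₀(Q/A) = k − log₁₀(Q), giving
Q = 10^((k + log₁₀A)/2) μC. Perceptual thresholds are found by a 0.01 mA
amplitude ramp at 250 μs followed by a binary search on pulse width to 10 μs
resolution. Tissue resistance is V/I from sub-threshold probe pulses averaged
over eight trials, with contacts excluded above 15 kΩ. Percept-location
stability is the mean pairwise Jaccard similarity of drawing rasters.

**Control.** An 18-posture protocol (all single and paired combinations of
hand open–close, wrist flex–extend, pronate–supinate) yields effort vectors
e(t) = d · meanWFL(t); a 14-hidden-node tanh network maps the WFL vector to
simultaneous 3-DOF velocities, decoded through per-direction deadband and
gain. The virtual task requires holding all joint angles within 15 % of a
target for 1 s inside a 30 s limit, with stimulation feedback stepping
0 → 50 → 100 Hz as errors shrink below 22.5 % and 15 %.

## Worked example

```python
import numpy as np
from emgstim import (SimConfig, generate_emg, compute_wfl, classify_noise_only,
                     ShannonParams, shannon_limit, make_observer, measure_threshold)

# one strongly active channel (50 uV RMS) and one silent channel
act = np.array([[50.0, 50.0, 50.0], [0.0, 0.0, 0.0]])
rec, truth = generate_emg(SimConfig(activation_matrix=act,
                                    posture_sequence=[(0, 2.0), (1, 2.0), (2, 2.0)],
                                    baseline_noise=1.0, seed=7))
feats = compute_wfl(rec, window_ms=100.0, step_ms=100.0)
for c in classify_noise_only(feats):
    print(c.channel, c.status, round(c.wfl_variance, 4))

print(round(shannon_limit(ShannonParams(k=1.1, contact_area_cm2=0.005)), 1))
m = measure_threshold(make_observer(100.0))
print(m.amplitude_ma, m.pulse_width_us, round(m.threshold_charge_nc, 1))
```

prints

```
0 responsive 415.3258
1 noise_only 0.0082
250.9
0.4000000000000002 250.0 100.0
```

Channel 0 modulates with posture (WFL variance far above the 0.02 noise
criterion) while channel 1 is flagged noise-only; the Shannon ceiling for a
0.5 mm² contact at k = 1.1 is ≈ 250 nC; and the two-phase search recovers a
100 nC latent detection threshold exactly (0.4 mA at 250 μs).

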