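# Methods

This note documents the models, parameter choices, and numerical decisions
behind `emgstim`, and what the synthetic-data experiments do and do not show
about real implanted recordings.

## Synthetic EMG model

Interference-pattern intramuscular EMG is modeled as band-limited Gaussian
noise amplitude-modulated by a posture envelope. Each channel's carrier is
white Gaussian noise passed through a zero-phase 4th-order Butterworth
bandpass (default 15–350 Hz) and renormalized to unit RMS; it is scaled per
sample by `activation_matrix[channel, posture]` (target μV RMS per held
posture) times a 0–1 envelope with 200 ms raised-cosine rise/fall ramps, and
summed with an independent baseline-noise floor generated the same way. The
RMS of a channel during a held posture therefore approaches
√(activation² + noise²). Two-second rest segments (label −1) are interleaved
between postures so the channel-quality classifier always has a labelled
baseline.

This reproduces the *statistical* character downstream stages assume —
band-limited stochastic amplitude modulation, a stationary noise floor,
labelled rest — but not motor-unit structure, volume conduction, or
recruitment nonlinearity. Passing tests demonstrate that the analysis
recovers known generating parameters, not that it would behave identically
on physiological EMG.

Default amplitudes (50 μV activation over 1–2 μV baseline noise in the
experiments) are plausible for intramuscular bipolar recordings but are not
fitted to any participant; responsive/noise-only regimes are deliberately
well separated (dead channels at 0.5 μV noise sit ~10× below the noise-only
thresholds, live ones ~25× above).

Stimulation artifact is injected either as a sum of phase-randomized
sinusoids at the stimulation frequency and its harmonics with specified
per-harmonic amplitudes — chosen over a pulse train because it controls
per-harmonic spectral power directly — or, for the increased-overall-power
mode, as a √gain amplitude scaling. In intermittent mode the trial-list
helper affects exactly `round(fraction × n_trials)` trials so the stated
fraction is realized rather than merely expected.

## Feature extraction

WFL divides the summed absolute first differences by the number of samples
in the window (not the window duration in seconds), keeping μV units
consistent with the 17 μV MAV ceiling and 0.02 variance threshold used by
the classifier. Windows are half-open `[t, t+window)`; trailing partial
windows are dropped to match streaming semantics (a 1 s recording at
100 ms/50 ms yields 19 windows). The window label is the posture label at
the window's first sample. The bandpass is applied forward–backward, which
preserves alignment between samples and labels at the cost of being
non-causal; the real-time device necessarily filters causally.

Raw-signal quantization rounds to the nearest LSB and saturates at the
signed code range (±127/−128 LSB at 8 bits). Streamed features are quantized
to a 10-bit unsigned range whose full scale defaults to 0–200 μV
(configurable; the hardware's actual feature scaling is not public).

## Channel quality and crosstalk

The noise-only rule requires all three criteria: WFL-series variance
< 0.02, ≤ 3 WFL peaks above 3× baseline, and ≥ 90 % of MAV windows < 17 μV.
The 0.02 threshold is applied to the variance of the μV-valued WFL series
(units μV²; the threshold's printed unit is ambiguous and the μV² reading is
adopted). Baseline noise per channel is the median WFL over rest windows —
robust to stray movement bursts. A "peak" is a local maximum above 3×
baseline with nearby maxima (< 3 windows apart) merged, so one burst is not
counted twice.

Crosstalk is the zero-lag Pearson correlation of two channels' full-signal
WFL series; the feature domain (rather than raw samples) matches how
crosstalk magnitudes in the 0–0.4 range are conventionally reported for
myoelectric channel independence. Zero-variance channels get entries of 0
and a flag rather than NaN. Session trends regress the mean off-diagonal
value on weeks post-implant.

## Artifact ratios

Spectrograms use 500 ms Hann windows with 50 % overlap (the window length is
part of the protocol; taper and overlap are this package's choices), giving
2 Hz bins at 1 kHz. For φ_f at frequency f, excess power is the across-frame
median at the f bin minus the pooled median over frames and bins of
[f−10, f−5] ∪ [f+5, f+10] Hz — the generalization to any f of the printed
60–65/75–80 Hz neighbor bands at 70 Hz. φ_f is the quotient of stimulation
over no-stimulation excess, with the denominator floored at the
no-stimulation neighbor-band level so the ratio stays finite and
conservative when the no-stimulation excess is ≤ 0; a nonpositive
stimulation excess reports φ_f = 1 (no increase). φ_overall pools the median
over all frames and 10–500 Hz bins excluding ±5 Hz around every harmonic.

Category precedence (unresponsive → increased overall power → consistent →
intermittent → unaffected) applies the threshold of 15 to φ_overall in any
trial and to the per-trial maximum of φ_f across harmonics.

## Psychophysics and electrode health

The detection observer is logistic in charge with midpoint at the latent
threshold; infinite slope gives a deterministic step. The threshold search
ramps amplitude from 0 in 0.01 mA steps at 250 μs (the ramp floor is a
package choice; only the step size is prescribed), then binary-searches
cathodic width on [10, 250] μs until the bracket is ≤ 10 μs, returning the
smallest detected width. For a deterministic observer the recovered charge
is ≥ the latent charge and overshoots by at most
`amplitude_step × start_width + amplitude × width_resolution`. Searches that
reach the 250 nC Shannon ceiling are returned censored, and censored
measurements are excluded from trend regressions (conservative; their
handling is otherwise unspecified).

Tissue resistance is V/I per trial (V in volts, I = 0.2 mA → kΩ), averaged
over eight trials; any single trial above 15 kΩ flags the contact as a
suspected loose connection and excludes it.

Percept rasters are 512 × 512 binary images; the wrist is a stored row
index, and "on the hand" means ≥ 1 pixel distal to that row — a pixel rule
rather than a centroid rule so split percepts still count.
Proprioception-only reports are excluded from location analyses. The
descriptor → category map (tactile/proprioceptive/pain) ships as editable
JSON data, not code; unknown terms default to tactile with a warning.

## Statistics

Linear trends use OLS with the model F-test against an intercept-only fit
(identical to the two-sided slope t-test, property-tested). A constant
series returns p = 1 (F = 0/0 treated as no evidence of trend). Proportion
trends use binomial logistic regression with a 1-df likelihood-ratio
chi-squared test; statsmodels flags any deviance-zero fit as separation, so
the penalized (small-ridge) fallback is taken only when the slope has
actually diverged. Group comparisons dispatch Kruskal–Wallis with an
all-pairs studentized-range (Nemenyi-style) post hoc for ≥ 3 groups — one of
several defensible readings of a rank-based "Tukey adjustment", implemented
behind a single function so it can be swapped — Wilcoxon rank-sum for two
unpaired groups, and Wilcoxon signed-rank for paired samples, with one-sided
alternatives available. AM-ULA summary scores are 10 × the mean over tasks
of per-task repetition means, with malfunction trials entered as NaN and
condition differences judged against a minimum detectable change of 4.4.

## Controller

Repetition selection correlates each repetition's per-channel mean-WFL
pattern with the across-repetition median pattern (Pearson); the three least
similar are excluded, the four most similar of the remainder train, the
last three validate, with ties broken by repetition index. The network is a
single hidden layer of 14 tanh units with linear outputs, trained by Adam on
per-channel-standardized features and dispersion-scaled effort targets in
rounds of 20 iterations, keeping the weights with the best validation RMSE
and stopping after 10 evaluations without improvement. Decoding subtracts
the direction-specific deadband threshold from |r| before applying the
direction's gain — subtract-then-scale keeps velocity continuous at the
deadband edge. Gains and thresholds are (3 DOF × 2 direction) user-tunable
parameters, exactly as a participant would tune them.

## Virtual task

Angles are normalized to [−1, 1] per DOF; "within 15 %" means absolute error
≤ 0.15 range units per DOF, making the criterion dimensionless. Velocities
integrate at the 50 ms feature update rate with clipping (not reflection) at
range limits. Success requires continuous in-band dwell of 1.0 s; the
time-to-target is the dwell's end. Feedback frequency is a three-level step
function (0/50/100 Hz) of the error bands, not a proportional ramp. Random
targets are uniform in [−0.8, 0.8]³ so every target is reachable with
margin for the success band.

## Experiment sizes

The packaged recovery experiments use 1,000 simulated observers, 200
artifact channels (each a 14 s single-channel recording plus three
stimulation trials), 2,000 null replicates per statistical test, and one
full 18-posture × 10-repetition controller dataset with 40 feature frames
per repetition — sizes chosen to give stable rates while keeping a full run
in well under a minute per experiment on one core.

## Known limitations

Synthetic EMG carries no motor-unit or recruitment structure, so classifier
and controller results bound behavior only under the stated generative
assumptions. The real-time device quantizes and filters causally; this
package's zero-phase filtering is a post-hoc idealization. The psychophysics
covers detection thresholds only, not intensity scaling. Human-subject
medians from chronic implant studies (e.g., multi-second times-to-target,
~38 % path efficiency) arise from human motor behavior and are not
reproduced by the ideal scripted user, which completes the task near the
kinematic optimum.
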