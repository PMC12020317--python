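"""Ground-truthed synthetic inputs for every downstream analysis stage.

No participant data is distributed with this package, so each analysis is
exercised on synthetic signals whose generating parameters are known exactly:

* interference-pattern intramuscular EMG — band-limited (15-350 Hz) Gaussian
  noise amplitude-modulated by a posture envelope, with labelled rest
  segments and optional stimulation contamination;
* binary "percept drawing" rasters on a limb template with controllable
  session-to-session drift;
* a psychophysical detection observer with a latent threshold charge;
* tissue-resistance session series with linear drift and trial noise.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import expit

from .recording import REST_LABEL, EmgRecording

REST_DURATION_S = 2.0
RAMP_S = 0.2


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass
class SimConfig:
    """Parameters of one synthetic EMG recording session.

    ``activation_matrix[c, p]`` is the target RMS amplitude (uV) of channel
    ``c`` while posture ``p`` is held; rest segments of 2 s are interleaved
    between postures so the channel-quality classifier has a labelled
    baseline. ``baseline_noise`` (uV RMS) is present at all times.
    """

    activation_matrix: np.ndarray
    posture_sequence: list[tuple[int, float]]
    n_channels: int | None = None
    sampling_rate: float = 1000.0
    baseline_noise: float = 2.0
    band: tuple[float, float] = (15.0, 350.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.activation_matrix = np.atleast_2d(np.asarray(self.activation_matrix, dtype=float))
        if self.n_channels is None:
            self.n_channels = self.activation_matrix.shape[0]
        if self.activation_matrix.shape[0] != self.n_channels:
            raise ValueError("activation_matrix rows must equal n_channels")
        if (self.activation_matrix < 0).any():
            raise ValueError("activation_matrix entries must be nonnegative")
        if self.sampling_rate <= 2 * self.band[1]:
            raise ValueError("sampling_rate must exceed twice the band's upper edge")
        if any(d <= 0 for _, d in self.posture_sequence):
            raise ValueError("all posture durations must be positive")
        if self.baseline_noise < 0:
            raise ValueError("baseline_noise must be nonnegative")


@dataclass
class ArtifactSpec:
    """Stimulation contamination model.

    ``consistent`` and ``intermittent`` modes add sinusoids at ``f_stim``
    and its harmonics with the given per-harmonic amplitudes (uV);
    ``overall_power`` multiplies the broadband signal power by
    ``broadband_gain`` instead. ``intermittent_fraction`` is the proportion
    of recording trials affected in intermittent mode.
    """

    f_stim: float = 70.0
    harmonic_amplitudes: tuple[float, ...] = (20.0,)
    mode: str = "consistent"
    intermittent_fraction: float = 0.5
    broadband_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.f_stim <= 0:
            raise ValueError("f_stim must be positive")
        if self.broadband_gain < 1:
            raise ValueError("broadband_gain must be >= 1")
        if not 0 <= self.intermittent_fraction <= 1:
            raise ValueError("intermittent_fraction must lie in [0, 1]")
        if self.mode not in {"consistent", "intermittent", "overall_power"}:
            raise ValueError(f"unknown artifact mode {self.mode!r}")


@dataclass
class PerceptDrift:
    """Session-to-session instability of a percept drawing."""

    translation_px: tuple[float, float] = (0.0, 0.0)
    area_jitter_frac: float = 0.0


@dataclass
class GroundTruth:
    """Generating parameters recorded alongside synthetic outputs."""

    channel_roles: list[str] = field(default_factory=list)
    latent_threshold_charge: dict[int, float] = field(default_factory=dict)
    true_resistance: dict[int, np.ndarray] = field(default_factory=dict)
    percept_drift: dict[int, PerceptDrift] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# EMG generation


def _band_noise(rng: np.random.Generator, n: int, shape, fs: float, band) -> np.ndarray:
    """Band-limited Gaussian noise normalized to unit RMS per channel."""
    white = rng.standard_normal((*shape, n))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _posture_envelope(config: SimConfig):
    """Per-sample posture labels and a 0..1 activation envelope with ramps."""
    fs = config.sampling_rate
    rest_n = int(round(REST_DURATION_S * fs))
    ramp_n = int(round(RAMP_S * fs))
    labels, env = [], []
    for posture_id, dur in config.posture_sequence:
        labels.append(np.full(rest_n, REST_LABEL))
        env.append(np.zeros(rest_n))
        n = int(round(dur * fs))
        e = np.ones(n)
        k = min(ramp_n, n // 2)
        if k > 0:
            ramp = 0.5 * (1 - np.cos(np.linspace(0, math.pi, k)))
            e[:k] = ramp
            e[-k:] = ramp[::-1]
        labels.append(np.full(n, posture_id))
        env.append(e)
    labels.append(np.full(rest_n, REST_LABEL))
    env.append(np.zeros(rest_n))
    return np.concatenate(labels).astype(int), np.concatenate(env)


def generate_emg(config: SimConfig) -> tuple[EmgRecording, GroundTruth]:
    """Synthesize a labelled multichannel EMG recording.

    Each channel is unit-RMS band-limited noise scaled per sample by the
    posture envelope times ``activation_matrix[channel, posture]``, plus an
    independent baseline-noise floor, so the RMS of channel ``c`` during a
    held posture ``p`` approaches ``sqrt(activation[c, p]**2 + noise**2)``.
    """
    rng = np.random.default_rng(config.seed)
    labels, env = _posture_envelope(config)
    n = len(labels)
    fs = config.sampling_rate
    n_ch = config.n_channels
    amp = np.zeros((n_ch, n))
    active = labels >= 0
    if active.any():
        amp[:, active] = config.activation_matrix[:, labels[active]] * env[active]

    if np.any(amp > 0):
        carrier = _band_noise(rng, n, (n_ch,), fs, config.band)
    else:
        carrier = np.zeros((n_ch, n))
    samples = carrier * amp
    if config.baseline_noise > 0:
        samples = samples + config.baseline_noise * _band_noise(
            rng, n, (n_ch,), fs, config.band
        )

    roles = [
        "responsive" if config.activation_matrix[c].max() > 0 else "noise_only"
        for c in range(n_ch)
    ]
    rec = EmgRecording(samples=samples, sampling_rate=fs, posture_labels=labels)
    return rec, GroundTruth(channel_roles=roles)


def inject_artifact(
    recording: EmgRecording,
    spec: ArtifactSpec,
    affected_channels,
    seed: int = 0,
) -> EmgRecording:
    """Contaminate selected channels with a stimulation artifact.

    ``consistent`` mode adds phase-randomized sinusoids at ``f_stim`` and its
    harmonics; ``intermittent`` mode does the same with probability
    ``intermittent_fraction`` for this recording (trial); ``overall_power``
    scales the affected channels' amplitude by ``sqrt(broadband_gain)``.
    The stimulation flag is set on the returned recording either way.
    """
    fs = recording.sampling_rate
    n_harm = len(spec.harmonic_amplitudes)
    top = spec.f_stim * n_harm
    if spec.mode != "overall_power" and top >= fs / 2:
        raise ValueError(f"harmonic {top} Hz is at or above Nyquist {fs / 2} Hz")
    rng = np.random.default_rng(seed)
    affected = np.asarray(sorted(affected_channels), dtype=int)
    out = recording.samples.copy()

    apply_tone = spec.mode == "consistent" or (
        spec.mode == "intermittent" and rng.random() < spec.intermittent_fraction
    )
    if spec.mode == "overall_power":
        out[affected] *= math.sqrt(spec.broadband_gain)
    elif apply_tone:
        t = np.arange(recording.n_samples) / fs
        tone = np.zeros_like(t)
        for k, a in enumerate(spec.harmonic_amplitudes, start=1):
            tone += a * np.sin(2 * math.pi * k * spec.f_stim * t + rng.uniform(0, 2 * math.pi))
        out[affected] += tone
    rec = recording.with_samples(out)
    rec.stim_flag = np.ones(recording.n_samples, dtype=bool)
    return rec


def inject_artifact_trials(
    recordings: list[EmgRecording],
    spec: ArtifactSpec,
    affected_channels,
    seed: int = 0,
) -> tuple[list[EmgRecording], list[bool]]:
    """Apply an artifact spec across a list of recording trials.

    In ``intermittent`` mode, exactly ``round(intermittent_fraction *
    n_trials)`` trials (chosen at random) receive the tonal artifact, so the
    stated fraction is realized rather than merely expected. Other modes
    affect every trial. Returns the contaminated recordings and a
    per-trial flag of whether the artifact waveform was actually applied.
    """
    rng = np.random.default_rng(seed)
    n = len(recordings)
    if spec.mode == "intermittent":
        n_aff = int(round(spec.intermittent_fraction * n))
        chosen = set(rng.choice(n, size=n_aff, replace=False).tolist())
        tone_spec = ArtifactSpec(
            f_stim=spec.f_stim,
            harmonic_amplitudes=spec.harmonic_amplitudes,
            mode="consistent",
            broadband_gain=1.0,
        )
        out, flags = [], []
        for i, rec in enumerate(recordings):
            if i in chosen:
                out.append(inject_artifact(rec, tone_spec, affected_channels,
                                           seed=int(rng.integers(2**31))))
                flags.append(True)
            else:
                stamped = rec.with_samples(rec.samples)
                stamped.stim_flag = np.ones(rec.n_samples, dtype=bool)
                out.append(stamped)
                flags.append(False)
        return out, flags
    out = [
        inject_artifact(rec, spec, affected_channels, seed=int(rng.integers(2**31)))
        for rec in recordings
    ]
    applied = spec.mode == "consistent" or spec.broadband_gain > 1
    return out, [applied] * n


# ---------------------------------------------------------------------------
# percept drawings


@dataclass(frozen=True)
class LimbTemplate:
    """Raster geometry of the upper-limb drawing template.

    Rows below ``wrist_row`` (larger indices) are proximal; rows at or above
    it are the hand, distal to the wrist.
    """

    height: int = 512
    width: int = 512
    wrist_row: int = 256

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def distal_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[: self.wrist_row, :] = True
        return m


DEFAULT_DESCRIPTOR_LEXICON = {
    "vibration": 0.25,
    "pressure": 0.25,
    "tingle": 0.15,
    "tap": 0.1,
    "electrical": 0.1,
    "contraction": 0.08,
    "movement": 0.04,
    "sharp": 0.03,
}


def square_mask(
    template: LimbTemplate, center: tuple[int, int], side: int
) -> np.ndarray:
    """Axis-aligned square percept mask, clipped to the template."""
    r0 = center[0] - side // 2
    c0 = center[1] - side // 2
    m = np.zeros(template.shape, dtype=bool)
    rr = slice(max(r0, 0), min(r0 + side, template.height))
    cc = slice(max(c0, 0), min(c0 + side, template.width))
    m[rr, cc] = True
    return m


def generate_percept_series(
    n_sessions: int,
    drift: PerceptDrift,
    template: LimbTemplate,
    seed: int = 0,
    base_mask: np.ndarray | None = None,
    descriptor_probs: dict[str, float] | None = None,
    n_descriptors: int = 2,
) -> list[dict]:
    """One percept drawing per session with linear translation drift.

    Session ``s`` shifts the base mask by ``s * translation_px`` (rounded to
    whole pixels) and, with ``area_jitter_frac > 0``, randomly toggles that
    fraction of boundary-area pixels. Raises if any session's mask leaves the
    template entirely. Returns dicts with keys ``session``, ``mask``,
    ``descriptors``.
    """
    rng = np.random.default_rng(seed)
    if base_mask is None:
        base_mask = square_mask(template, (template.wrist_row // 2, template.width // 2), 64)
    probs = descriptor_probs or DEFAULT_DESCRIPTOR_LEXICON
    terms = list(probs)
    p = np.array([probs[t] for t in terms], dtype=float)
    p = p / p.sum()
    rows, cols = np.nonzero(base_mask)
    if rows.size == 0:
        raise ValueError("base mask is empty")

    reports = []
    for s in range(n_sessions):
        dr = int(round(s * drift.translation_px[0]))
        dc = int(round(s * drift.translation_px[1]))
        r, c = rows + dr, cols + dc
        keep = (r >= 0) & (r < template.height) & (c >= 0) & (c < template.width)
        if not keep.any():
            raise ValueError(f"session {s}: drift moved the percept off the template")
        mask = np.zeros(template.shape, dtype=bool)
        mask[r[keep], c[keep]] = True
        if drift.area_jitter_frac > 0:
            n_flip = int(round(drift.area_jitter_frac * keep.sum()))
            if n_flip:
                idx = np.nonzero(mask)
                sel = rng.choice(idx[0].size, size=min(n_flip, idx[0].size), replace=False)
                mask[idx[0][sel], idx[1][sel]] = False
        descriptors = list(rng.choice(terms, size=n_descriptors, replace=False, p=p))
        reports.append({"session": s, "mask": mask, "descriptors": descriptors})
    return reports


# ---------------------------------------------------------------------------
# detection observer and resistance series


class DetectionObserver:
    """Simulated participant reporting whether a stimulus was felt.

    Detection probability is a logistic function of charge per phase with
    midpoint at the latent threshold; an infinite slope gives a
    deterministic step (detected iff charge >= threshold).
    """

    def __init__(self, latent_threshold_nc: float, slope: float = math.inf, seed: int = 0):
        if latent_threshold_nc <= 0:
            raise ValueError("latent threshold must be positive")
        self.latent_threshold_nc = latent_threshold_nc
        self.slope = slope
        self._rng = np.random.default_rng(seed)

    def probability(self, charge_nc: float) -> float:
        if math.isinf(self.slope):
            return 1.0 if charge_nc >= self.latent_threshold_nc else 0.0
        return float(expit(self.slope * (charge_nc - self.latent_threshold_nc)))

    def detect(self, charge_nc: float) -> bool:
        p = self.probability(charge_nc)
        if p in (0.0, 1.0):
            return bool(p)
        return bool(self._rng.random() < p)

    __call__ = detect


def make_observer(
    latent_threshold_nc: float, slope: float = math.inf, seed: int = 0
) -> DetectionObserver:
    """Build a detection observer with the given latent threshold (nC)."""
    return DetectionObserver(latent_threshold_nc, slope, seed)


def generate_resistance_series(
    r0_kohm: float,
    drift_kohm_per_week: float,
    weeks,
    trial_noise_kohm: float = 0.0,
    n_trials: int = 8,
    probe_current_ma: float = 0.2,
    seed: int = 0,
):
    """Per-session trial voltages for a contact whose true resistance drifts.

    True resistance at week ``w`` is ``r0 + drift * w``; each session yields
    ``n_trials`` voltage readings ``V = R_trial * I`` (volts) with Gaussian
    per-trial resistance noise. Returns ``(weeks, voltages)`` where voltages
    has shape ``(n_sessions, n_trials)``.
    """
    rng = np.random.default_rng(seed)
    weeks = np.asarray(weeks, dtype=float)
    true_r = r0_kohm + drift_kohm_per_week * weeks
    trials = true_r[:, None] + trial_noise_kohm * rng.standard_normal((len(weeks), n_trials))
    voltages = trials * probe_current_ma  # kOhm * mA = V
    return weeks, voltages
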