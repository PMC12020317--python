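"""Spectral detection of stimulation artifact in EMG and channel categorization.

Stimulation at frequency f (70 Hz in the deployed system) leaks narrow-band
power into EMG at f and its harmonics. Contamination is quantified against a
matched no-stimulation recording through two ratios computed from 500 ms
short-time Fourier spectrograms:

* ``phi_f`` — the stimulation/no-stimulation ratio of excess power at a
  harmonic, where excess is the median power at that frequency minus the
  pooled median in the neighbor bands [f-10, f-5] and [f+5, f+10] Hz;
* ``phi_overall`` — the ratio of median broadband power (10-500 Hz,
  excluding +/-5 Hz around every harmonic) with vs without stimulation.

Channels are then assigned one of five categories: unaffected, increased
overall power, intermittent artifact, consistent artifact, or unresponsive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .hardware import stimulation_harmonics
from .quality import ChannelClassification
from .recording import EmgRecording

PHI_THRESHOLD = 15.0
STFT_WINDOW_S = 0.5
ANALYSIS_BAND = (10.0, 500.0)
NEIGHBOR_OFFSETS = (5.0, 10.0)
EXCLUSION_HALF_WIDTH = 5.0


def spectrogram(recording: EmgRecording, window_s: float = STFT_WINDOW_S, channel: int = 0):
    """Power spectral density per (frequency bin, time frame).

    500 ms Hann windows with 50% overlap; frequency resolution 1/window_s.
    Returns (freqs, frame_times, power) with power of shape (n_freqs, n_frames).
    """
    fs = recording.sampling_rate
    nperseg = int(round(window_s * fs))
    if recording.n_samples < nperseg:
        raise ValueError("recording shorter than one STFT window")
    f, t, sxx = signal.spectrogram(
        recording.samples[channel],
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        scaling="density",
        mode="psd",
    )
    return f, t, sxx


def _excess_at(f: np.ndarray, sxx: np.ndarray, freq: float) -> tuple[float, float]:
    """(median power at freq, pooled neighbor-band median) over all frames."""
    near, far = NEIGHBOR_OFFSETS
    bin_idx = int(np.argmin(np.abs(f - freq)))
    at_f = float(np.median(sxx[bin_idx, :]))
    neighbor = ((f >= freq - far) & (f <= freq - near)) | (
        (f >= freq + near) & (f <= freq + far)
    )
    floor = float(np.median(sxx[neighbor, :]))
    return at_f - floor, floor


def _phi_from_spectra(f_s, sxx_s, f_n, sxx_n, freq: float) -> float:
    excess_stim, _ = _excess_at(f_s, sxx_s, freq)
    excess_nostim, floor_nostim = _excess_at(f_n, sxx_n, freq)
    if excess_stim <= 0:
        return 1.0
    denom = max(excess_nostim, floor_nostim, np.finfo(float).tiny)
    return float(excess_stim / denom)


def phi_at_frequency(
    stim_rec: EmgRecording,
    nostim_rec: EmgRecording,
    freq: float,
    channel: int = 0,
    window_s: float = STFT_WINDOW_S,
) -> float:
    """Ratio of stimulation-evoked excess power at one frequency.

    Excess power is the across-frame median at the target bin minus the
    pooled median of the neighbor bands. The denominator is floored at the
    no-stimulation neighbor-band level so the ratio stays finite when the
    no-stimulation recording has no excess at that frequency; a nonpositive
    stimulation excess is reported as 1.0 (no increase).
    """
    lo, hi = ANALYSIS_BAND
    if not lo < freq <= hi:
        raise ValueError(f"frequency {freq} Hz outside analysis band {ANALYSIS_BAND}")
    f_s, _, sxx_s = spectrogram(stim_rec, window_s, channel)
    f_n, _, sxx_n = spectrogram(nostim_rec, window_s, channel)
    return _phi_from_spectra(f_s, sxx_s, f_n, sxx_n, freq)


def phi_overall(
    stim_rec: EmgRecording,
    nostim_rec: EmgRecording,
    f_stim: float = 70.0,
    channel: int = 0,
    window_s: float = STFT_WINDOW_S,
) -> float:
    """Broadband median-power ratio with vs without stimulation.

    Pools power over all frames and all bins in 10-500 Hz outside +/-5 Hz of
    the stimulation frequency and each harmonic.
    """
    f_s, _, sxx_s = spectrogram(stim_rec, window_s, channel)
    f_n, _, sxx_n = spectrogram(nostim_rec, window_s, channel)
    lo, hi = ANALYSIS_BAND
    keep = (f_s >= lo) & (f_s <= hi)
    for h in stimulation_harmonics(f_stim, f_max=hi, f_min=0.0):
        keep &= np.abs(f_s - h) > EXCLUSION_HALF_WIDTH
    num = float(np.median(sxx_s[keep, :]))
    den = float(np.median(sxx_n[keep, :]))
    if den <= 0:
        raise ValueError("no-stimulation recording has zero broadband power")
    return num / den


@dataclass
class SpectralSummary:
    """Per-trial artifact ratios for one channel."""

    phi_f: dict[float, float]  # analyzed frequency -> ratio
    phi_overall: float
    window_s: float = STFT_WINDOW_S

    @property
    def max_phi_f(self) -> float:
        return max(self.phi_f.values())


def summarize_trial(
    stim_rec: EmgRecording,
    nostim_rec: EmgRecording,
    f_stim: float = 70.0,
    channel: int = 0,
    window_s: float = STFT_WINDOW_S,
) -> SpectralSummary:
    """phi_f at every harmonic plus phi_overall for one stim/no-stim trial pair."""
    freqs = stimulation_harmonics(f_stim, f_max=ANALYSIS_BAND[1], f_min=ANALYSIS_BAND[0])
    f_s, _, sxx_s = spectrogram(stim_rec, window_s, channel)
    f_n, _, sxx_n = spectrogram(nostim_rec, window_s, channel)
    phis = {h: _phi_from_spectra(f_s, sxx_s, f_n, sxx_n, h) for h in freqs}
    lo, hi = ANALYSIS_BAND
    keep = (f_s >= lo) & (f_s <= hi)
    for h in stimulation_harmonics(f_stim, f_max=hi, f_min=0.0):
        keep &= np.abs(f_s - h) > EXCLUSION_HALF_WIDTH
    den = float(np.median(sxx_n[keep, :]))
    if den <= 0:
        raise ValueError("no-stimulation recording has zero broadband power")
    return SpectralSummary(
        phi_f=phis,
        phi_overall=float(np.median(sxx_s[keep, :])) / den,
        window_s=window_s,
    )


CATEGORIES = (
    "unaffected",
    "increased_overall_power",
    "intermittent_artifact",
    "consistent_artifact",
    "unresponsive",
)


def categorize_channel(
    trials: list[SpectralSummary],
    classification: ChannelClassification,
    phi_threshold: float = PHI_THRESHOLD,
) -> str:
    """Assign one of the five stimulation-impact categories.

    Precedence: unresponsive (noise-only channel); increased overall power
    (phi_overall over threshold in any trial); consistent artifact (harmonic
    phi_f over threshold in every trial); intermittent artifact (over
    threshold in some but not all trials); otherwise unaffected.
    """
    if not trials:
        raise ValueError("need at least one trial")
    if classification.status == "noise_only":
        return "unresponsive"
    if any(t.phi_overall >= phi_threshold for t in trials):
        return "increased_overall_power"
    hot = [t.max_phi_f >= phi_threshold for t in trials]
    if all(hot):
        return "consistent_artifact"
    if any(hot):
        return "intermittent_artifact"
    return "unaffected"
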