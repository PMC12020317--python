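"""EMG filtering, quantization, and windowed WFL/MAV feature extraction.

Implements the feature pipeline as the implant streams it: a 15-350 Hz
bandpass on the raw 1 kHz signal, then waveform length (WFL) and mean
absolute value (MAV) computed over 100 ms windows.

Waveform length here is the sum of absolute sample-to-sample changes within
a window divided by the number of samples in the window, so it carries
microvolt units and is directly comparable to the noise-floor thresholds
used by the channel-quality classifier. MAV is the windowed mean of the
rectified signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .recording import EmgRecording, FeatureSeries

# legal input-referred resolution ranges, uV per least-significant bit
_RESOLUTION_RANGES = {8: (10.0, 100.0), 16: (0.04, 0.4)}


@dataclass(frozen=True)
class QuantizationModel:
    """Signed uniform quantizer of the analog front end.

    ``input_referred_resolution`` is the LSB size in microvolts; the legal
    range depends on bit depth (10-100 uV at 8 bits, 0.04-0.4 uV at 16 bits),
    reflecting the device's configurable gain.
    """

    bit_depth: int
    input_referred_resolution: float

    def __post_init__(self) -> None:
        if self.bit_depth not in _RESOLUTION_RANGES:
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        lo, hi = _RESOLUTION_RANGES[self.bit_depth]
        if not lo <= self.input_referred_resolution <= hi:
            raise ValueError(
                f"{self.bit_depth}-bit resolution must lie in [{lo}, {hi}] uV/LSB"
            )

    @property
    def max_code(self) -> int:
        return 2 ** (self.bit_depth - 1) - 1

    @property
    def min_code(self) -> int:
        return -(2 ** (self.bit_depth - 1))


def bandpass(recording: EmgRecording, low: float = 15.0, high: float = 350.0) -> EmgRecording:
    """Zero-phase 4th-order Butterworth bandpass.

    Applied forward-backward (``sosfiltfilt``) so that features stay aligned
    with the per-sample posture labels.
    """
    nyq = recording.sampling_rate / 2
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=recording.sampling_rate, output="sos")
    return recording.with_samples(signal.sosfiltfilt(sos, recording.samples, axis=1))


def _window_indices(n_samples: int, fs: float, window_ms: float, step_ms: float):
    win = int(round(window_ms * fs / 1000))
    step = int(round(step_ms * fs / 1000))
    if step <= 0 or win <= 0:
        raise ValueError("window and step must be positive")
    if step > win:
        raise ValueError("step must not exceed window length")
    if n_samples < win:
        raise ValueError("recording shorter than one window")
    n_win = (n_samples - win) // step + 1
    starts = np.arange(n_win) * step
    return win, step, starts


def _window_labels(recording: EmgRecording, starts: np.ndarray, win: int):
    """Label each window by its first sample (windows are short vs postures)."""
    labels = recording.posture_labels[starts]
    stim = recording.stim_flag[starts]
    return labels, stim


def compute_wfl(
    recording: EmgRecording, window_ms: float = 100.0, step_ms: float | None = None
) -> FeatureSeries:
    """Waveform length per window: sum of |x[i+1]-x[i]| over the window / n samples."""
    if step_ms is None:
        step_ms = window_ms
    win, step, starts = _window_indices(
        recording.n_samples, recording.sampling_rate, window_ms, step_ms
    )
    if win < 2:
        raise ValueError("WFL window must contain at least 2 samples")
    absdiff = np.abs(np.diff(recording.samples, axis=1))
    # window of length `win` samples spans win-1 first differences
    views = sliding_window_view(absdiff, win - 1, axis=1)[:, ::step, :]
    wfl = views[:, : len(starts), :].sum(axis=2) / win
    mav = _mav_values(recording.samples, win, step, len(starts))
    labels, stim = _window_labels(recording, starts, win)
    return FeatureSeries(
        wfl=wfl,
        mav=mav,
        window_ms=window_ms,
        step_ms=step_ms,
        window_start_times=starts / recording.sampling_rate,
        posture_labels=labels,
        stim_flag=stim,
    )


def _mav_values(samples: np.ndarray, win: int, step: int, n_win: int) -> np.ndarray:
    views = sliding_window_view(np.abs(samples), win, axis=1)[:, ::step, :]
    return views[:, :n_win, :].mean(axis=2)


def compute_mav(
    recording: EmgRecording, window_ms: float = 100.0, step_ms: float | None = None
) -> FeatureSeries:
    """Mean absolute value per window (sliding average of the rectified signal)."""
    if step_ms is None:
        step_ms = window_ms
    win, step, starts = _window_indices(
        recording.n_samples, recording.sampling_rate, window_ms, step_ms
    )
    mav = _mav_values(recording.samples, win, step, len(starts))
    if win >= 2:
        return compute_wfl(recording, window_ms, step_ms)
    labels, stim = _window_labels(recording, starts, win)
    return FeatureSeries(
        wfl=np.zeros_like(mav),
        mav=mav,
        window_ms=window_ms,
        step_ms=step_ms,
        window_start_times=starts / recording.sampling_rate,
        posture_labels=labels,
        stim_flag=stim,
    )


def quantize(recording: EmgRecording, model: QuantizationModel) -> EmgRecording:
    """Round each sample to the nearest LSB and clip to the signed code range."""
    res = model.input_referred_resolution
    codes = np.round(recording.samples / res)
    codes = np.clip(codes, model.min_code, model.max_code)
    return recording.with_samples(codes * res)


def quantize_features(
    values: np.ndarray, full_scale: float = 200.0, bits: int = 10
) -> np.ndarray:
    """Quantize nonnegative feature values to an unsigned code range.

    The implant streams features at 10-bit resolution; the full scale of
    that range is configurable (default 0-200 uV).
    """
    res = full_scale / (2**bits - 1)
    codes = np.clip(np.round(values / res), 0, 2**bits - 1)
    return codes * res


def stream_features(
    recording: EmgRecording,
    window_ms: float = 100.0,
    step_ms: float = 50.0,
    full_scale_uv: float = 200.0,
) -> FeatureSeries:
    """WFL features as streamed in real time: 100 ms bins, 50 ms update, 10-bit codes."""
    if recording.sampling_rate != 1000.0:
        raise ValueError("feature streaming is defined for 1 kHz recordings")
    feats = compute_wfl(recording, window_ms, step_ms)
    feats.wfl = quantize_features(feats.wfl, full_scale=full_scale_uv)
    feats.mav = quantize_features(feats.mav, full_scale=full_scale_uv)
    return feats
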