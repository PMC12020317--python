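"""Core data containers for intramuscular EMG recordings and windowed features.

An :class:`EmgRecording` holds a multichannel time series in microvolts at a
fixed sampling rate, with per-sample posture labels (``-1`` marks rest) and a
per-sample stimulation on/off flag. A :class:`FeatureSeries` holds per-window,
per-channel waveform length (WFL) and mean absolute value (MAV) features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

REST_LABEL = -1
DEFAULT_SAMPLING_RATE = 1000.0


@dataclass
class EmgRecording:
    """Multichannel EMG time series in microvolts.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    sampling_rate
        Samples per second; implanted sense modules stream at 1 kHz.
    posture_labels
        Per-sample posture id, ``-1`` during rest. Defaults to all rest.
    stim_flag
        Per-sample boolean, True while nerve stimulation is active.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    posture_labels: np.ndarray | None = None
    stim_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        n = self.samples.shape[1]
        if self.posture_labels is None:
            self.posture_labels = np.full(n, REST_LABEL, dtype=int)
        else:
            self.posture_labels = np.asarray(self.posture_labels, dtype=int)
        if self.stim_flag is None:
            self.stim_flag = np.zeros(n, dtype=bool)
        else:
            self.stim_flag = np.asarray(self.stim_flag, dtype=bool)
        if self.posture_labels.shape != (n,) or self.stim_flag.shape != (n,):
            raise ValueError("posture_labels and stim_flag must match sample count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        """Copy of this recording with the sample array replaced."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def to_hdf5(self, path: str, *, seed: int | None = None) -> None:
        """Write the recording as a single-file hierarchical dataset."""
        with h5py.File(path, "w") as f:
            f.create_dataset("emg", data=self.samples)
            f.create_dataset("labels", data=self.posture_labels)
            f.create_dataset("stim_flag", data=self.stim_flag)
            f.attrs["sampling_rate_hz"] = self.sampling_rate
            if seed is not None:
                f.attrs["seed"] = seed

    @classmethod
    def from_hdf5(cls, path: str) -> "EmgRecording":
        with h5py.File(path, "r") as f:
            return cls(
                samples=f["emg"][()],
                sampling_rate=float(f.attrs["sampling_rate_hz"]),
                posture_labels=f["labels"][()],
                stim_flag=f["stim_flag"][()].astype(bool),
            )


@dataclass
class FeatureSeries:
    """Windowed EMG features: WFL and MAV per channel per window.

    Windows are half-open intervals ``[t, t + window_ms)``; incomplete
    trailing windows are dropped to match streaming semantics.
    """

    wfl: np.ndarray
    mav: np.ndarray
    window_ms: float
    step_ms: float
    window_start_times: np.ndarray
    posture_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    stim_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wfl = np.atleast_2d(np.asarray(self.wfl, dtype=float))
        self.mav = np.atleast_2d(np.asarray(self.mav, dtype=float))
        self.window_start_times = np.asarray(self.window_start_times, dtype=float)
        n_win = self.wfl.shape[1]
        if self.posture_labels is None:
            self.posture_labels = np.full(n_win, REST_LABEL, dtype=int)
        if self.stim_flag is None:
            self.stim_flag = np.zeros(n_win, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.wfl.shape[0]

    @property
    def n_windows(self) -> int:
        return self.wfl.shape[1]

    def rest_windows(self) -> np.ndarray:
        """Boolean mask of windows labelled rest."""
        return self.posture_labels == REST_LABEL

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: channel, window_start_s, wfl_uv, mav_uv, labels."""
        n_ch, n_win = self.wfl.shape
        return pd.DataFrame(
            {
                "channel": np.repeat(np.arange(n_ch), n_win),
                "window_start_s": np.tile(self.window_start_times, n_ch),
                "wfl_uv": self.wfl.ravel(),
                "mav_uv": self.mav.ravel(),
                "posture_id": np.tile(self.posture_labels, n_ch),
                "stim_flag": np.tile(self.stim_flag, n_ch),
            }
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureSeries":
        df = pd.read_csv(path, sep="\t")
        channels = np.sort(df["channel"].unique())
        starts = np.sort(df["window_start_s"].unique())
        n_ch, n_win = len(channels), len(starts)
        df = df.sort_values(["channel", "window_start_s"])
        wfl = df["wfl_uv"].to_numpy().reshape(n_ch, n_win)
        mav = df["mav_uv"].to_numpy().reshape(n_ch, n_win)
        first = df.iloc[:n_win]
        step_ms = float(np.diff(starts).min() * 1000) if n_win > 1 else 50.0
        return cls(
            wfl=wfl,
            mav=mav,
            window_ms=step_ms,  # window length is not stored in the table
            step_ms=step_ms,
            window_start_times=starts,
            posture_labels=first["posture_id"].to_numpy(dtype=int),
            stim_flag=first["stim_flag"].to_numpy(dtype=bool),
        )
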