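"""Channel-quality classification and inter-channel crosstalk.

A channel is a viable myoelectric source only if its waveform-length (WFL)
series modulates with attempted movement. A channel is flagged noise-only
when all three of the following hold on its feature series: WFL variance
below 0.02, at most three WFL peaks exceeding three times the rest-period
baseline, and at least 90% of MAV windows below 17 uV. Crosstalk between
channels is the zero-lag Pearson correlation of their full-signal WFL
series; its session-to-session trend is tested against a constant model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .recording import FeatureSeries
from .stats import TrendResult, linear_trend_test

WFL_VARIANCE_THRESHOLD = 0.02  # uV^2-scale variance of the WFL series
PEAK_BASELINE_MULTIPLE = 3.0
MAX_NOISE_PEAKS = 3
MAV_CEILING_UV = 17.0
MAV_BELOW_FRACTION = 0.90
PEAK_MERGE_WINDOWS = 3  # peaks closer than this many windows count once


@dataclass
class ChannelClassification:
    channel: int
    status: str  # "responsive" | "noise_only"
    wfl_variance: float
    n_wfl_peaks: int
    mav_below_frac: float
    baseline_wfl: float


def _count_wfl_peaks(wfl: np.ndarray, baseline: float) -> int:
    """Local maxima of the WFL series above 3x baseline, nearby peaks merged."""
    height = PEAK_BASELINE_MULTIPLE * baseline
    if height <= 0:
        height = np.finfo(float).tiny  # all-zero baseline: any positive bump counts
    peaks, _ = find_peaks(wfl, height=height, distance=PEAK_MERGE_WINDOWS)
    return int(len(peaks))


def classify_noise_only(
    features: FeatureSeries, baseline_noise: np.ndarray | None = None
) -> list[ChannelClassification]:
    """Classify every channel as responsive or noise-only.

    ``baseline_noise`` (uV per channel) defaults to the median WFL over
    rest-labelled windows; an error is raised if no rest windows exist and
    no explicit baseline is given.
    """
    if baseline_noise is None:
        rest = features.rest_windows()
        if not rest.any():
            raise ValueError("no rest-labelled windows; baseline noise undefined")
        baseline_noise = np.median(features.wfl[:, rest], axis=1)
    else:
        baseline_noise = np.asarray(baseline_noise, dtype=float)

    out = []
    for c in range(features.n_channels):
        wfl = features.wfl[c]
        mav = features.mav[c]
        var = float(np.var(wfl))
        n_peaks = _count_wfl_peaks(wfl, float(baseline_noise[c]))
        below = float(np.mean(mav < MAV_CEILING_UV))
        noise_only = (
            var < WFL_VARIANCE_THRESHOLD
            and n_peaks <= MAX_NOISE_PEAKS
            and below >= MAV_BELOW_FRACTION
        )
        out.append(
            ChannelClassification(
                channel=c,
                status="noise_only" if noise_only else "responsive",
                wfl_variance=var,
                n_wfl_peaks=n_peaks,
                mav_below_frac=below,
                baseline_wfl=float(baseline_noise[c]),
            )
        )
    return out


@dataclass
class CrosstalkMatrix:
    """Symmetric matrix of zero-lag WFL correlations between channels."""

    values: np.ndarray
    session_week: float = 0.0
    zero_variance_channels: list[int] = field(default_factory=list)

    def mean_off_diagonal(self) -> float:
        n = self.values.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())


def crosstalk_matrix(features: FeatureSeries, session_week: float = 0.0) -> CrosstalkMatrix:
    """Pearson correlation of WFL series between every channel pair.

    Zero-variance channels get off-diagonal entries of 0 and are listed in
    ``zero_variance_channels``; the diagonal is 1 by definition.
    """
    wfl = features.wfl
    if wfl.shape[0] < 2:
        raise ValueError("crosstalk needs at least 2 channels")
    sd = wfl.std(axis=1)
    degenerate = np.nonzero(sd == 0)[0]
    n = wfl.shape[0]
    values = np.zeros((n, n))
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(wfl[ok])
        idx = np.nonzero(ok)[0]
        values[np.ix_(idx, idx)] = sub
    np.fill_diagonal(values, 1.0)
    return CrosstalkMatrix(
        values=values,
        session_week=session_week,
        zero_variance_channels=list(degenerate),
    )


def crosstalk_trend(matrices: list[CrosstalkMatrix]) -> TrendResult:
    """Regress mean off-diagonal crosstalk on session time vs a constant model."""
    if len(matrices) < 3:
        raise ValueError("need at least 3 sessions for a trend")
    weeks = [m.session_week for m in matrices]
    means = [m.mean_off_diagonal() for m in matrices]
    return linear_trend_test(weeks, means)
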