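"""Virtual posture-matching task with optional stimulation feedback.

A trial presents a target posture (three normalized joint angles in
[-1, +1]). The decoded 3-DOF velocity is integrated every 50 ms, with
angles clipped to range. A trial succeeds when all three joint-angle errors
stay within 15% of full range continuously for one second, inside a 30 s
limit. In the stimulation condition, feedback pulse frequency steps from 0
to 50 Hz when every DOF error falls within 22.5% of the target and to
100 Hz within 15%, at a fixed 250 us / 0.3 mA pulse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .controller import AnnController, decode
from .stats import group_compare

DT_S = 0.05
TRIAL_LIMIT_S = 30.0
SUCCESS_BAND = 0.15
FEEDBACK_BAND = 0.225
DWELL_S = 1.0
FEEDBACK_PULSE = {"width_us": 250.0, "amplitude_ma": 0.3}


@dataclass
class Trial:
    """One posture-matching attempt and its outcome metrics."""

    target: np.ndarray
    trajectory: np.ndarray  # (n_samples, 3) at 50 ms spacing
    success: bool
    time_to_target_s: float | None
    path_efficiency: float
    stim_condition: bool = False
    stim_frequency_log: np.ndarray = field(default_factory=lambda: np.array([]))


def stim_feedback(angles, target) -> float:
    """Feedback pulse frequency (Hz) from current joint-angle errors.

    0 Hz outside the 22.5% band, 50 Hz inside it, 100 Hz once every DOF is
    within the 15% success band.
    """
    err = np.abs(np.asarray(angles, dtype=float) - np.asarray(target, dtype=float))
    if np.all(err <= SUCCESS_BAND):
        return 100.0
    if np.all(err <= FEEDBACK_BAND):
        return 50.0
    return 0.0


def path_efficiency(trajectory) -> float:
    """Straight-line displacement over total distance traveled in angle space."""
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] < 2:
        raise ValueError("trajectory needs at least 2 samples")
    steps = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    total = steps.sum()
    if total == 0:
        warnings.warn("zero path length; efficiency defined as 0", stacklevel=2)
        return 0.0
    return float(np.linalg.norm(traj[-1] - traj[0]) / total)


def run_trial(
    controller,
    feature_stream,
    target,
    start=None,
    stim_condition: bool = False,
    dt_s: float = DT_S,
    limit_s: float = TRIAL_LIMIT_S,
) -> Trial:
    """Integrate one posture-matching trial.

    ``controller`` is an :class:`AnnController` or any callable mapping a
    feature vector to a 3-velocity. ``feature_stream`` is either an array of
    per-step feature vectors (open loop) or a callable
    ``(angles, target, t) -> features`` standing in for the user closing the
    loop. Success requires all DOF errors within the 15% band continuously
    for 1 s; ``time_to_target_s`` is the time at the end of that dwell.
    """
    target = np.asarray(target, dtype=float)
    angles = np.zeros(3) if start is None else np.asarray(start, dtype=float).copy()
    if isinstance(controller, AnnController):
        velocity_of = lambda f: decode(controller, f)
    else:
        velocity_of = controller
    scripted = callable(feature_stream)
    if not scripted:
        feature_stream = np.atleast_2d(np.asarray(feature_stream, dtype=float))
        if feature_stream.shape[0] == 0:
            raise ValueError("empty feature stream")

    traj = [angles.copy()]
    freq_log = []
    entered: float | None = None
    success = False
    time_to_target = None
    n_steps = int(round(limit_s / dt_s))
    for k in range(n_steps + 1):
        t = k * dt_s
        freq_log.append(stim_feedback(angles, target) if stim_condition else 0.0)
        in_band = np.all(np.abs(angles - target) <= SUCCESS_BAND)
        if in_band:
            if entered is None:
                entered = t
            if t - entered >= DWELL_S - 1e-9:
                success = True
                time_to_target = entered + DWELL_S
                break
        else:
            entered = None
        if t >= limit_s:
            break
        if scripted:
            feats = feature_stream(angles, target, t)
        else:
            feats = feature_stream[min(k, feature_stream.shape[0] - 1)]
        vel = np.asarray(velocity_of(np.asarray(feats, dtype=float)), dtype=float)
        angles = np.clip(angles + dt_s * vel, -1.0, 1.0)
        traj.append(angles.copy())

    traj = np.array(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eff = path_efficiency(traj) if traj.shape[0] >= 2 else 0.0
    return Trial(
        target=target,
        trajectory=traj,
        success=success,
        time_to_target_s=time_to_target,
        path_efficiency=eff,
        stim_condition=stim_condition,
        stim_frequency_log=np.array(freq_log),
    )


def generate_targets(n: int, seed: int = 0, margin: float = 0.8) -> np.ndarray:
    """Random reachable target postures, uniform in [-margin, margin]^3."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-margin, margin, size=(n, 3))


def evaluate_conditions(trials_stim: list[Trial], trials_nostim: list[Trial]) -> dict:
    """Compare matched stimulation/no-stimulation trial sets.

    Trials are paired by position and must share targets. Time-to-target is
    compared over pairs where both trials succeeded; path efficiency over
    all pairs; both with paired Wilcoxon signed-rank tests.
    """
    if len(trials_stim) != len(trials_nostim):
        raise ValueError("conditions have different trial counts")
    for a, b in zip(trials_stim, trials_nostim):
        if not np.allclose(a.target, b.target):
            raise ValueError("conditions must use matched targets")

    def _summary(trials):
        times = [t.time_to_target_s for t in trials if t.success]
        return {
            "success_rate": sum(t.success for t in trials) / len(trials),
            "median_time_to_target_s": float(np.median(times)) if times else None,
            "median_path_efficiency": float(np.median([t.path_efficiency for t in trials])),
        }

    both_ok = [
        (a.time_to_target_s, b.time_to_target_s)
        for a, b in zip(trials_stim, trials_nostim)
        if a.success and b.success
    ]
    report = {
        "stim": _summary(trials_stim),
        "no_stim": _summary(trials_nostim),
    }
    if len(both_ok) >= 2:
        ts, tn = map(np.array, zip(*both_ok))
        report["time_to_target_p"] = group_compare([ts, tn], paired=True).p_value
    eff_s = np.array([t.path_efficiency for t in trials_stim])
    eff_n = np.array([t.path_efficiency for t in trials_nostim])
    report["path_efficiency_p"] = group_compare([eff_s, eff_n], paired=True).p_value
    return report
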