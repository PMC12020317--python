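"""Proportional 3-DOF myoelectric controller trained on WFL features.

The controller maps a per-channel waveform-length vector to simultaneous
velocities for three degrees of freedom (hand open-close, wrist
flex-extend, pronate-supinate). Training targets are effort vectors: the
posture's direction vector (entries in {-1, 0, +1}) scaled at each time
point by the mean WFL across channels. Of the ten recorded repetitions per
posture, the three least similar in activation pattern are excluded, four
train the network, and three validate it. The network is a single hidden
layer of 14 tanh units with linear outputs; decoded velocities pass through
a per-direction deadband and gain.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor


@dataclass(eq=False)
class TrainingTrial:
    """One repetition of one prompted posture."""

    posture_id: int
    direction: np.ndarray  # shape (3,), entries in {-1, 0, +1}
    features: np.ndarray  # channels x time WFL, uV

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))


def enumerate_postures() -> list[np.ndarray]:
    """All single- and paired-DOF direction vectors, deterministically ordered.

    Vectors in {-1, 0, +1}^3 with exactly one or two nonzero entries:
    singles first, then pairs, in lexicographic order; 18 in total.
    """
    singles, pairs = [], []
    for v in itertools.product((-1, 0, 1), repeat=3):
        nnz = sum(1 for x in v if x != 0)
        if nnz == 1:
            singles.append(np.array(v, dtype=float))
        elif nnz == 2:
            pairs.append(np.array(v, dtype=float))
    return singles + pairs


def build_effort_targets(features: np.ndarray, direction) -> np.ndarray:
    """Effort time series e(t) = direction * mean-over-channels WFL(t); shape (3, T)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 0:
        raise ValueError("no channels")
    direction = np.asarray(direction, dtype=float)
    mean_wfl = features.mean(axis=0)
    return np.outer(direction, mean_wfl)


def _activation_pattern(trial: TrainingTrial) -> np.ndarray:
    return trial.features.mean(axis=1)


def _pattern_similarity(pattern: np.ndarray, reference: np.ndarray) -> float:
    if pattern.std() == 0 or reference.std() == 0:
        return 0.0
    return float(np.corrcoef(pattern, reference)[0, 1])


def select_repetitions(reps: list[TrainingTrial]):
    """Partition ten repetitions into (excluded 3, train 4, validation 3).

    Each repetition's per-channel mean-WFL pattern is correlated with the
    across-repetition median pattern; the three least similar are excluded,
    the four most similar of the remainder train, and the last three
    validate. Ties break on the lower repetition index.
    """
    if len(reps) != 10:
        raise ValueError(f"expected 10 repetitions, got {len(reps)}")
    patterns = np.array([_activation_pattern(r) for r in reps])
    median_pattern = np.median(patterns, axis=0)
    sims = [_pattern_similarity(p, median_pattern) for p in patterns]
    # ascending similarity, ties by index: first three are excluded
    order = sorted(range(10), key=lambda i: (sims[i], i))
    excluded_idx = order[:3]
    kept = order[3:]
    # remaining seven by descending similarity (ties by index)
    kept_desc = sorted(kept, key=lambda i: (-sims[i], i))
    train_idx, val_idx = kept_desc[:4], kept_desc[4:]
    pick = lambda idx: [reps[i] for i in sorted(idx)]
    return pick(excluded_idx), pick(train_idx), pick(val_idx)


@dataclass
class AnnController:
    """Trained feed-forward WFL-to-velocity mapping with per-direction tuning.

    ``gains`` and ``thresholds`` have shape (3, 2): column 0 applies to
    positive raw outputs, column 1 to negative, giving six independently
    tunable direction channels.
    """

    model: MLPRegressor
    input_channels: list[int]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    output_scale: float
    hidden_nodes: int = 14
    gains: np.ndarray = field(default=None)  # type: ignore[assignment]
    thresholds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gains is None:
            self.gains = np.ones((3, 2))
        if self.thresholds is None:
            self.thresholds = np.zeros((3, 2))
        if (np.asarray(self.gains) < 0).any() or (np.asarray(self.thresholds) < 0).any():
            raise ValueError("gains must be positive and thresholds nonnegative")

    def raw_output(self, features: np.ndarray) -> np.ndarray:
        """Network output before deadband/gain; accepts (n_ch,) or (T, n_ch)."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(self.input_channels):
            raise ValueError(
                f"expected {len(self.input_channels)} features, got {x.shape[1]}"
            )
        z = (x - self.feature_mean) / self.feature_std
        out = self.model.predict(z) * self.output_scale
        return out[0] if np.asarray(features).ndim == 1 else out


def _stack_trials(trials: list[TrainingTrial], channels) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for t in trials:
        feats = t.features[channels]
        xs.append(feats.T)
        ys.append(build_effort_targets(feats, t.direction).T)
    return np.vstack(xs), np.vstack(ys)


def train_ann(
    train: list[TrainingTrial],
    validation: list[TrainingTrial],
    hidden_nodes: int = 14,
    seed: int = 0,
    input_channels: list[int] | None = None,
    max_rounds: int = 60,
    iters_per_round: int = 20,
    patience: int = 10,
) -> AnnController:
    """Train the proportional controller network.

    Features are standardized per channel with training-set statistics and
    targets scaled to unit dispersion. Training runs in rounds, stopping
    when validation RMSE has not improved for ``patience`` evaluations; the
    best-validation weights are kept. Identical seed gives identical weights.
    """
    if not train:
        raise ValueError("empty training set")
    n_ch = train[0].features.shape[0]
    channels = list(range(n_ch)) if input_channels is None else list(input_channels)
    X, Y = _stack_trials(train, channels)
    if not np.any(X):
        raise ValueError("training features are all zero")
    Xv, Yv = _stack_trials(validation, channels) if validation else (None, None)

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    yscale = float(np.abs(Y).max()) or 1.0
    Xz, Yz = (X - mean) / std, Y / yscale

    model = MLPRegressor(
        hidden_layer_sizes=(hidden_nodes,),
        activation="tanh",
        solver="adam",
        random_state=seed,
        max_iter=iters_per_round,
        warm_start=True,
        tol=0.0,
    )
    best_rmse, best_state, stale = np.inf, None, 0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings per round are expected
        for _ in range(max_rounds):
            model.fit(Xz, Yz)
            if Xv is None:
                continue
            pred = model.predict((Xv - mean) / std) * yscale
            rmse = float(np.sqrt(np.mean((pred - Yv) ** 2)))
            if rmse < best_rmse - 1e-12:
                best_rmse, best_state, stale = rmse, copy.deepcopy(model), 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if best_state is not None:
        model = best_state
    return AnnController(
        model=model,
        input_channels=channels,
        feature_mean=mean,
        feature_std=std,
        output_scale=yscale,
        hidden_nodes=hidden_nodes,
    )


def decode(controller: AnnController, features: np.ndarray) -> np.ndarray:
    """Map one WFL feature vector to a 3-DOF velocity.

    Per DOF, with raw network output r: the direction-specific deadband
    threshold is subtracted from |r| (output is zero inside the deadband)
    and the remainder scaled by that direction's gain, preserving sign.
    Subtracting the threshold keeps velocity continuous at the deadband edge.
    """
    r = controller.raw_output(np.asarray(features, dtype=float))
    vel = np.zeros(3)
    for d in range(3):
        col = 0 if r[d] >= 0 else 1
        mag = abs(r[d]) - controller.thresholds[d, col]
        if mag > 0:
            vel[d] = np.sign(r[d]) * controller.gains[d, col] * mag
    return vel
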