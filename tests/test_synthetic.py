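"""Ground-truthed synthetic generators: EMG, artifacts, percepts, observers."""

import numpy as np
import pytest
from scipy import signal

from emgstim import (
    ArtifactSpec,
    LimbTemplate,
    PerceptDrift,
    SimConfig,
    generate_emg,
    generate_percept_series,
    generate_resistance_series,
    inject_artifact,
    jaccard,
    make_observer,
)
from emgstim.synthetic import inject_artifact_trials, square_mask


class TestGenerateEmg:
    def test_silent_config_gives_all_zeros(self):
        cfg = SimConfig(
            activation_matrix=np.zeros((3, 2)),
            posture_sequence=[(0, 1.0), (1, 1.0)],
            baseline_noise=0.0,
        )
        rec, gt = generate_emg(cfg)
        assert np.all(rec.samples == 0)
        assert gt.channel_roles == ["noise_only"] * 3

    def test_seed_determinism_is_bitwise(self):
        cfg = dict(
            activation_matrix=np.array([[30.0, 10.0]]),
            posture_sequence=[(0, 1.0), (1, 1.0)],
            seed=7,
        )
        a, _ = generate_emg(SimConfig(**cfg))
        b, _ = generate_emg(SimConfig(**cfg))
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.posture_labels, b.posture_labels)

    def test_posture_rms_matches_activation(self):
        cfg = SimConfig(
            activation_matrix=np.array([[0, 0, 0, 50.0]]),
            posture_sequence=[(3, 12.0)],
            baseline_noise=2.0,
            seed=1,
        )
        rec, _ = generate_emg(cfg)
        rms = np.sqrt(np.mean(rec.samples[0, rec.posture_labels == 3] ** 2))
        assert rms == pytest.approx(np.hypot(50.0, 2.0), rel=0.10)

    def test_rest_segments_are_labelled(self):
        cfg = SimConfig(
            activation_matrix=np.array([[20.0]]),
            posture_sequence=[(0, 1.0)],
            seed=0,
        )
        rec, _ = generate_emg(cfg)
        assert (rec.posture_labels == -1).sum() == 4000  # 2 s rest each side

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                activation_matrix=np.zeros((1, 1)),
                posture_sequence=[(0, 1.0)],
                sampling_rate=500.0,
                band=(15.0, 350.0),
            )


def _noise_recording(seed=2, dur=8.0, noise=5.0):
    cfg = SimConfig(
        activation_matrix=np.zeros((1, 1)),
        posture_sequence=[(0, dur)],
        baseline_noise=noise,
        seed=seed,
    )
    return generate_emg(cfg)[0]


class TestInjectArtifact:
    def test_null_spec_is_identity_up_to_flag(self):
        rec = _noise_recording()
        spec = ArtifactSpec(harmonic_amplitudes=(0.0,), broadband_gain=1.0)
        out = inject_artifact(rec, spec, [0])
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert out.stim_flag.all()

    def test_consistent_tone_dominates_periodogram(self):
        rec = _noise_recording()
        out = inject_artifact(rec, ArtifactSpec(harmonic_amplitudes=(20.0,)), [0])
        f, p = signal.periodogram(out.samples[0], fs=1000.0)
        peak = p[np.argmin(np.abs(f - 70.0))]
        neighbors = p[(np.abs(f - 70.0) > 5) & (np.abs(f - 70.0) < 15)]
        assert peak > 10 * np.median(neighbors)

    def test_broadband_gain_scales_median_power(self):
        rec = _noise_recording()
        out = inject_artifact(rec, ArtifactSpec(mode="overall_power", broadband_gain=4.0), [0])
        f, p0 = signal.periodogram(rec.samples[0], fs=1000.0)
        _, p1 = signal.periodogram(out.samples[0], fs=1000.0)
        keep = (f > 20) & (f < 340) & (np.abs(f - 70.0) > 5) & (np.abs(f - 140.0) > 5)
        ratio = np.median(p1[keep]) / np.median(p0[keep])
        assert ratio == pytest.approx(4.0, rel=0.20)

    def test_harmonic_above_nyquist_rejected(self):
        rec = _noise_recording()
        spec = ArtifactSpec(f_stim=70.0, harmonic_amplitudes=tuple([1.0] * 8))  # 560 Hz
        with pytest.raises(ValueError):
            inject_artifact(rec, spec, [0])

    def test_intermittent_trials_realize_stated_fraction(self):
        recs = [_noise_recording(seed=s) for s in range(6)]
        spec = ArtifactSpec(mode="intermittent", intermittent_fraction=0.5)
        out, flags = inject_artifact_trials(recs, spec, [0], seed=9)
        assert sum(flags) == 3
        assert all(r.stim_flag.all() for r in out)


class TestPerceptSeries:
    template = LimbTemplate()

    def test_zero_drift_gives_identical_rasters(self):
        reports = generate_percept_series(5, PerceptDrift(), self.template, seed=1)
        for r in reports[1:]:
            assert jaccard(reports[0]["mask"], r["mask"]) == 1.0

    def test_full_width_translation_disjoint(self):
        base = square_mask(self.template, (100, 100), 40)
        reports = generate_percept_series(
            2, PerceptDrift(translation_px=(0.0, 40.0)), self.template, seed=1, base_mask=base
        )
        assert jaccard(reports[0]["mask"], reports[1]["mask"]) == 0.0

    def test_half_width_translation_gives_one_third(self):
        base = square_mask(self.template, (100, 100), 40)
        reports = generate_percept_series(
            2, PerceptDrift(translation_px=(0.0, 20.0)), self.template, seed=1, base_mask=base
        )
        assert jaccard(reports[0]["mask"], reports[1]["mask"]) == pytest.approx(1 / 3)

    def test_centroid_drift_is_linear(self):
        drift = PerceptDrift(translation_px=(3.0, -2.0))
        reports = generate_percept_series(4, drift, self.template, seed=1)
        c0 = np.array(np.nonzero(reports[0]["mask"])).mean(axis=1)
        for s, r in enumerate(reports):
            c = np.array(np.nonzero(r["mask"])).mean(axis=1)
            np.testing.assert_allclose(c - c0, [3.0 * s, -2.0 * s], atol=1.0)

    def test_drift_off_template_raises(self):
        base = square_mask(self.template, (10, 10), 8)
        with pytest.raises(ValueError):
            generate_percept_series(
                5, PerceptDrift(translation_px=(-200.0, 0.0)), self.template, base_mask=base
            )

    def test_descriptors_drawn_from_lexicon(self):
        reports = generate_percept_series(3, PerceptDrift(), self.template, seed=5)
        for r in reports:
            assert len(r["descriptors"]) == 2


class TestObserver:
    def test_step_observer_at_threshold(self):
        obs = make_observer(100.0)
        assert not obs.detect(99.0)
        assert obs.detect(100.0)

    def test_detection_probability_nondecreasing(self):
        obs = make_observer(100.0, slope=0.05)
        charges = np.linspace(0, 250, 60)
        probs = [obs.probability(q) for q in charges]
        assert np.all(np.diff(probs) >= 0)

    def test_midpoint_detection_rate_is_half(self):
        obs = make_observer(100.0, slope=0.1, seed=3)
        hits = sum(obs.detect(100.0) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            make_observer(0.0)


class TestResistanceSeries:
    def test_noiseless_series_reflects_true_resistance(self):
        weeks, volts = generate_resistance_series(4.0, -0.078, np.arange(10.0))
        r = volts / 0.2  # kOhm
        np.testing.assert_allclose(r.mean(axis=1), 4.0 - 0.078 * weeks, atol=1e-12)

    def test_seeded_noise_is_reproducible(self):
        _, a = generate_resistance_series(4.0, 0.0, np.arange(5.0), trial_noise_kohm=0.3, seed=2)
        _, b = generate_resistance_series(4.0, 0.0, np.arange(5.0), trial_noise_kohm=0.3, seed=2)
        np.testing.assert_array_equal(a, b)
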