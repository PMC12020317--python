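"""Charge safety, threshold search, tissue resistance, and percept stability."""

import numpy as np
import pytest

from emgstim import (
    LimbTemplate,
    PerceptReport,
    ShannonParams,
    StimPulse,
    categorize_descriptors,
    charge_per_phase,
    estimate_resistance,
    hand_fraction,
    jaccard,
    linear_trend_test,
    location_stability,
    make_observer,
    measure_threshold,
    shannon_limit,
)
from emgstim.synthetic import square_mask


class TestChargePerPhase:
    @pytest.mark.parametrize(
        "amp,width,expected", [(0.3, 250.0, 75.0), (0.0, 250.0, 0.0), (1.0, 250.0, 250.0)]
    )
    def test_unit_arithmetic(self, amp, width, expected):
        assert charge_per_phase(amp, width) == expected

    def test_pulse_is_charge_balanced(self):
        p = StimPulse(amplitude_ma=0.4, cathodic_width_us=200.0)
        assert p.anodic_width_us == 2 * p.cathodic_width_us
        assert p.anodic_amplitude_ma == p.amplitude_ma / 2
        # equal charge per phase in both directions
        assert p.anodic_amplitude_ma * p.anodic_width_us == p.charge_per_phase_nc


class TestShannonLimit:
    def test_deployed_contact_gives_250_nc(self):
        q = shannon_limit(ShannonParams(k=1.1, contact_area_cm2=0.005))
        assert float(f"{q:.2g}") == 250.0

    def test_closed_form_cases(self):
        assert shannon_limit(ShannonParams(k=0.0, contact_area_cm2=1.0)) == pytest.approx(1000.0)
        # closed form: 10 ** ((1.1 + log10(0.02)) / 2) uC = 501.8 nC
        assert shannon_limit(ShannonParams(k=1.1, contact_area_cm2=0.02)) == pytest.approx(
            501.8, abs=0.1
        )

    def test_strictly_increasing_in_k_and_area(self):
        base = shannon_limit(ShannonParams(k=1.1, contact_area_cm2=0.005))
        assert shannon_limit(ShannonParams(k=1.2, contact_area_cm2=0.005)) > base
        assert shannon_limit(ShannonParams(k=1.1, contact_area_cm2=0.006)) > base

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            ShannonParams(contact_area_cm2=0.0)


class TestMeasureThreshold:
    def test_hypersensitive_observer_hits_search_floor(self):
        m = measure_threshold(lambda q: True)
        assert (m.amplitude_ma, m.pulse_width_us) == (0.01, 10.0)
        assert m.threshold_charge_nc == pytest.approx(0.1)

    def test_insensate_observer_is_censored(self):
        m = measure_threshold(lambda q: False)
        assert m.censored

    def test_deterministic_observer_recovered_within_grid(self):
        m = measure_threshold(make_observer(50.0))
        bound = 0.01 * 250.0 + m.amplitude_ma * 10.0
        assert 50.0 - 1e-9 <= m.threshold_charge_nc <= 50.0 + bound
        assert not m.censored

    def test_noncensored_charge_never_exceeds_safety_limit(self, rng):
        for latent in rng.uniform(20, 240, size=50):
            m = measure_threshold(make_observer(float(latent)))
            assert m.threshold_charge_nc <= 250.0 + 1e-9
            assert m.threshold_charge_nc >= latent - 1e-9


class TestResistance:
    def test_ohms_law_average(self):
        m = estimate_resistance(np.full(8, 0.8))
        assert m.resistance_kohm == pytest.approx(4.0)
        assert m.n_trials == 8
        assert not m.excluded

    def test_single_high_trial_excludes_contact(self):
        volts = np.r_[np.full(7, 0.8), 16.0 * 0.2]
        assert estimate_resistance(volts).excluded

    def test_noiseless_drift_slope_recovered(self):
        from emgstim import generate_resistance_series

        weeks, volts = generate_resistance_series(4.0, -0.078, np.arange(12.0))
        r = [estimate_resistance(v, session_week=w).resistance_kohm for w, v in zip(weeks, volts)]
        res = linear_trend_test(weeks, r)
        assert res.slope == pytest.approx(-0.078, abs=1e-9)


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        b = ~a
        assert jaccard(a, a) == 1.0
        assert jaccard(a, b) == 0.0

    def test_pixel_count_oracle(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert jaccard(a, b) == pytest.approx(50 / 150)

    def test_symmetry(self, rng):
        a = rng.random((15, 15)) > 0.5
        b = rng.random((15, 15)) > 0.5
        assert jaccard(a, b) == jaccard(b, a)

    def test_empty_masks_warn_and_return_zero(self):
        z = np.zeros((5, 5), bool)
        with pytest.warns(UserWarning):
            assert jaccard(z, z) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard(np.zeros((5, 5), bool), np.zeros((6, 5), bool))


def _report(mask, descriptors=("pressure",), week=0.0):
    return PerceptReport(contact=0, session_week=week, location_mask=mask,
                         descriptors=list(descriptors))


class TestLocationStability:
    template = LimbTemplate(height=64, width=64, wrist_row=32)

    def test_identical_masks_give_unity(self):
        m = square_mask(self.template, (10, 10), 8)
        assert location_stability([_report(m)] * 3) == 1.0

    def test_disjoint_masks_give_zero(self):
        masks = [square_mask(self.template, (8 + 16 * i, 8), 8) for i in range(3)]
        assert location_stability([_report(m) for m in masks]) == 0.0

    def test_mean_of_pairwise_similarities(self):
        # J(a,b) = 1, J(a,c) = J(b,c) = 0.5 -> mean 2/3
        a = np.zeros((64, 64), bool)
        a.ravel()[:150] = True
        c = np.zeros((64, 64), bool)
        c.ravel()[50:200] = True
        reports = [_report(a), _report(a.copy()), _report(c)]
        assert location_stability(reports) == pytest.approx(2 / 3)

    def test_proprioception_only_sessions_excluded(self):
        m = square_mask(self.template, (10, 10), 8)
        reports = [_report(m), _report(m), _report(m, descriptors=["contraction"])]
        usable = location_stability(reports)
        assert usable == 1.0
        assert location_stability(reports[:1] + [reports[2]]) is None


class TestHandFraction:
    template = LimbTemplate(height=64, width=64, wrist_row=32)

    def test_counting_oracle(self):
        distal = square_mask(self.template, (10, 10), 8)  # above wrist row
        proximal = square_mask(self.template, (50, 10), 8)
        by_contact = {}
        for c in range(15):
            mask = distal if c < 3 else proximal
            by_contact[c] = [_report(mask)]
        assert hand_fraction(by_contact, self.template) == pytest.approx(3 / 15)

    @pytest.mark.parametrize("row,expected", [(10, 1.0), (50, 0.0)])
    def test_all_on_one_side(self, row, expected):
        mask = square_mask(self.template, (row, 10), 8)
        by_contact = {c: [_report(mask)] for c in range(4)}
        assert hand_fraction(by_contact, self.template) == expected

    def test_proprioception_only_contacts_not_counted(self):
        distal = square_mask(self.template, (10, 10), 8)
        by_contact = {
            0: [_report(distal)],
            1: [_report(distal, descriptors=["contraction"])],
        }
        assert hand_fraction(by_contact, self.template) == 1.0


class TestPerceptIO:
    def test_png_sidecar_round_trip(self, tmp_path, rng):
        from emgstim.percepts import load_percept_mask, save_percept_mask

        mask = rng.random((32, 32)) > 0.5
        report = _report(mask, descriptors=("vibration", "tap"), week=6.0)
        path = str(tmp_path / "contact0_s6.png")
        save_percept_mask(report, path)
        back = load_percept_mask(path)
        np.testing.assert_array_equal(back.location_mask, mask)
        assert back.descriptors == ["vibration", "tap"]
        assert back.session_week == 6.0


class TestDescriptorCategories:
    def test_tactile_terms(self):
        assert categorize_descriptors(["vibration", "pressure"]) == {"tactile"}

    def test_proprioceptive_term(self):
        assert categorize_descriptors(["contraction"]) == {"proprioceptive"}

    def test_empty_list(self):
        assert categorize_descriptors([]) == set()

    def test_mixed_categories_union(self):
        cats = categorize_descriptors(["pressure", "sharp", "movement"])
        assert cats == {"tactile", "pain", "proprioceptive"}

    def test_unknown_term_defaults_to_tactile_with_warning(self):
        with pytest.warns(UserWarning):
            assert categorize_descriptors(["fizzy"]) == {"tactile"}
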