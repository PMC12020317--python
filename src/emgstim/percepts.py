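"""Perceptual-threshold psychophysics, charge safety, tissue resistance, and
percept stability metrics for nerve-cuff stimulation.

Charge per phase Q = I * t (cathodic amplitude times cathodic width) is the
dose metric throughout. The safe-charge ceiling follows the Shannon
criterion log10(Q/A) = k - log10(Q) with Q in uC and charge density Q/A in
uC/cm^2; thresholds are found by an amplitude ramp followed by a binary
search on pulse width. Percept-location stability is quantified by Jaccard
similarity between binary drawing rasters.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np


@dataclass(frozen=True)
class StimPulse:
    """Biphasic, cathode-first, charge-balanced rectangular pulse.

    The anodic phase is twice the cathodic width at half the amplitude so
    that the two phases carry equal charge.
    """

    amplitude_ma: float
    cathodic_width_us: float
    frequency_hz: float = 100.0

    @property
    def anodic_width_us(self) -> float:
        return 2.0 * self.cathodic_width_us

    @property
    def anodic_amplitude_ma(self) -> float:
        return self.amplitude_ma / 2.0

    @property
    def charge_per_phase_nc(self) -> float:
        return charge_per_phase(self.amplitude_ma, self.cathodic_width_us)


@dataclass(frozen=True)
class ShannonParams:
    """Shannon-criterion coefficient and electrode contact area (cm^2)."""

    k: float = 1.1
    contact_area_cm2: float = 0.005

    def __post_init__(self) -> None:
        if self.contact_area_cm2 <= 0:
            raise ValueError("contact area must be positive")


@dataclass
class ThresholdMeasurement:
    contact: int
    session_week: float
    amplitude_ma: float
    pulse_width_us: float
    threshold_charge_nc: float
    censored: bool = False


@dataclass
class ResistanceMeasurement:
    contact: int
    session_week: float
    resistance_kohm: float
    n_trials: int
    excluded: bool


@dataclass
class PerceptReport:
    """One contact x session percept description."""

    contact: int
    session_week: float
    location_mask: np.ndarray
    descriptors: list[str] = field(default_factory=list)

    @property
    def categories(self) -> set[str]:
        return categorize_descriptors(self.descriptors)

    @property
    def proprioception_only(self) -> bool:
        return self.categories == {"proprioceptive"}


def charge_per_phase(amplitude_ma: float, cathodic_width_us: float) -> float:
    """Charge per phase in nC: mA x us = nC."""
    if amplitude_ma < 0 or cathodic_width_us < 0:
        raise ValueError("amplitude and width must be nonnegative")
    return amplitude_ma * cathodic_width_us


def shannon_limit(params: ShannonParams) -> float:
    """Maximum safe charge per phase (nC) under the Shannon criterion.

    Solving log10(Q/A) = k - log10(Q) for Q (uC, area in cm^2) gives
    Q = 10 ** ((k + log10 A) / 2); the default parameters (k = 1.1,
    0.5 mm^2 contact) give approximately 250 nC.
    """
    q_uc = 10 ** ((params.k + math.log10(params.contact_area_cm2)) / 2)
    return q_uc * 1000.0


def measure_threshold(
    observer,
    safety_limit_nc: float = 250.0,
    contact: int = 0,
    session_week: float = 0.0,
    amplitude_step_ma: float = 0.01,
    start_width_us: float = 250.0,
    min_width_us: float = 10.0,
    width_resolution_us: float = 10.0,
) -> ThresholdMeasurement:
    """Two-phase perceptual threshold search.

    Phase 1 ramps pulse amplitude from zero in 0.01 mA steps at a fixed
    250 us cathodic width until the observer reports detection; if the
    safety limit is reached first the measurement is censored. Phase 2 holds
    that amplitude and binary-searches the cathodic width on
    [min_width, start_width] until the bracket is within the stated
    resolution, returning the smallest detected width.
    """
    amp = 0.0
    detected = False
    while True:
        amp_next = amp + amplitude_step_ma
        if charge_per_phase(amp_next, start_width_us) > safety_limit_nc:
            break
        amp = amp_next
        if observer(charge_per_phase(amp, start_width_us)):
            detected = True
            break
    if not detected:
        return ThresholdMeasurement(
            contact=contact,
            session_week=session_week,
            amplitude_ma=amp,
            pulse_width_us=start_width_us,
            threshold_charge_nc=safety_limit_nc,
            censored=True,
        )

    if observer(charge_per_phase(amp, min_width_us)):
        width = min_width_us
    else:
        lo, hi = min_width_us, start_width_us  # lo undetected, hi detected
        while hi - lo > width_resolution_us:
            mid = (lo + hi) / 2
            if observer(charge_per_phase(amp, mid)):
                hi = mid
            else:
                lo = mid
        width = hi
    return ThresholdMeasurement(
        contact=contact,
        session_week=session_week,
        amplitude_ma=amp,
        pulse_width_us=width,
        threshold_charge_nc=charge_per_phase(amp, width),
        censored=False,
    )


RESISTANCE_PROBE = StimPulse(amplitude_ma=0.2, cathodic_width_us=70.0, frequency_hz=1000.0)
RESISTANCE_EXCLUSION_KOHM = 15.0


def estimate_resistance(
    trial_voltages_v,
    probe: StimPulse = RESISTANCE_PROBE,
    contact: int = 0,
    session_week: float = 0.0,
) -> ResistanceMeasurement:
    """Tissue resistance from sub-threshold probe pulses, averaged over trials.

    Per-trial R = V / I (V in volts, I in mA gives kOhm); a contact with any
    trial above 15 kOhm is flagged excluded (interpreted as a loose
    connection rather than a tissue change).
    """
    if probe.amplitude_ma <= 0:
        raise ValueError("probe current must be positive")
    v = np.asarray(trial_voltages_v, dtype=float)
    r_trials = v / probe.amplitude_ma
    return ResistanceMeasurement(
        contact=contact,
        session_week=session_week,
        resistance_kohm=float(r_trials.mean()),
        n_trials=v.size,
        excluded=bool((r_trials > RESISTANCE_EXCLUSION_KOHM).any()),
    )


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard similarity |A n B| / |A u B| of two binary rasters."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty; Jaccard defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def location_stability(reports: list[PerceptReport]) -> float | None:
    """Mean pairwise Jaccard similarity across a contact's sessions.

    Proprioception-only reports are excluded; returns None when fewer than
    two usable sessions remain.
    """
    usable = [r for r in reports if not r.proprioception_only]
    if len(usable) < 2:
        return None
    sims = [
        jaccard(usable[i].location_mask, usable[j].location_mask)
        for i in range(len(usable))
        for j in range(i + 1, len(usable))
    ]
    return float(np.mean(sims))


def hand_fraction(reports_by_contact: dict[int, list[PerceptReport]], template) -> float:
    """Fraction of contacts evoking percepts distal to the wrist line.

    A contact counts as "on the hand" if any of its (non
    proprioception-only) drawings has at least one pixel distal to the
    wrist; proprioception-only contacts are excluded from the denominator.
    """
    distal = template.distal_mask()
    n_eligible = 0
    n_hand = 0
    for reports in reports_by_contact.values():
        usable = [r for r in reports if not r.proprioception_only]
        if not usable:
            continue
        n_eligible += 1
        if any((r.location_mask & distal).any() for r in usable):
            n_hand += 1
    if n_eligible == 0:
        return 0.0
    return n_hand / n_eligible


def save_percept_mask(report: PerceptReport, png_path: str) -> None:
    """Write a percept drawing as a binary PNG plus a JSON sidecar.

    The sidecar (same stem, ``.json``) carries contact id, session, and
    descriptors; the PNG holds the location raster (255 = selected).
    """
    from PIL import Image

    img = Image.fromarray((report.location_mask.astype(np.uint8)) * 255, mode="L")
    img.save(png_path)
    sidecar = {
        "contact_id": report.contact,
        "session": report.session_week,
        "descriptors": report.descriptors,
    }
    with open(str(png_path).rsplit(".", 1)[0] + ".json", "w") as f:
        json.dump(sidecar, f)


def load_percept_mask(png_path: str) -> PerceptReport:
    """Read a percept drawing written by :func:`save_percept_mask`."""
    from PIL import Image

    mask = np.asarray(Image.open(png_path).convert("L")) > 127
    with open(str(png_path).rsplit(".", 1)[0] + ".json") as f:
        sidecar = json.load(f)
    return PerceptReport(
        contact=int(sidecar["contact_id"]),
        session_week=float(sidecar["session"]),
        location_mask=mask,
        descriptors=list(sidecar["descriptors"]),
    )


def _load_default_category_map() -> dict[str, str]:
    with resources.files("emgstim.data").joinpath("descriptor_categories.json").open() as f:
        return json.load(f)


_DEFAULT_CATEGORY_MAP: dict[str, str] | None = None


def default_category_map() -> dict[str, str]:
    """Descriptor -> {tactile, proprioceptive, pain} lookup (editable data)."""
    global _DEFAULT_CATEGORY_MAP
    if _DEFAULT_CATEGORY_MAP is None:
        _DEFAULT_CATEGORY_MAP = _load_default_category_map()
    return dict(_DEFAULT_CATEGORY_MAP)


def categorize_descriptors(
    descriptors: list[str], category_map: dict[str, str] | None = None
) -> set[str]:
    """Map free-text quality descriptors to their category set.

    Unknown terms default to tactile with a warning; an empty descriptor
    list yields an empty set.
    """
    if not descriptors:
        return set()
    cmap = category_map if category_map is not None else default_category_map()
    cats = set()
    for term in descriptors:
        key = term.strip().lower()
        if key not in cmap:
            warnings.warn(f"unknown descriptor {term!r}; defaulting to tactile", stacklevel=2)
            cats.add("tactile")
        else:
            cats.add(cmap[key])
    return cats
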