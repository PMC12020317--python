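"""Data model of the implanted stimulation/recording hardware configuration.

The implant architecture pairs multi-contact extraneural nerve cuffs
(stimulation) with intramuscular electrode arrays (bipolar EMG recording),
driven by stimulation and sense modules under one implanted controller.
This module encodes the channel arithmetic of that architecture so that
derived counts (bipolar pairs, total channels) come from constructors rather
than hand-entered constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class NerveCuff:
    """Multi-contact extraneural cuff electrode (one nerve)."""

    n_contacts: int = 16

    def __post_init__(self) -> None:
        if self.n_contacts <= 0:
            raise ValueError("cuff must have at least one contact")


@dataclass(frozen=True)
class IntramuscularArray:
    """Intramuscular electrode array providing bipolar EMG channels."""

    n_bipolar_channels: int = 4


@dataclass(frozen=True)
class SenseModule:
    """EMG sense module: monopolar inputs configured into bipolar pairs."""

    n_inputs: int = 16

    def __post_init__(self) -> None:
        if self.n_inputs % 2:
            raise ValueError("bipolar pairing needs an even input count")

    @property
    def n_bipolar_pairs(self) -> int:
        return self.n_inputs // 2


@dataclass(frozen=True)
class StimModule:
    """Stimulation module driving two nerve cuffs."""

    cuffs: tuple[NerveCuff, ...] = (NerveCuff(), NerveCuff())

    @property
    def n_stim_channels(self) -> int:
        return sum(c.n_contacts for c in self.cuffs)


@dataclass(frozen=True)
class ImplantSystem:
    """Full implant: stimulation modules plus sense modules.

    Defaults describe the deployed configuration: two stim modules, each
    driving two 16-contact cuffs (64 stimulation channels total), and two
    sense modules at 16 inputs each, connected to four intramuscular arrays
    (16 bipolar recording channels total).
    """

    stim_modules: tuple[StimModule, ...] = (StimModule(), StimModule())
    sense_modules: tuple[SenseModule, ...] = (SenseModule(), SenseModule())
    arrays: tuple[IntramuscularArray, ...] = field(
        default=tuple(IntramuscularArray() for _ in range(4))
    )

    @property
    def total_stim_channels(self) -> int:
        return sum(m.n_stim_channels for m in self.stim_modules)

    @property
    def total_recording_channels(self) -> int:
        return sum(a.n_bipolar_channels for a in self.arrays)

    @property
    def n_cuffs(self) -> int:
        return sum(len(m.cuffs) for m in self.stim_modules)


def stimulation_harmonics(
    f_stim: float, f_max: float = 500.0, f_min: float = 10.0
) -> list[float]:
    """Stimulation frequency and its harmonics inside the analysis band.

    Returns every integer multiple of ``f_stim`` in ``(f_min, f_max]``,
    the frequencies at which narrow-band artifact power is assessed
    (70 Hz stimulation gives 70, 140, ..., 490 Hz under a 500 Hz cap).
    """
    if f_stim <= 0:
        raise ValueError("f_stim must be positive")
    k_max = int(f_max // f_stim)
    return [k * f_stim for k in range(1, k_max + 1) if k * f_stim > f_min]
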