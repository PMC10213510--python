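"""Sentence timeline model and three-interval trial assembly.

Each trial presents a reference sentence (intact speech) followed by
two comparison sentences in which the two gap words are replaced by
silence: one comparison keeps the reference gap duration ``T`` and the
other carries a shortened gap ``T*(1 - dT/T)`` (early final-word onset)
or a lengthened gap ``T*(1 + dT/T)`` (late onset).  The comparison
order is randomised, the inter-stimulus intervals are jittered to block
cross-sentence timing cues, and in the altered-rhythm conditions the
same sinusoidal warp (same starting phase) is applied to the early
region of all three intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .warp import PHASE_SET, Modulator, build_frame_schedule, warp_waveform

__all__ = [
    "RHYTHM_CONDITIONS",
    "DIRECTIONS",
    "SentenceTemplate",
    "TrialSpec",
    "MALE_TEMPLATE",
    "FEMALE_TEMPLATE",
    "condition_modulator",
    "altered_gap_ms",
    "make_trial",
    "render_trial_audio",
    "NoiseBurstSynth",
]

RHYTHM_CONDITIONS = ("unaltered", "low_rate", "high_rate")
DIRECTIONS = ("early", "late")

#: default modulation depth in the altered-rhythm conditions
DEFAULT_DEPTH = 0.75
#: modulator cycles per condition (low-rate = 1, high-rate = 3)
CONDITION_CYCLES = {"low_rate": 1, "high_rate": 3}

ISI_RANGE_MS = (400.0, 800.0)


@dataclass(frozen=True)
class SentenceTemplate:
    """Abstract timeline of a CRM-style sentence.

    ``early_ms`` covers the pre-gap carrier words, ``gap_ms`` is the
    reference gap duration ``T`` (the duration of the two removed
    words), and ``final_word_ms`` the sentence-final target word.
    """

    speaker: Literal["male", "female"]
    early_ms: float
    gap_ms: float
    final_word_ms: float

    def __post_init__(self) -> None:
        for name in ("early_ms", "gap_ms", "final_word_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: reference gap T is 1661 ms (male) / 1603 ms (female); the early-region
#: and final-word durations are plausible spoken-word lengths for the
#: four carrier words and the monosyllabic target.
MALE_TEMPLATE = SentenceTemplate("male", early_ms=1200.0, gap_ms=1661.0, final_word_ms=350.0)
FEMALE_TEMPLATE = SentenceTemplate("female", early_ms=1150.0, gap_ms=1603.0, final_word_ms=330.0)

_DELTA_BOUNDS = {"early": (0.0, 1.0), "late": (0.0, 2.0)}


@dataclass(frozen=True)
class TrialSpec:
    """One two-interval trial: condition labels plus the random draws."""

    rhythm_condition: str
    direction: Literal["early", "late"]
    delta_frac: float
    altered_position: Literal["first", "second"]
    isi_ms: tuple[float, float]
    modulator_phase: float
    speaker: str

    def __post_init__(self) -> None:
        if self.rhythm_condition not in RHYTHM_CONDITIONS:
            raise ValueError(f"unknown rhythm condition {self.rhythm_condition!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        lo, hi = _DELTA_BOUNDS[self.direction]
        if not lo <= self.delta_frac <= hi:
            raise ValueError(
                f"delta_frac {self.delta_frac} outside [{lo}, {hi}] for {self.direction} onsets"
            )
        if self.altered_position not in ("first", "second"):
            raise ValueError("altered_position must be 'first' or 'second'")
        for isi in self.isi_ms:
            if not ISI_RANGE_MS[0] <= isi <= ISI_RANGE_MS[1]:
                raise ValueError(f"ISI {isi} ms outside {ISI_RANGE_MS}")


def condition_modulator(
    rhythm_condition: str, phase: float, depth: float = DEFAULT_DEPTH
) -> Modulator:
    """Modulator for a rhythm condition; the unaltered condition maps to depth 0."""
    if rhythm_condition == "unaltered":
        return Modulator(depth=0.0, cycles=1, phase=phase)
    return Modulator(depth=depth, cycles=CONDITION_CYCLES[rhythm_condition], phase=phase)


def altered_gap_ms(template: SentenceTemplate, direction: str, delta_frac: float) -> float:
    """Altered gap duration: ``T*(1 - dT/T)`` for early, ``T*(1 + dT/T)`` for late."""
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    lo, hi = _DELTA_BOUNDS[direction]
    if not lo <= delta_frac <= hi:
        raise ValueError(
            f"delta_frac {delta_frac} outside [{lo}, {hi}] for {direction} onsets"
        )
    sign = -1.0 if direction == "early" else 1.0
    return template.gap_ms * (1.0 + sign * delta_frac)


def make_trial(
    template: SentenceTemplate,
    rhythm_condition: str,
    direction: str,
    delta_frac: float,
    rng: np.random.Generator,
) -> TrialSpec:
    """Draw the random trial attributes: comparison order, ISIs, phase.

    The modulator phase is drawn uniformly from the eight permitted
    values and, by construction of :func:`render_trial_audio`, the same
    phase (hence the same warp schedule) applies to the early region of
    the reference and of both comparisons.
    """
    return TrialSpec(
        rhythm_condition=rhythm_condition,
        direction=direction,
        delta_frac=delta_frac,
        altered_position="first" if rng.random() < 0.5 else "second",
        isi_ms=tuple(rng.uniform(*ISI_RANGE_MS, size=2)),
        modulator_phase=PHASE_SET[rng.integers(len(PHASE_SET))],
        speaker=template.speaker,
    )


class NoiseBurstSynth:
    """Synthetic stand-in audio: amplitude-modulated noise word bursts.

    Words are rendered as Gaussian noise shaped by raised-cosine
    envelopes of word-like lengths.  The observer model consumes event
    timing only, so phonetic realism is irrelevant; the synth exists so
    that the rendering pipeline (warp, gap arithmetic, concatenation)
    can be exercised on real waveforms.
    """

    def __init__(self, template: SentenceTemplate, sample_rate: float = 16000.0,
                 rng: np.random.Generator | None = None):
        self.template = template
        self.sample_rate = sample_rate
        rng = rng if rng is not None else np.random.default_rng(0)
        self._early = self._word_sequence(template.early_ms, n_words=4, rng=rng)
        self._gap_words = self._word_sequence(template.gap_ms, n_words=2, rng=rng)
        self._final = self._word_sequence(template.final_word_ms, n_words=1, rng=rng)

    def _word_sequence(self, total_ms: float, n_words: int,
                       rng: np.random.Generator) -> np.ndarray:
        n = int(round(total_ms * self.sample_rate / 1000.0))
        out = np.zeros(n)
        edges = np.linspace(0, n, n_words + 1).astype(int)
        for a, b in zip(edges[:-1], edges[1:]):
            seg = b - a
            burst = int(seg * 0.8)  # 20% inter-word breath
            env = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(burst) / max(burst - 1, 1)))
            out[a : a + burst] = rng.standard_normal(burst) * env * 0.3
        return out

    def early(self) -> np.ndarray:
        return self._early

    def gap_words(self) -> np.ndarray:
        return self._gap_words

    def final(self) -> np.ndarray:
        return self._final


def _ms_to_samples(ms: float, rate: float) -> int:
    return int(round(ms * rate / 1000.0))


def render_trial_audio(
    trial: TrialSpec,
    template: SentenceTemplate,
    synth: NoiseBurstSynth,
    depth: float = DEFAULT_DEPTH,
    frame_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (reference, first comparison, second comparison) waveforms.

    The reference keeps the gap words audible; both comparisons replace
    them by silence — of duration ``T`` in the correct comparison and of
    the altered duration in the other, placed at ``altered_position``.
    All three intervals share one warp schedule for the early region.
    """
    rate = synth.sample_rate
    early, gap_words, final = synth.early(), synth.gap_words(), synth.final()
    for arr, ms, name in (
        (early, template.early_ms, "early"),
        (gap_words, template.gap_ms, "gap_words"),
        (final, template.final_word_ms, "final"),
    ):
        if abs(len(arr) - _ms_to_samples(ms, rate)) > 1:
            raise ValueError(f"synth {name} duration does not match the template")

    mod = condition_modulator(trial.rhythm_condition, trial.modulator_phase, depth)
    schedule = build_frame_schedule(template.early_ms, mod, frame_ms)
    early_warped = warp_waveform(early, rate, schedule)

    def interval(gap_ms: float, audible: bool) -> np.ndarray:
        if audible:
            middle = gap_words
        else:
            middle = np.zeros(_ms_to_samples(gap_ms, rate))
        return np.concatenate([early_warped, middle, final])

    reference = interval(template.gap_ms, audible=True)
    correct = interval(template.gap_ms, audible=False)
    altered = interval(altered_gap_ms(template, trial.direction, trial.delta_frac),
                       audible=False)
    if trial.altered_position == "first":
        return reference, altered, correct
    return reference, correct, altered
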