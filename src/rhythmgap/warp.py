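"""Frame-wise sinusoidal time warping of the early sentence region.

The early portion of the sentence is cut into fixed-length frames
(50 ms by default) and each frame is independently stretched or
compressed by a sinusoidal duration modulator::

    new_duration / original_duration = 1 + m * sin(2*pi*f_m*t + phi)

where ``m`` is the modulation depth (0..1), ``f_m`` the number of whole
modulator cycles spanning the warped region, and ``phi`` the starting
phase.  ``t`` is the normalised position of the frame centre within the
warped region, so one cycle covers the region exactly regardless of its
absolute length.  Because the discrete frame-centre samples of a sine do
not sum exactly to zero for arbitrary phase, a uniform residual
correction is applied so that the warped region keeps exactly the
original total duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Modulator",
    "FrameSchedule",
    "frame_duration_ratio",
    "build_frame_schedule",
    "warp_waveform",
]

#: the eight permitted modulator starting phases, k*pi/4 for k = 0..7
PHASE_SET = tuple(k * math.pi / 4 for k in range(8))


@dataclass(frozen=True)
class Modulator:
    """Sinusoidal duration-modulator parameters.

    Parameters
    ----------
    depth:
        Modulation depth ``m`` in [0, 1].  0 leaves every frame
        untouched; 1 compresses trough frames to zero duration and
        doubles peak frames.
    cycles:
        Number of whole modulator cycles across the warped region
        (1 = low-rate alteration, 3 = high-rate).
    phase:
        Starting phase in radians, in [0, 2*pi).  The experiment draws
        it from :data:`PHASE_SET`.
    """

    depth: float
    cycles: int
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"depth must lie in [0, 1], got {self.depth}")
        if int(self.cycles) != self.cycles or self.cycles < 1:
            raise ValueError(f"cycles must be a positive integer, got {self.cycles}")
        if not 0.0 <= self.phase < 2.0 * math.pi:
            raise ValueError(f"phase must lie in [0, 2*pi), got {self.phase}")


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame target durations for one warped region.

    ``sum(new_durations_ms)`` equals ``n_frames * original_frame_ms`` to
    within 1e-9 ms: duration conservation is enforced at construction.
    """

    original_frame_ms: float
    new_durations_ms: np.ndarray = field(repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.new_durations_ms)

    @property
    def total_ms(self) -> float:
        return float(np.sum(self.new_durations_ms))

    def __post_init__(self) -> None:
        d = np.asarray(self.new_durations_ms, dtype=float)
        object.__setattr__(self, "new_durations_ms", d)
        if np.any(d < 0):
            raise ValueError("frame durations must be non-negative")
        target = self.n_frames * self.original_frame_ms
        if abs(float(d.sum()) - target) > 1e-9:
            raise ValueError(
                f"schedule violates duration conservation: sum {d.sum()} != {target}"
            )


def frame_duration_ratio(mod: Modulator, t_norm: float) -> float:
    """Duration ratio ``1 + m*sin(2*pi*cycles*t_norm + phase)``.

    ``t_norm`` is the normalised position in [0, 1) of the frame centre
    within the warped region.  The result is guaranteed to lie in
    ``[1 - depth, 1 + depth]``.
    """
    if not 0.0 <= t_norm < 1.0:
        raise ValueError(f"t_norm must lie in [0, 1), got {t_norm}")
    ratio = 1.0 + mod.depth * math.sin(2.0 * math.pi * mod.cycles * t_norm + mod.phase)
    # guard against floating-point excursions just outside the band
    return float(min(max(ratio, 1.0 - mod.depth), 1.0 + mod.depth))


def build_frame_schedule(
    region_ms: float, mod: Modulator, frame_ms: float = 50.0
) -> FrameSchedule:
    """Build the per-frame duration schedule for a warped region.

    The region is divided into ``floor(region_ms / frame_ms)`` frames;
    any remainder shorter than one frame is passed through unwarped by
    :func:`warp_waveform` and is not part of the schedule.  Each frame's
    ratio is evaluated at its centre, ``(i + 0.5) / n_frames``.  The
    mean deviation from ``frame_ms`` is then subtracted from every frame
    so the total duration is conserved exactly; should that correction
    drive a frame negative, the frame is clipped to zero and the deficit
    redistributed over the remaining positive frames.
    """
    if frame_ms <= 0:
        raise ValueError("frame_ms must be positive")
    if region_ms < frame_ms:
        raise ValueError(
            f"region ({region_ms} ms) must be at least one frame ({frame_ms} ms) long"
        )
    n = int(math.floor(region_ms / frame_ms + 1e-12))
    centers = (np.arange(n) + 0.5) / n
    ratios = 1.0 + mod.depth * np.sin(2.0 * math.pi * mod.cycles * centers + mod.phase)
    durations = ratios * frame_ms
    # uniform residual correction: exact conservation of the region total
    durations -= durations.mean() - frame_ms
    # clip-and-redistribute, preserving the total
    for _ in range(n):
        negative = durations < 0
        if not negative.any():
            break
        deficit = -durations[negative].sum()
        durations[negative] = 0.0
        positive = durations > 0
        durations[positive] -= deficit / positive.sum()
    # absorb the last floating-point residue in the largest frame
    durations[np.argmax(durations)] += n * frame_ms - durations.sum()
    return FrameSchedule(original_frame_ms=frame_ms, new_durations_ms=durations)


def warp_waveform(
    samples: np.ndarray, sample_rate: float, schedule: FrameSchedule
) -> np.ndarray:
    """Resample each frame of ``samples`` to its scheduled duration.

    Frames are linearly interpolated onto a uniform grid of the target
    length and concatenated; samples beyond the scheduled region are
    passed through unchanged.  Cumulative rounding of frame boundaries
    keeps the output length within one sample of the scheduled total.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty input waveform")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = schedule.n_frames
    frame_ms = schedule.original_frame_ms
    region_samples_needed = int(round(n * frame_ms * sample_rate / 1000.0))
    if samples.size < region_samples_needed:
        raise ValueError(
            f"waveform ({samples.size} samples) shorter than the scheduled "
            f"region ({region_samples_needed} samples)"
        )

    src_edges = np.round(np.arange(n + 1) * frame_ms * sample_rate / 1000.0).astype(int)
    dst_edges = np.round(
        np.concatenate(([0.0], np.cumsum(schedule.new_durations_ms)))
        * sample_rate
        / 1000.0
    ).astype(int)

    pieces = []
    for i in range(n):
        src = samples[src_edges[i] : src_edges[i + 1]]
        out_len = dst_edges[i + 1] - dst_edges[i]
        if out_len == 0:
            continue
        if len(src) == out_len:
            pieces.append(src)
        elif len(src) == 1:
            pieces.append(np.full(out_len, src[0]))
        else:
            x_new = np.linspace(0.0, len(src) - 1.0, out_len)
            pieces.append(np.interp(x_new, np.arange(len(src)), src))
    pieces.append(samples[src_edges[-1] :])
    return np.concatenate(pieces)
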