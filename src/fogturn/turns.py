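"""Completed-turn counting from the lumbar gyroscope yaw channel.

A turn is one complete 360° rotation about the longitudinal axis; partial
rotations do not count.  Because the turning task alternates direction after
each full turn, rotation is accumulated per same-direction segment — a net
integral over the whole trial would cancel.  The yaw rate is low-pass
filtered (zero-phase Butterworth) before integration to suppress step-cycle
oscillation, and a direction reversal is only recognized when the filtered
rate holds the new sign for a dwell time, so brief zero-crossings during
freezing pauses do not fragment a turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid


@dataclass(frozen=True)
class TurnConfig:
    """Filter and reversal-detection knobs.

    lowpass_hz
        Cutoff of the 4th-order zero-phase Butterworth low-pass applied to
        the yaw rate before integration; ``None`` disables filtering (useful
        on clean piecewise-constant profiles).
    reversal_dwell_s
        Minimum time the filtered yaw rate must hold an opposite sign before
        a direction reversal is recognized.
    """

    lowpass_hz: float | None = 1.5
    filter_order: int = 4
    reversal_dwell_s: float = 0.5


@dataclass(frozen=True)
class TurnResult:
    """Completed 360° rotations in a trial."""

    n_complete_turns: int
    turn_boundaries_s: tuple[float, ...]
    residual_deg: float  # unfinished rotation in the final direction segment

    def __post_init__(self):
        assert self.n_complete_turns == len(self.turn_boundaries_s)
        assert 0.0 <= self.residual_deg < 360.0


def _direction_segments(rate: np.ndarray, fs: float, dwell_s: float) -> list[slice]:
    """Split samples into same-direction segments, ignoring brief sign flips.

    A new direction is established only by a run of opposite (nonzero) sign
    lasting at least ``dwell_s``.
    """
    n = rate.size
    sign = np.sign(rate)
    dwell = max(1, int(round(dwell_s * fs)))

    # runs of constant sign
    change = np.flatnonzero(np.diff(sign) != 0) + 1
    run_starts = np.concatenate(([0], change))
    run_ends = np.concatenate((change, [n]))
    run_signs = sign[run_starts]

    # initial direction: first run of nonzero sign lasting >= dwell (fallback:
    # sign of the largest-magnitude net rotation)
    current = 0.0
    for s0, s1, sg in zip(run_starts, run_ends, run_signs):
        if sg != 0 and s1 - s0 >= dwell:
            current = sg
            break
    if current == 0.0:
        current = np.sign(np.trapezoid(rate)) or 1.0

    assigned = np.empty(n)
    for s0, s1, sg in zip(run_starts, run_ends, run_signs):
        if sg != 0 and sg != current and s1 - s0 >= dwell:
            current = sg
        assigned[s0:s1] = current

    boundaries = np.flatnonzero(np.diff(assigned) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    return [slice(int(a), int(b)) for a, b in zip(starts, ends)]


def count_turns(
    yaw_rate_dps: np.ndarray,
    sample_rate_hz: float,
    config: TurnConfig | None = None,
) -> TurnResult:
    """Count completed 360° rotations from a yaw-rate series (deg/s).

    Rotation is the trapezoidal integral of the (filtered) yaw rate within
    each same-direction segment; each crossing of a 360° multiple inside a
    segment counts one turn.  Sign is irrelevant: negating the input yields
    the same count.
    """
    config = config or TurnConfig()
    rate = np.asarray(yaw_rate_dps, dtype=float)
    if rate.size == 0:
        raise ValueError("yaw-rate series is empty")
    if config.lowpass_hz is not None:
        nyq = sample_rate_hz / 2.0
        if not 0 < config.lowpass_hz < nyq:
            raise ValueError(f"lowpass_hz must lie in (0, {nyq}) Hz")
        sos = sps.butter(config.filter_order, config.lowpass_hz, btype="low", fs=sample_rate_hz, output="sos")
        filtered = sps.sosfiltfilt(sos, rate)
    else:
        filtered = rate

    dt = 1.0 / sample_rate_hz
    segments = _direction_segments(filtered, sample_rate_hz, config.reversal_dwell_s)

    n_turns = 0
    boundaries: list[float] = []
    residual = 0.0
    eps = 1e-9  # tolerate float round-off at exact 360° multiples
    for seg in segments:
        cum = np.abs(cumulative_trapezoid(filtered[seg], dx=dt, initial=0.0))
        total = cum[-1]
        k = int(np.floor((total + eps) / 360.0))
        n_turns += k
        t0 = seg.start * dt
        for m in range(1, k + 1):
            idx = int(np.searchsorted(cum, m * 360.0 - eps))
            idx = min(idx, cum.size - 1)
            boundaries.append(t0 + idx * dt)
        residual = total - 360.0 * k
    residual = float(min(max(residual, 0.0), np.nextafter(360.0, 0.0)))
    return TurnResult(
        n_complete_turns=int(n_turns),
        turn_boundaries_s=tuple(boundaries),
        residual_deg=residual,
    )
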