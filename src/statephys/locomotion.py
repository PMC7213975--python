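"""Locomotion-state segmentation of head-fixed wheel-running data.

The wheel angle sensor gives position on a 15-cm wheel; everything
downstream (state-conditioned LFP power, firing-rate modulation) hangs on
the division of the session into locomotion (L) bouts and quiescence (Q).
States are found by nonparametric change-point detection on the speed
trace followed by a 1 cm/s mean-speed labeling rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .changepoint import rank_binseg

Interval = tuple[float, float]

#: Default analysis thresholds (seconds, cm/s).
MIN_QUIESCENCE_S = 20.0
PRE_BOUT_EXCLUSION_S = 10.0
SPEED_THRESHOLD_CM_S = 1.0
MIN_RUN_DURATION_S = 2.0


@dataclass(frozen=True)
class WheelTrace:
    """Raw wheel angle-sensor trace.

    ``angle`` is in radians, wrapped to [0, 2*pi); ``t`` in seconds,
    strictly increasing and uniformly sampled (1 % jitter tolerated).
    """

    t: np.ndarray
    angle: np.ndarray
    wheel_diameter_cm: float = 15.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.angle, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("t and angle must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.ptp(dt) > 0.01 * np.median(dt) + 1e-12:
                raise ValueError("sampling must be uniform within 1% jitter")
        if self.wheel_diameter_cm <= 0:
            raise ValueError("wheel_diameter_cm must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "angle", np.mod(a, 2 * np.pi))


@dataclass(frozen=True)
class VelocityTrace:
    """Signed linear velocity (cm/s); analyses use ``speed`` = |v|."""

    t: np.ndarray
    v: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.abs(self.v)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class StateSegmentation:
    """Alternating locomotion (L) and quiescence (Q) intervals.

    L and Q are disjoint, sorted, and jointly tile the session span.
    """

    bouts: list[Interval]
    quiescent: list[Interval]
    session: Interval

    def __post_init__(self) -> None:
        labeled = sorted(
            [(s, e, "L") for s, e in self.bouts] + [(s, e, "Q") for s, e in self.quiescent]
        )
        if not labeled:
            raise ValueError("segmentation must contain at least one interval")
        t0, t1 = self.session
        if not np.isclose(labeled[0][0], t0) or not np.isclose(labeled[-1][1], t1):
            raise ValueError("intervals do not span the session")
        for (s, e, _), (s2, _, _) in zip(labeled, labeled[1:]):
            if not np.isclose(e, s2):
                raise ValueError("intervals must tile the session without gaps or overlap")
        if any(e <= s for s, e, _ in labeled):
            raise ValueError("zero-length interval")

    def intervals(self) -> list[tuple[str, float, float]]:
        """All intervals in time order as (label, start, end)."""
        out = [("L", s, e) for s, e in self.bouts] + [("Q", s, e) for s, e in self.quiescent]
        return sorted(out, key=lambda r: r[1])


@dataclass(frozen=True)
class LocomotionTrial:
    """One locomotion-onset candidate with its selection metadata."""

    onset_s: float
    offset_s: float
    preceding_quiescence_s: float
    mean_speed_cm_s: float

    @property
    def run_duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def accepted(self) -> bool:
        return (
            self.preceding_quiescence_s > MIN_QUIESCENCE_S
            and self.mean_speed_cm_s > SPEED_THRESHOLD_CM_S
            and self.run_duration_s > MIN_RUN_DURATION_S
        )


@dataclass(frozen=True)
class SegmentationParams:
    min_segment_s: float = 0.5
    penalty_scale: float = 3.0
    speed_threshold_cm_s: float = SPEED_THRESHOLD_CM_S


def angle_to_velocity(wheel: WheelTrace, smoothing_window_s: float = 0.25) -> VelocityTrace:
    """Differentiate the unwrapped wheel arc-length into linear velocity.

    The angle is unwrapped before differentiation so the 2*pi -> 0 sensor
    wrap produces no velocity transient, converted to arc length with the
    wheel radius, differentiated with a central difference and smoothed
    with a boxcar of ``smoothing_window_s``.
    """
    if wheel.t.size < 2:
        raise ValueError("need at least two samples to differentiate")
    arc = np.unwrap(wheel.angle) * (wheel.wheel_diameter_cm / 2.0)
    v = np.gradient(arc, wheel.t)
    if smoothing_window_s > 0:
        dt = float(np.median(np.diff(wheel.t)))
        w = max(1, int(round(smoothing_window_s / dt)))
        if w > 1:
            v = uniform_filter1d(v, size=w, mode="nearest")
    return VelocityTrace(t=wheel.t, v=v)


def segment_states(
    v: VelocityTrace, params: SegmentationParams | None = None
) -> StateSegmentation:
    """Partition the session into L/Q states.

    Change points are detected on the rank-transformed speed trace
    (distributional shifts, no Gaussian assumption); each segment is
    labeled L when its mean speed exceeds the threshold, and adjacent
    same-label segments are merged.
    """
    params = params or SegmentationParams()
    t, speed = v.t, v.speed
    if t.size == 0:
        raise ValueError("empty velocity trace")
    if not np.all(np.isfinite(speed)):
        raise ValueError("velocity contains non-finite values")
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    min_size = max(2, int(round(params.min_segment_s / dt))) if dt > 0 else 2
    breaks = rank_binseg(speed, min_size=min_size, penalty_scale=params.penalty_scale)

    bounds = [0, *breaks, t.size]
    segments: list[tuple[str, float, float]] = []
    for a, b in zip(bounds, bounds[1:]):
        label = "L" if speed[a:b].mean() >= params.speed_threshold_cm_s else "Q"
        start = float(t[a])
        end = float(t[b]) if b < t.size else float(t[-1])
        if segments and segments[-1][0] == label:
            segments[-1] = (label, segments[-1][1], end)
        else:
            segments.append((label, start, end))
    bouts = [(s, e) for lab, s, e in segments if lab == "L"]
    quiet = [(s, e) for lab, s, e in segments if lab == "Q"]
    return StateSegmentation(bouts=bouts, quiescent=quiet, session=(float(t[0]), float(t[-1])))


def select_quiescent_epochs(
    seg: StateSegmentation,
    purpose: str,
    min_quiescence_s: float = MIN_QUIESCENCE_S,
    pre_bout_exclusion_s: float = PRE_BOUT_EXCLUSION_S,
    stationarity: str = "trim",
) -> list[Interval]:
    """Quiescent intervals eligible for analysis.

    purpose="firing": Q intervals lasting longer than ``min_quiescence_s``,
    returned whole.

    purpose="lfp": additionally excludes data within
    ``pre_bout_exclusion_s`` of the next locomotion onset. Two readings of
    the stationarity requirement are available: ``stationarity="trim"``
    (default) treats usable data as starting ``min_quiescence_s`` after
    quiescence onset; ``stationarity="duration"`` merely requires the Q
    interval to last longer than ``min_quiescence_s`` and uses it from its
    onset. Intervals emptied by trimming are dropped.
    """
    if purpose not in ("firing", "lfp"):
        raise ValueError(f"unknown purpose {purpose!r}")
    if stationarity not in ("trim", "duration"):
        raise ValueError(f"unknown stationarity convention {stationarity!r}")
    onsets = np.array([s for s, _ in seg.bouts])
    out: list[Interval] = []
    for s, e in seg.quiescent:
        if e - s <= min_quiescence_s:
            continue
        if purpose == "firing":
            out.append((s, e))
            continue
        start = s + min_quiescence_s if stationarity == "trim" else s
        later = onsets[onsets >= e - 1e-9]
        end = min(e, float(later[0]) - pre_bout_exclusion_s) if later.size else e
        if end > start:
            out.append((start, end))
    return out


def select_locomotion_trials(
    seg: StateSegmentation, v: VelocityTrace
) -> list[LocomotionTrial]:
    """One candidate trial per bout, flagged by the selection rule.

    A trial is accepted when its preceding quiescent period lasted longer
    than 20 s, mean speed from onset to the locomotion offset exceeded
    1 cm/s, and the run lasted longer than 2 s.
    """
    quiet = sorted(seg.quiescent)
    trials = []
    for onset, offset in sorted(seg.bouts):
        prec = 0.0
        for qs, qe in quiet:
            if np.isclose(qe, onset):
                prec = qe - qs
                break
        sel = (v.t >= onset) & (v.t < offset)
        mean_speed = float(v.speed[sel].mean()) if sel.any() else 0.0
        trials.append(
            LocomotionTrial(
                onset_s=onset,
                offset_s=offset,
                preceding_quiescence_s=prec,
                mean_speed_cm_s=mean_speed,
            )
        )
    return trials
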