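"""Single-unit metrics: rates, sorting quality, class labels, modulation.

Quality control mirrors standard tetrode practice: a unit is accepted when
its isolation distance exceeds 20 and no more than 0.1 % of inter-spike
intervals violate a 1.5 ms refractory period. Accepted units are labeled
regular-spiking (RS, putative pyramidal) or fast-spiking (FS, putative
interneuron) by waveform trough-to-peak width. State-dependent modulation
compares firing in the [-0.5, 0.5] s window around locomotion onset with
the [-5, -2] s quiescent window before it, via the bounded index
(FR_L - FR_Q) / (FR_L + FR_Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locomotion import LocomotionTrial

__all__ = [
    "SpikeTrain",
    "Waveform",
    "FeatureCloud",
    "UnitQC",
    "ModulationResult",
    "firing_rate",
    "isi_contamination",
    "isolation_distance",
    "classify_unit",
    "locomotion_modulation",
]

ID_THRESHOLD = 20.0
ISI_CONTAMINATION_MAX = 0.001
REFRACTORY_S = 0.0015
RS_BOUNDARY_MS = 0.4  # conventional cortical trough-to-peak split

ONSET_WINDOW_S = (-0.5, 0.5)
QUIESCENT_WINDOW_S = (-5.0, -2.0)


@dataclass(frozen=True)
class Waveform:
    """Mean spike waveform (arbitrary units) and its sampling rate."""

    samples: np.ndarray
    fs: float

    def trough_to_peak_ms(self) -> float:
        """Time from waveform trough to the subsequent peak, in ms."""
        x = np.asarray(self.samples, dtype=float)
        i_trough = int(np.argmin(x))
        after = x[i_trough:]
        if after.size < 2:
            raise ValueError("waveform trough at final sample; width undefined")
        i_peak = i_trough + int(np.argmax(after))
        return (i_peak - i_trough) / self.fs * 1000.0


@dataclass(frozen=True)
class SpikeTrain:
    unit_id: str
    spike_times: np.ndarray
    waveform: Waveform | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(t) < 0):
            raise ValueError("spike_times must be sorted ascending")
        object.__setattr__(self, "spike_times", t)

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass(frozen=True)
class FeatureCloud:
    """Points in spike-sorting feature space: one unit's cluster vs noise."""

    cluster_points: np.ndarray
    noise_points: np.ndarray

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.cluster_points, dtype=float))
        z = np.asarray(self.noise_points, dtype=float)
        z = z.reshape(0, c.shape[1]) if z.size == 0 else np.atleast_2d(z)
        if c.shape[1] != z.shape[1]:
            raise ValueError("cluster and noise dimensionality differ")
        object.__setattr__(self, "cluster_points", c)
        object.__setattr__(self, "noise_points", z)


@dataclass(frozen=True)
class UnitQC:
    isolation_distance: float  # np.inf if no noise constrains it; NaN undefined
    isi_contamination: float  # NaN when < 2 spikes

    @property
    def accepted(self) -> bool:
        ok_id = not np.isnan(self.isolation_distance) and self.isolation_distance > ID_THRESHOLD
        ok_isi = (
            not np.isnan(self.isi_contamination)
            and self.isi_contamination <= ISI_CONTAMINATION_MAX
        )
        return ok_id and ok_isi


@dataclass(frozen=True)
class ModulationResult:
    fr_l: float
    fr_q: float
    n_trials: int

    @property
    def index(self) -> float:
        """(FR_L - FR_Q)/(FR_L + FR_Q); NaN when both rates are zero."""
        denom = self.fr_l + self.fr_q
        if denom == 0:
            return float("nan")
        return (self.fr_l - self.fr_q) / denom


def firing_rate(train: SpikeTrain, intervals: list[tuple[float, float]]) -> float:
    """Spike count within the (half-open) intervals over their total duration."""
    duration = float(sum(e - s for s, e in intervals))
    if duration <= 0:
        raise ValueError("total interval duration must be positive")
    t = train.spike_times
    count = sum(
        int(np.searchsorted(t, e, "left") - np.searchsorted(t, s, "left"))
        for s, e in intervals
    )
    return count / duration


def isi_contamination(train: SpikeTrain, refractory_s: float = REFRACTORY_S) -> float:
    """Fraction of inter-spike intervals shorter than the refractory period.

    Undefined (NaN) for trains with fewer than two spikes.
    """
    if train.n_spikes < 2:
        return float("nan")
    isi = np.diff(train.spike_times)
    return float(np.count_nonzero(isi < refractory_s) / isi.size)


def isolation_distance(cloud: FeatureCloud) -> float:
    """Squared Mahalanobis distance of the n-th closest noise point.

    n is the cluster size and the metric is defined by the cluster's own
    mean and covariance. Returns ``inf`` when fewer than n noise points
    exist (nothing constrains the isolation).
    """
    c, z = cloud.cluster_points, cloud.noise_points
    n, d = c.shape
    if n < d + 1:
        raise ValueError(f"need at least dim+1={d + 1} cluster points, got {n}")
    if z.shape[0] < n:
        return float("inf")
    mu = c.mean(axis=0)
    cov = np.cov(c, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < d:
        raise ValueError("singular cluster covariance; isolation distance undefined")
    delta = z - mu
    d2 = np.einsum("ij,ij->i", delta, np.linalg.solve(cov, delta.T).T)
    return float(np.sort(d2)[n - 1])


def classify_unit(train: SpikeTrain, qc: UnitQC, rs_boundary_ms: float = RS_BOUNDARY_MS) -> str:
    """Label a unit 'RS', 'FS', 'rejected', or 'unclassified'.

    Rejected unless QC passes; otherwise RS when the waveform trough-to-peak
    width exceeds ``rs_boundary_ms``, FS when narrower, and 'unclassified'
    when no waveform is available.
    """
    if not qc.accepted:
        return "rejected"
    if train.waveform is None:
        return "unclassified"
    return "RS" if train.waveform.trough_to_peak_ms() > rs_boundary_ms else "FS"


def locomotion_modulation(
    train: SpikeTrain,
    trials: list[LocomotionTrial],
    session_start_s: float = 0.0,
    onset_window_s: tuple[float, float] = ONSET_WINDOW_S,
    quiescent_window_s: tuple[float, float] = QUIESCENT_WINDOW_S,
    per_trial_mean: bool = False,
) -> ModulationResult:
    """Locomotion-onset modulation of one unit over accepted trials.

    FR_L and FR_Q pool spike counts and window durations across accepted
    trials (set ``per_trial_mean`` for the mean of per-trial rates
    instead). Trials whose quiescent window would start before the session
    are excluded.
    """
    usable = [
        tr
        for tr in trials
        if tr.accepted and tr.onset_s + quiescent_window_s[0] >= session_start_s
    ]
    if not usable:
        raise ValueError("no accepted trials with an in-session quiescent window")
    rates = []
    for win in (onset_window_s, quiescent_window_s):
        ivals = [(tr.onset_s + win[0], tr.onset_s + win[1]) for tr in usable]
        if per_trial_mean:
            rates.append(float(np.mean([firing_rate(train, [iv]) for iv in ivals])))
        else:
            rates.append(firing_rate(train, ivals))
    return ModulationResult(fr_l=rates[0], fr_q=rates[1], n_trials=len(usable))
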