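"""Synthetic wheel, LFP and spike-train sessions with known ground truth.

The generators emulate the recordings the pipeline consumes: locomotion
bouts on a 15-cm wheel read out by an angle sensor, an LFP whose band
amplitudes are state-modulated, inhomogeneous-Poisson spike trains whose
rates differ between quiescence and locomotion (optionally phase-locked
to an LFP band via von-Mises thinning), and labeled feature-space clouds
for sorting-QC tests. Every planted quantity is returned alongside the
data so tests can check recovery; the analysis pipeline never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.special import i0

from ..locomotion import WheelTrace
from ..spectral import LFPSignal
from ..units import FeatureCloud, SpikeTrain, Waveform

__all__ = [
    "BandComponent",
    "GroundTruthSession",
    "gen_wheel_trace",
    "random_bout_spec",
    "gen_state_lfp",
    "gen_state_spikes",
    "gen_feature_clouds",
    "gen_session",
]

RAMP_S = 0.5  # trapezoidal bout velocity rise/fall
WHEEL_FS_HZ = 100.0
LFP_FS_HZ = 1000.0


@dataclass(frozen=True)
class BandComponent:
    """One band-limited LFP component: flat spectrum on [f_lo, f_hi] with
    the given RMS amplitude (microvolts) during quiescence."""

    name: str
    f_lo: float
    f_hi: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError("need 0 <= f_lo < f_hi")
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class GroundTruthSession:
    """One synthetic recording session plus its planted truth."""

    wheel: WheelTrace
    true_bouts: list[tuple[float, float]]
    lfp: LFPSignal
    true_band_gain: dict[str, float]
    spikes: list[SpikeTrain]
    true_rate_q: dict[str, float]
    true_rate_l: dict[str, float]
    locking: tuple[float, float] | None
    seed: int
    duration_s: float


def _validate_bouts(
    bout_spec: list[tuple[float, float, float]] | list[tuple[float, float]],
    duration_s: float,
) -> None:
    prev_end = -np.inf
    for b in sorted(bout_spec):
        on, off = b[0], b[1]
        if not (0 <= on < off <= duration_s):
            raise ValueError(f"bout ({on}, {off}) outside [0, {duration_s}]")
        if on < prev_end:
            raise ValueError(f"overlapping bouts at t={on:.2f} s")
        prev_end = off
        if len(b) > 2 and b[2] < 0:
            raise ValueError("bout speeds must be non-negative")


def _bout_velocity_profile(
    t: np.ndarray, bout_spec: list[tuple[float, float, float]]
) -> np.ndarray:
    """Trapezoidal speed profile: RAMP_S rise/fall inside each bout."""
    v = np.zeros_like(t)
    for on, off, speed in bout_spec:
        ramp = min(RAMP_S, (off - on) / 2.0)
        sel = (t >= on) & (t < off)
        tt = t[sel]
        prof = np.full(tt.size, speed)
        if ramp > 0:
            prof = np.minimum(prof, speed * (tt - on) / ramp)
            prof = np.minimum(prof, speed * (off - tt) / ramp)
        v[sel] = prof
    return v


def gen_wheel_trace(
    duration_s: float,
    bout_spec: list[tuple[float, float, float]],
    noise_sd_cm_s: float = 0.3,
    sample_rate_hz: float = WHEEL_FS_HZ,
    seed: int = 0,
    wheel_diameter_cm: float = 15.0,
) -> tuple[WheelTrace, list[tuple[float, float]]]:
    """Simulate the angle-sensor trace for a set of running bouts.

    ``bout_spec`` is a list of (onset_s, offset_s, speed_cm_s); the speed
    profile is trapezoidal so onsets are well defined. White velocity
    noise of ``noise_sd_cm_s`` is added before integration to angle.
    """
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("duration and sample rate must be positive")
    _validate_bouts(bout_spec, duration_s)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    v = _bout_velocity_profile(t, sorted(bout_spec))
    if noise_sd_cm_s > 0:
        v = v + rng.normal(0.0, noise_sd_cm_s, size=n)
    arc = np.concatenate(([0.0], np.cumsum(v[:-1]))) / sample_rate_hz
    angle = np.mod(arc / (wheel_diameter_cm / 2.0), 2.0 * np.pi)
    wheel = WheelTrace(t=t, angle=angle, wheel_diameter_cm=wheel_diameter_cm)
    return wheel, [(on, off) for on, off, _ in sorted(bout_spec)]


def random_bout_spec(
    duration_s: float,
    n_bouts: int,
    seed: int = 0,
    min_gap_s: float = 25.0,
    bout_dur_range_s: tuple[float, float] = (3.0, 8.0),
    speed_range_cm_s: tuple[float, float] = (4.0, 10.0),
) -> list[tuple[float, float, float]]:
    """Random non-overlapping bouts separated by quiescent gaps.

    Gaps are at least ``min_gap_s`` (default 25 s, comfortably above the
    20-s trial-selection rule) with the remaining slack spread randomly.
    """
    rng = np.random.default_rng(seed)
    durs = rng.uniform(*bout_dur_range_s, size=n_bouts)
    speeds = rng.uniform(*speed_range_cm_s, size=n_bouts)
    slack = duration_s - durs.sum() - min_gap_s * (n_bouts + 1)
    if slack < 0:
        raise ValueError("duration too short for requested bouts and gaps")
    extra = rng.dirichlet(np.ones(n_bouts + 1)) * slack
    spec, t = [], 0.0
    for i in range(n_bouts):
        t += min_gap_s + extra[i]
        spec.append((t, t + durs[i], speeds[i]))
        t += durs[i]
    return spec


def _state_mask(
    t: np.ndarray, bouts: list[tuple[float, float]], lead_s: float = 0.0
) -> np.ndarray:
    m = np.zeros(t.size, dtype=bool)
    for on, off in bouts:
        m |= (t >= on - lead_s) & (t < off)
    return m


def _band_noise(rng: np.random.Generator, n: int, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [f_lo, f_hi]."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freq = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freq < f_lo) | (freq > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_state_lfp(
    duration_s: float,
    fs_hz: float,
    band_components: list[BandComponent],
    band_gain_l: dict[str, float],
    true_bouts: list[tuple[float, float]],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> LFPSignal:
    """Sum of band-limited components whose amplitude is state-modulated.

    During locomotion bouts each component's amplitude is multiplied by
    ``band_gain_l[name]`` (default 1). Broadband white noise of SD
    ``noise_sd`` is added and the mean removed.
    """
    for c in band_components:
        if c.f_hi >= fs_hz / 2.0:
            raise ValueError(f"band {c.name} exceeds the Nyquist frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    in_l = _state_mask(t, true_bouts)
    x = np.zeros(n)
    for c in band_components:
        comp = _band_noise(rng, n, fs_hz, c.f_lo, c.f_hi) * c.amplitude_uv
        gain = band_gain_l.get(c.name, 1.0)
        comp = np.where(in_l, comp * gain, comp)
        x += comp
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    x -= x.mean()
    return LFPSignal(fs=fs_hz, samples=x, t0=0.0)


def band_phase(lfp: LFPSignal, freq_hz: float, half_bw_hz: float = 2.0) -> np.ndarray:
    """Instantaneous phase of the LFP narrowband-filtered around freq_hz."""
    spec = np.fft.rfft(lfp.samples)
    f = np.fft.rfftfreq(lfp.samples.size, d=1.0 / lfp.fs)
    spec[(f < freq_hz - half_bw_hz) | (f > freq_hz + half_bw_hz)] = 0.0
    narrow = np.fft.irfft(spec, n=lfp.samples.size)
    return np.angle(hilbert(narrow))


def gen_state_spikes(
    rate_q_hz: float,
    rate_l_hz: float,
    true_bouts: list[tuple[float, float]],
    duration_s: float,
    locking: tuple[float, float] | None = None,
    lfp: LFPSignal | None = None,
    seed: int = 0,
    unit_id: str = "u0",
    waveform: Waveform | None = None,
    rate_lead_s: float = 0.5,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train with state-dependent rate.

    The rate is ``rate_q_hz`` in quiescence and ``rate_l_hz`` inside
    bouts, so the expected count is rate_Q*T_Q + rate_L*T_L (with T_L
    extended by ``rate_lead_s`` per bout). The rate transition leads each
    locomotion onset by ``rate_lead_s`` — the anticipatory modulation
    seen in awake cortex — so the locomotion-rate state fully covers a
    +/-0.5 s onset-centered analysis window. With
    ``locking=(freq_hz, kappa)`` the train is thinned with a von-Mises
    acceptance on the instantaneous phase of the LFP at that frequency;
    the candidate rate is inflated by e^kappa / I0(kappa) so the thinning
    leaves the expected rate unchanged (phases uniform in the long run).
    """
    if rate_q_hz < 0 or rate_l_hz < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    max_rate = max(rate_q_hz, rate_l_hz)
    if max_rate == 0:
        return SpikeTrain(unit_id=unit_id, spike_times=np.empty(0), waveform=waveform)

    kappa = 0.0
    phase = None
    if locking is not None:
        freq, kappa = locking
        if kappa < 0:
            raise ValueError("locking concentration must be non-negative")
        if kappa > 0:
            if lfp is None:
                raise ValueError("phase locking requires an LFP")
            phase = band_phase(lfp, freq)

    lam_max = max_rate * (np.exp(kappa) / i0(kappa) if kappa > 0 else 1.0)
    n_cand = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
    rate = np.where(_state_mask(cand, true_bouts, lead_s=rate_lead_s), rate_l_hz, rate_q_hz)
    accept_p = rate / lam_max
    if kappa > 0 and phase is not None:
        ph = np.interp(cand, np.arange(phase.size) / lfp.fs + lfp.t0, phase)
        accept_p = accept_p * np.exp(kappa * np.cos(ph)) / i0(kappa)
    times = cand[rng.uniform(size=n_cand) < accept_p]
    return SpikeTrain(unit_id=unit_id, spike_times=times, waveform=waveform)


def gen_feature_clouds(
    n_cluster: int,
    n_noise: int,
    dim: int,
    separation: float,
    seed: int = 0,
) -> FeatureCloud:
    """Gaussian cluster at the origin and noise offset by ``separation``.

    Both clouds have identity covariance; the noise mean sits at distance
    ``separation`` along a random direction, so isolation distance grows
    with separation in a controlled way.
    """
    if n_cluster <= dim:
        raise ValueError("n_cluster must exceed the feature dimension")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(dim)
    direction /= np.linalg.norm(direction)
    cluster = rng.standard_normal((n_cluster, dim))
    noise = rng.standard_normal((n_noise, dim)) + separation * direction
    return FeatureCloud(cluster_points=cluster, noise_points=noise)


def _default_waveform(width_ms: float, fs: float = 40000.0) -> Waveform:
    """Stylized extracellular spike: trough then a peak ``width_ms`` later."""
    n_pre = int(round(0.3e-3 * fs))
    n_gap = max(1, int(round(width_ms * 1e-3 * fs)))
    n_post = int(round(0.4e-3 * fs))
    x = np.zeros(n_pre + n_gap + n_post + 1)
    x[n_pre] = -1.0
    x[n_pre + n_gap] = 0.6
    return Waveform(samples=x, fs=fs)


def gen_session(
    duration_s: float = 300.0,
    n_bouts: int = 8,
    n_units: int = 4,
    rate_q_hz: float = 5.0,
    rate_l_hz: float = 10.0,
    gamma_gain: float = 1.0,
    gamma_amplitude_uv: float = 2.0,
    theta_amplitude_uv: float = 3.0,
    lfp_fs_hz: float = LFP_FS_HZ,
    wheel_fs_hz: float = WHEEL_FS_HZ,
    noise_sd_cm_s: float = 0.3,
    lfp_noise_sd: float = 0.5,
    locking: tuple[float, float] | None = None,
    rs_width_ms: float = 0.7,
    seed: int = 0,
) -> GroundTruthSession:
    """One full synthetic session: wheel, state-modulated LFP, spike trains.

    The LFP carries a low-frequency (3-6 Hz) and a gamma (40-55 Hz)
    component; ``gamma_gain`` multiplies the gamma amplitude in *both*
    states (a group-level effect), while the within-session locomotion
    gain of the low band is mildly < 1 as in awake recordings.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3 + n_units)
    bout_spec = random_bout_spec(duration_s, n_bouts, seed=int(sub[0]))
    wheel, bouts = gen_wheel_trace(
        duration_s, bout_spec, noise_sd_cm_s=noise_sd_cm_s,
        sample_rate_hz=wheel_fs_hz, seed=int(sub[1]),
    )
    components = [
        BandComponent("low", 3.0, 6.0, theta_amplitude_uv),
        BandComponent("gamma", 40.0, 55.0, gamma_amplitude_uv * gamma_gain),
    ]
    band_gain_l = {"low": 0.7, "gamma": 1.0}
    lfp = gen_state_lfp(
        duration_s, lfp_fs_hz, components, band_gain_l, bouts,
        noise_sd=lfp_noise_sd, seed=int(sub[2]),
    )
    spikes, rq, rl = [], {}, {}
    for i in range(n_units):
        uid = f"u{i}"
        train = gen_state_spikes(
            rate_q_hz, rate_l_hz, bouts, duration_s, locking=locking, lfp=lfp,
            seed=int(sub[3 + i]), unit_id=uid, waveform=_default_waveform(rs_width_ms),
        )
        spikes.append(train)
        rq[uid], rl[uid] = rate_q_hz, rate_l_hz
    return GroundTruthSession(
        wheel=wheel,
        true_bouts=bouts,
        lfp=lfp,
        true_band_gain={"gamma": gamma_gain},
        spikes=spikes,
        true_rate_q=rq,
        true_rate_l=rl,
        locking=locking,
        seed=seed,
        duration_s=duration_s,
    )
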