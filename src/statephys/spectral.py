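"""State-conditioned LFP spectral analysis.

Power spectra are averaged modified periodograms (Hann-tapered windows,
50 % overlap) computed only from windows lying wholly inside the supplied
quiescent epochs, so bout-contaminated data never enter the estimate.
Band quantification is the relative power: the trapezoidal integral of the
spectrum over a band divided by the integral over the full analysis range
(0.5-100 Hz by default). Spike-field coherence uses the same windowing on
the LFP and the spike train binned at the LFP rate, with a small-sample
bias correction so independent processes converge to zero coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "LFPSignal",
    "PowerSpectrum",
    "BandPower",
    "CoherenceSpectrum",
    "SpectralParams",
    "InsufficientQuiescenceError",
    "compute_psd",
    "relative_band_power",
    "spike_field_coherence",
    "decimate_lfp",
]

#: Frequency range (Hz) over which "total power" is defined for
#: normalization and relative band power; excludes DC drift, covers both
#: reported bands (3-6 Hz and 40-55 Hz).
ANALYSIS_RANGE_HZ = (0.5, 100.0)

THETA_BAND_HZ = (3.0, 6.0)
GAMMA_BAND_HZ = (40.0, 55.0)


class InsufficientQuiescenceError(ValueError):
    """No complete analysis window fits inside the supplied epochs."""


@dataclass(frozen=True)
class LFPSignal:
    """Single-channel LFP: sample values (microvolts) at rate ``fs``."""

    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        x = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("LFP samples must be finite")
        object.__setattr__(self, "samples", x)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class PowerSpectrum:
    freq: np.ndarray
    power: np.ndarray
    normalized: bool
    n_segments: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("freq must be ascending")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def normalize(self, analysis_range: tuple[float, float] = ANALYSIS_RANGE_HZ) -> "PowerSpectrum":
        """Rescale so the spectrum integrates to 1 over the analysis range."""
        total = _band_integral(self.freq, self.power, *analysis_range)
        if total <= 0:
            raise ValueError("cannot normalize a zero spectrum")
        return replace(self, power=self.power / total, normalized=True)


@dataclass(frozen=True)
class BandPower:
    band: tuple[float, float]
    relative_power: float

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise ValueError("band must satisfy f_lo < f_hi")
        if not 0.0 <= self.relative_power <= 1.0 + 1e-9:
            raise ValueError("relative power must lie in [0, 1]")


@dataclass(frozen=True)
class CoherenceSpectrum:
    freq: np.ndarray
    coherence: np.ndarray
    n_spikes: int
    n_segments: int
    low_spike_count: bool = False


@dataclass(frozen=True)
class SpectralParams:
    window_s: float = 2.0
    overlap: float = 0.5
    analysis_range_hz: tuple[float, float] = ANALYSIS_RANGE_HZ
    min_spikes: int = 50


def _window_starts(
    lfp: LFPSignal, epochs: list[tuple[float, float]], nper: int, step: int
) -> list[int]:
    starts: list[int] = []
    n = lfp.samples.size
    for s, e in epochs:
        i0 = int(np.ceil((s - lfp.t0) * lfp.fs - 1e-9))
        i1 = int(np.floor((e - lfp.t0) * lfp.fs + 1e-9))
        i0, i1 = max(i0, 0), min(i1, n)
        k = i0
        while k + nper <= i1:
            starts.append(k)
            k += step
    return starts


def _windowed_ffts(
    x: np.ndarray, starts: list[int], taper: np.ndarray
) -> np.ndarray:
    """Complex rFFTs of mean-removed, tapered windows; shape (k, nfreq)."""
    nper = taper.size
    segs = np.stack([x[s : s + nper] for s in starts])
    segs = segs - segs.mean(axis=1, keepdims=True)
    return np.fft.rfft(segs * taper, axis=1)


def _psd_scale(fs: float, taper: np.ndarray, nfreq: int, nper: int) -> np.ndarray:
    # density scaling so that sum(psd) * df == signal variance (Parseval)
    scale = np.full(nfreq, 2.0 / (fs * np.sum(taper**2)))
    scale[0] /= 2.0
    if nper % 2 == 0:
        scale[-1] /= 2.0
    return scale


def compute_psd(
    lfp: LFPSignal,
    epochs: list[tuple[float, float]],
    params: SpectralParams | None = None,
) -> PowerSpectrum:
    """Averaged modified-periodogram PSD over epoch-interior windows.

    Raises :class:`InsufficientQuiescenceError` when no complete window
    fits inside the epochs.
    """
    params = params or SpectralParams()
    nper = int(round(params.window_s * lfp.fs))
    step = max(1, int(round(nper * (1.0 - params.overlap))))
    starts = _window_starts(lfp, epochs, nper, step)
    if not starts:
        raise InsufficientQuiescenceError(
            f"insufficient quiescence: no complete {params.window_s} s window fits in epochs"
        )
    taper = sps.get_window("hann", nper)
    ffts = _windowed_ffts(lfp.samples, starts, taper)
    freq = np.fft.rfftfreq(nper, d=1.0 / lfp.fs)
    psd = (np.abs(ffts) ** 2).mean(axis=0) * _psd_scale(lfp.fs, taper, freq.size, nper)
    return PowerSpectrum(freq=freq, power=psd, normalized=False, n_segments=len(starts))


def _band_integral(freq: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the spectrum over [lo, hi], interpolating at
    the band edges so the result is exact for piecewise-linear spectra."""
    if lo < freq[0] - 1e-9 or hi > freq[-1] + 1e-9:
        raise ValueError(f"band ({lo}, {hi}) outside spectrum range")
    grid = np.unique(np.concatenate((freq[(freq > lo) & (freq < hi)], [lo, hi])))
    vals = np.interp(grid, freq, power)
    return float(np.trapezoid(vals, grid))


def relative_band_power(
    ps: PowerSpectrum,
    band: tuple[float, float],
    analysis_range: tuple[float, float] = ANALYSIS_RANGE_HZ,
) -> BandPower:
    """Power in ``band`` as a fraction of total power in the analysis range."""
    lo, hi = band
    if lo < analysis_range[0] or hi > analysis_range[1]:
        raise ValueError(f"band {band} outside analysis range {analysis_range}")
    total = _band_integral(ps.freq, ps.power, *analysis_range)
    if total <= 0:
        raise ValueError("total power in analysis range is zero")
    frac = _band_integral(ps.freq, ps.power, lo, hi) / total
    return BandPower(band=band, relative_power=min(frac, 1.0))


def spike_field_coherence(
    spike_times: np.ndarray,
    lfp: LFPSignal,
    epochs: list[tuple[float, float]],
    params: SpectralParams | None = None,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence between a spike train and the LFP.

    The train is binned at the LFP sampling rate and the cross- and
    auto-spectra are averaged over the same epoch-interior windows as
    :func:`compute_psd`. The raw estimate is debiased as
    ``(C - 1/K) / (1 - 1/K)`` (K = number of windows), which keeps perfect
    locking at 1 and drives independent processes to 0 in expectation;
    results are clipped to [0, 1]. Trains with fewer than
    ``params.min_spikes`` spikes inside the epochs are returned flagged,
    not silently NaN.
    """
    params = params or SpectralParams()
    spike_times = np.asarray(spike_times, dtype=float)
    nper = int(round(params.window_s * lfp.fs))
    step = max(1, int(round(nper * (1.0 - params.overlap))))
    starts = _window_starts(lfp, epochs, nper, step)
    if not starts:
        raise InsufficientQuiescenceError("no complete window fits in epochs")

    idx = np.floor((spike_times - lfp.t0) * lfp.fs).astype(int)
    idx = idx[(idx >= 0) & (idx < lfp.samples.size)]
    binned = np.bincount(idx, minlength=lfp.samples.size).astype(float)
    n_spikes = int(
        sum(
            np.count_nonzero((spike_times >= s) & (spike_times < e))
            for s, e in epochs
        )
    )

    taper = sps.get_window("hann", nper)
    fx = _windowed_ffts(lfp.samples, starts, taper)
    fy = _windowed_ffts(binned, starts, taper)
    sxx = (np.abs(fx) ** 2).mean(axis=0)
    syy = (np.abs(fy) ** 2).mean(axis=0)
    sxy = (fx * np.conj(fy)).mean(axis=0)
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) ** 2 / denom, 0.0)
    k = len(starts)
    if k > 1:
        coh = (coh - 1.0 / k) / (1.0 - 1.0 / k)
    coh = np.clip(coh, 0.0, 1.0)
    freq = np.fft.rfftfreq(nper, d=1.0 / lfp.fs)
    return CoherenceSpectrum(
        freq=freq,
        coherence=coh,
        n_spikes=n_spikes,
        n_segments=k,
        low_spike_count=n_spikes < params.min_spikes,
    )


def decimate_lfp(lfp: LFPSignal, target_fs: float = 1000.0) -> LFPSignal:
    """Anti-alias filter and downsample to ``target_fs`` (integer factor)."""
    if target_fs >= lfp.fs:
        return lfp
    q = lfp.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError("fs must be an integer multiple of target_fs")
    out = sps.decimate(lfp.samples, int(round(q)), ftype="fir", zero_phase=True)
    return LFPSignal(fs=target_fs, samples=out, t0=lfp.t0)
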