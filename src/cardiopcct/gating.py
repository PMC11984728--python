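"""Retrospective intrinsic cardiac gating.

Recovers the cardiac phase of each exposure from the projection data itself:
a per-exposure scalar surrogate -- the total log-attenuation of the exposure,
i.e. the summed Beer-Lambert line integrals, which for parallel rays tracks
the instantaneous attenuating mass of the beating heart and is insensitive
to gantry angle -- is band-pass filtered around the expected heart rates.
Its dominant spectral peak gives the heart rate; after a second, narrow
band-pass around that rate, its peaks act as R-wave analogues (the surrogate
is maximal at end-diastole, when the iodinated blood volume peaks) that sort
exposures into ``n_phases`` bins across each R-R interval.

The surrogate choice sits entirely behind :class:`GatingSignal`; anything
that produces a cardiac-frequency trace with one peak per beat can replace
it.  The default band of 5-12 Hz (300-720 beats/min) brackets anaesthetised
mouse heart rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .phantom import ProjectionStream

__all__ = [
    "GatingSignal",
    "PhaseAssignment",
    "extract_intrinsic_signal",
    "assign_phases",
]

DEFAULT_BAND_HZ = (5.0, 12.0)


@dataclass
class GatingSignal:
    """Band-passed intrinsic-motion surrogate, one sample per exposure."""

    values: np.ndarray
    timestamps: np.ndarray  # s
    band: tuple  # (low, high) Hz
    estimated_HR: float  # beats/min
    nonstationary: bool = False

    def __post_init__(self):
        if len(self.values) != len(self.timestamps):
            raise ValueError("signal and timestamps must have equal length")
        if self.estimated_HR <= 0:
            raise ValueError("estimated_HR must be > 0")


@dataclass
class PhaseAssignment:
    """Phase-bin index per retained exposure; dropped exposures listed separately."""

    phase_index: np.ndarray  # -1 for dropped exposures
    n_phases: int
    dropped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def kept(self) -> np.ndarray:
        return np.nonzero(self.phase_index >= 0)[0]

    def exposures_in_phase(self, phase: int) -> np.ndarray:
        return np.nonzero(self.phase_index == phase)[0]


def _bandpass(x: np.ndarray, fs: float, band: tuple) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyq:g}) Hz")
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, x)


def _spectral_peak_hz(x: np.ndarray, fs: float, band: tuple) -> tuple[float, float, float]:
    """(peak frequency, peak power, median off-band power) of the periodogram."""
    f, p = sps.periodogram(x, fs=fs, detrend="constant")
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise ValueError("band contains no spectral samples")
    pk = np.argmax(np.where(in_band, p, 0.0))
    # parabolic refinement on log power
    if 1 <= pk < len(f) - 1 and p[pk] > 0:
        lp = np.log(np.maximum(p[pk - 1:pk + 2], 1e-300))
        denom = lp[0] - 2 * lp[1] + lp[2]
        shift = 0.5 * (lp[0] - lp[2]) / denom if denom < 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    f_peak = f[pk] + shift * (f[1] - f[0])
    floor = np.median(p[~in_band]) if np.any(~in_band) else 0.0
    return float(f_peak), float(p[pk]), float(floor)


def extract_intrinsic_signal(stream: ProjectionStream,
                             band: tuple = DEFAULT_BAND_HZ) -> GatingSignal:
    """Derive the cardiac surrogate trace and heart rate from a raw stream.

    The surrogate is the total log-attenuation of each exposure (all bins,
    all detector pixels), which oscillates at the heart rate as the
    iodinated blood volume changes and peaks at end-diastole.  After the
    heart rate is located spectrally inside ``band``, the trace is re-filtered
    in a narrow band around it so that peak times are noise-robust.  Raises
    ``"no cardiac signal detected"`` when the band holds no spectral energy
    above the broadband noise floor (e.g. a static phantom).
    """
    log_stream = stream.log_transform()
    surrogate = log_stream.projections.sum(axis=(1, 2, 3))
    if np.std(surrogate) < 1e-15:
        raise ValueError("no cardiac signal detected: constant projections")

    fs = stream.sample_rate
    filtered = _bandpass(surrogate - surrogate.mean(), fs, band)

    # detection statistic on the *raw* surrogate: the band-pass filter would
    # suppress the off-band floor and make any noise look like a signal
    f_peak, p_peak, p_floor = _spectral_peak_hz(surrogate - surrogate.mean(),
                                                fs, band)
    if p_peak <= 0 or (p_floor > 0 and p_peak < 50.0 * p_floor) or np.std(filtered) < 1e-12:
        raise ValueError("no cardiac signal detected in band "
                         f"{band[0]:g}-{band[1]:g} Hz")

    # second pass: narrow band around the located heart rate
    narrow = (max(band[0], 0.8 * f_peak), min(band[1], 1.25 * f_peak))
    if narrow[0] < narrow[1]:
        filtered = _bandpass(surrogate - surrogate.mean(), fs, narrow)

    half = len(filtered) // 2
    nonstationary = False
    if half > int(3 * fs / band[0]):
        f1, _, _ = _spectral_peak_hz(filtered[:half], fs, band)
        f2, _, _ = _spectral_peak_hz(filtered[half:], fs, band)
        if abs(f1 - f2) / f_peak > 0.08:
            nonstationary = True
            warnings.warn("heart rate appears non-stationary across the scan")

    return GatingSignal(values=filtered, timestamps=stream.timestamps,
                        band=tuple(band), estimated_HR=f_peak * 60.0,
                        nonstationary=nonstationary)


def _peak_times(x: np.ndarray, t: np.ndarray, smooth_s: float = 1.0) -> np.ndarray:
    """Sub-sample peak times of a narrowband oscillation.

    The unwrapped analytic-signal phase is detrended, smoothed over
    ``smooth_s`` seconds (averaging timing noise over several beats while
    following slow heart-rate drift) and its upward crossings of multiples
    of 2*pi -- the surrogate maxima -- are located by interpolation.
    """
    from scipy.ndimage import uniform_filter1d

    fs = 1.0 / np.median(np.diff(t))
    phi = np.unwrap(np.angle(sps.hilbert(x)))
    slope = (phi[-1] - phi[0]) / (t[-1] - t[0])
    resid = phi - slope * (t - t[0])
    win = max(1, int(round(smooth_s * fs)))
    resid = uniform_filter1d(resid, win, mode="nearest")
    phi_s = slope * (t - t[0]) + resid
    phi_s = np.maximum.accumulate(phi_s)  # guard monotonicity for interp
    k0 = int(np.ceil(phi_s[0] / (2 * np.pi)))
    k1 = int(np.floor(phi_s[-1] / (2 * np.pi)))
    if k1 < k0 + 1:
        return np.array([])
    return np.interp(2 * np.pi * np.arange(k0, k1 + 1), phi_s, t)


def assign_phases(sig: GatingSignal, n_phases: int = 10) -> PhaseAssignment:
    """Sort exposures into ``n_phases`` bins across each beat.

    Peaks of the surrogate define R-peak analogues.  An exposure between
    peaks ``k`` and ``k+1`` lands in bin ``floor(n_phases * fractional
    position within that R-R interval)``; exposures before the first or
    after the last peak are dropped and reported.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    x = np.asarray(sig.values, dtype=float)
    t = np.asarray(sig.timestamps, dtype=float)
    peak_t = _peak_times(x, t)
    if len(peak_t) < 2:
        raise ValueError("fewer than 2 surrogate peaks detected; cannot gate")

    phase = np.full(len(t), -1, dtype=int)
    interval = np.searchsorted(peak_t, t, side="right") - 1
    inside = (interval >= 0) & (interval < len(peak_t) - 1)
    k = interval[inside]
    frac = (t[inside] - peak_t[k]) / (peak_t[k + 1] - peak_t[k])
    phase[inside] = np.floor(n_phases * frac).astype(int) % n_phases

    dropped = np.nonzero(~inside)[0]
    return PhaseAssignment(phase_index=phase, n_phases=n_phases, dropped=dropped)
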