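"""EMG fatigue spectroscopy and kinematic movement indices.

Surface EMG is band-pass filtered (20-240 Hz, 4th-order Butterworth,
zero-phase) and full-wave rectified; muscle fatigue is tracked through the
median frequency of the band-limited power spectrum, which compresses
downward as fatigue accumulates.  Kinematic traces yield per-window
movement amplitude, mean absolute velocity and cycle interval, and all
indices feed the baseline-normalized change index

    delta_I = (I_comparison - I_standard) / I_baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig

__all__ = [
    "SpectralResult",
    "MovementIndices",
    "emg_preprocess",
    "median_frequency",
    "cycle_metrics",
    "delta_index",
]

EMG_BAND_HZ = (20.0, 240.0)
FILTER_ORDER = 4


@dataclass
class SpectralResult:
    freqs_hz: np.ndarray
    psd: np.ndarray
    median_frequency_hz: float
    window_id: str = ""


@dataclass
class MovementIndices:
    """Raw movement-profile indices over one analysis window."""

    amplitude_deg: float        # mean over cycles of (max peak - min peak)
    velocity_deg_s: float       # mean |d(angle)/dt|
    interval_s: float           # mean spacing of flexion-direction center crossings
    n_cycles: int


def _bandpass_sos(fs: float, band: tuple[float, float] = EMG_BAND_HZ):
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz must be below Nyquist {nyq} Hz")
    if lo <= 0 or lo >= hi:
        raise ValueError(f"invalid band {band}")
    return spsig.butter(FILTER_ORDER, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(x: np.ndarray, fs: float, band: tuple[float, float] = EMG_BAND_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (20-240 Hz by default)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in EMG trace")
    sos = _bandpass_sos(fs, band)
    return spsig.sosfiltfilt(sos, x)


def emg_preprocess(x: np.ndarray, fs: float, band: tuple[float, float] = EMG_BAND_HZ) -> np.ndarray:
    """Band-pass filter then full-wave rectify; output length equals input."""
    return np.abs(bandpass_filter(x, fs, band))


def median_frequency(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = EMG_BAND_HZ,
    window_s: float = 2.0,
    prefiltered: bool = False,
) -> float:
    """Median frequency of the band-limited power spectrum.

    The spectrum is estimated on the band-passed (not rectified) signal by
    Welch's method (Hann windows of ``window_s`` seconds, 50% overlap), and
    the median is the frequency splitting the in-band cumulative power into
    equal halves, located by linear interpolation of cumulative power.
    """
    return spectral_analysis(x, fs, band=band, window_s=window_s,
                             prefiltered=prefiltered).median_frequency_hz


def spectral_analysis(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = EMG_BAND_HZ,
    window_s: float = 2.0,
    prefiltered: bool = False,
    window_id: str = "",
) -> SpectralResult:
    x = np.asarray(x, dtype=float)
    nper = int(round(window_s * fs))
    if x.size < nper:
        raise ValueError(
            f"need >= {window_s} s of signal ({nper} samples at {fs} Hz), got {x.size}")
    if not prefiltered:
        x = bandpass_filter(x, fs, band)
    freqs, psd = spsig.welch(x, fs=fs, window="hann", nperseg=nper,
                             noverlap=nper // 2, detrend="constant")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    f_b, p_b = freqs[in_band], psd[in_band]
    total = p_b.sum()
    if total <= 0:
        raise ValueError("zero in-band power; median frequency undefined")
    mf = _equal_split_frequency(f_b, p_b / total)
    return SpectralResult(freqs, psd, mf, window_id)


def _equal_split_frequency(f: np.ndarray, p: np.ndarray, tol: float = 1e-4) -> float:
    """Frequency dividing normalized in-band power into equal halves.

    Located by linear interpolation of cumulative power from both ends and
    averaging the two crossings; the symmetric form keeps the convention
    well-defined when a plateau of the cumulative sits exactly at one half
    (e.g. two equal-power lines), returning the plateau midpoint.
    """

    def crossing(freqs, cum):
        k = int(np.argmax(cum >= 0.5 - tol))
        if k == 0:
            return float(freqs[0])
        c0, c1 = cum[k - 1], cum[k]
        frac = (0.5 - c0) / (c1 - c0) if c1 > c0 else 0.0
        return float(freqs[k - 1] + np.clip(frac, 0, 1) * (freqs[k] - freqs[k - 1]))

    lo = crossing(f, np.cumsum(p))
    hi = -crossing(-f[::-1], np.cumsum(p[::-1]))
    return 0.5 * (lo + hi)


def _cycle_peaks(angle: np.ndarray, fs: float, min_period_s: float = 0.2):
    """Per-cycle maxima and minima of the flexion angle."""
    dist = max(1, int(min_period_s * fs))
    prom = 0.1 * max(np.ptp(angle), 1e-12)
    maxima, _ = spsig.find_peaks(angle, distance=dist, prominence=prom)
    minima, _ = spsig.find_peaks(-angle, distance=dist, prominence=prom)
    return maxima, minima


def _center_crossings(angle: np.ndarray, t: np.ndarray, center: float) -> np.ndarray:
    """Times of flexion-direction (rising) crossings of the center line.

    Crossing instants are refined by linear interpolation between the
    bracketing samples; exact-hit ties resolve to the earlier sample.
    """
    below = angle < center
    # rising crossing: sample k at-or-below... strictly below, k+1 at or above
    idx = np.nonzero(below[:-1] & (angle[1:] >= center))[0]
    if idx.size == 0:
        return np.empty(0)
    a0, a1 = angle[idx], angle[idx + 1]
    frac = np.where(a1 > a0, (center - a0) / np.where(a1 > a0, a1 - a0, 1.0), 0.0)
    return t[idx] + frac * (t[idx + 1] - t[idx])


def cycle_metrics(
    angle: np.ndarray,
    fs: float,
    target_center_deg: float | None = None,
) -> MovementIndices:
    """Movement amplitude, velocity, and cycle interval over a window.

    amplitude: mean over cycles of (max peak - min peak), pairing each
    cycle's maximum with the preceding minimum; velocity: mean absolute
    angular velocity; interval: mean spacing of flexion-direction crossings
    of the target center (midline of the span if not given).
    """
    angle = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(angle)):
        raise ValueError("non-finite samples in kinematic trace")
    t = np.arange(angle.size) / fs
    maxima, minima = _cycle_peaks(angle, fs)
    if maxima.size < 2 or minima.size < 2:
        raise ValueError("degenerate movement: fewer than two cycles detected")

    # pair each maximum with the closest preceding minimum
    amps = []
    for mx in maxima:
        prev = minima[minima < mx]
        if prev.size:
            amps.append(angle[mx] - angle[prev[-1]])
    if not amps:
        raise ValueError("degenerate movement: no flexion excursions found")
    amplitude = float(np.mean(amps))

    velocity = float(np.mean(np.abs(np.gradient(angle, 1.0 / fs))))

    if target_center_deg is None:
        target_center_deg = 0.5 * (np.median(angle[maxima]) + np.median(angle[minima]))
    crossings = _center_crossings(angle, t, target_center_deg)
    if crossings.size < 3:
        raise ValueError("degenerate movement: fewer than two center-crossing intervals")
    interval = float(np.mean(np.diff(crossings)))

    return MovementIndices(amplitude, velocity, interval, n_cycles=len(amps))


def arv(emg_preprocessed: np.ndarray) -> float:
    """Average rectified value: mean of the preprocessed (rectified) EMG."""
    return float(np.mean(emg_preprocessed))


def delta_index(i_comparison, i_standard, i_baseline):
    """Baseline-normalized condition difference of a movement index.

    delta_I = (I_comparison - I_standard) / I_baseline, with I_baseline the
    participant's average of the index over non-delayed preparation periods.
    Accepts scalars or broadcastable arrays.
    """
    i_c = np.asarray(i_comparison, dtype=float)
    i_s = np.asarray(i_standard, dtype=float)
    i_b = np.asarray(i_baseline, dtype=float)
    if np.any(i_b <= 0):
        raise ValueError("I_baseline must be positive")
    out = (i_c - i_s) / i_b
    return float(out) if out.ndim == 0 else out
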