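"""Rate estimation from filtered cardiorespiratory signals.

Peaks of the band-passed signal are located with a minimum-separation rule
(the band-limited signal cannot oscillate faster than the band's upper edge,
so the floor of one period of f_hi in samples is the separation; on a
conflict the higher peak survives).  The rate follows from the mean cycle
length:

    CL = mean(diff(locs)) / fs       (seconds)
    M  = t / CL                      (implied cycles in the t-second window)
    CV = 60 * M / t = 60 / CL        (events per minute)

M is kept real-valued; the reported rate depends only on CL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientPeaksError, NoDominantFrequencyError
from .spectral import Band

__all__ = ["RateEstimate", "detect_peaks", "rate_from_peaks", "estimate_rate"]

RateStatus = Literal["ok", "out-of-band"]


@dataclass
class RateEstimate:
    """Peak locations and the rate they imply over one analysis window."""

    peak_indices: np.ndarray
    cycle_length_s: float
    peak_count: float  # M = t / CL; real-valued by construction
    rate_per_min: float
    window_s: float
    status: RateStatus = "ok"

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")


#: Fraction of the dominant period used as the adaptive separation floor;
#: admits up to ~30% beat-to-beat interval jitter.
_SEPARATION_GUARD = 0.7


def detect_peaks(x: np.ndarray, fs: float, band: Band) -> np.ndarray:
    """Strict local maxima of a band-limited signal.

    Peaks are separated by at least one period of ``band.f_hi`` and, when
    the signal has a well-defined dominant frequency, by at least
    ``_SEPARATION_GUARD`` of that period — the band-passed signal is
    narrowband, so sub-period local maxima are filter ringing (window-edge
    artifacts of the ideal filter), not cycles.  For a clean tone both rules
    coincide.  On a separation conflict the higher peak survives.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    # one sample of slack: a tone at exactly f_hi has peaks one period apart
    # but sample quantisation jitters the spacing by +/-1
    min_distance = max(1, int(np.floor(fs / band.f_hi)) - 1)
    try:
        from .spectral import amplitude_spectrum, dominant_frequency

        f_dom = dominant_frequency(amplitude_spectrum(x, fs))
        min_distance = max(min_distance, int(np.floor(_SEPARATION_GUARD * fs / f_dom)))
    except NoDominantFrequencyError:
        pass
    peaks, _ = find_peaks(x, distance=min_distance)
    if len(peaks) < 2:
        raise InsufficientPeaksError(
            f"found {len(peaks)} peak(s); at least 2 required for a cycle length"
        )
    return peaks


def rate_from_peaks(peaks: np.ndarray, fs: float, t: float) -> RateEstimate:
    """Mean-cycle-length rate from peak sample indices."""
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) < 2:
        raise InsufficientPeaksError("need at least 2 peaks")
    cl = float(np.mean(np.diff(peaks))) / fs
    m = t / cl
    cv = 60.0 * m / t  # identically 60 / CL
    return RateEstimate(
        peak_indices=peaks,
        cycle_length_s=cl,
        peak_count=m,
        rate_per_min=cv,
        window_s=t,
    )


def estimate_rate(x: np.ndarray, fs: float, band: Band, t: float) -> RateEstimate:
    """Detect peaks then compute the rate; flag out-of-band results.

    A rate outside the band's per-minute range is returned unchanged with
    ``status='out-of-band'`` rather than discarded.
    """
    est = rate_from_peaks(detect_peaks(x, fs, band), fs, t)
    lo, hi = band.rate_range_per_min
    tol = 1e-6 * hi
    if not (lo - tol <= est.rate_per_min <= hi + tol):
        est.status = "out-of-band"
    return est
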