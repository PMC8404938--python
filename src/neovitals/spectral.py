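"""FFT spectra, physiological-band mode selection and ideal band-pass filtering.

The cardiac and respiratory bands default to 1.5–3 Hz (90–180 beats/min) and
0.3–1.5 Hz (18–90 breaths/min).  The band-pass filter is *ideal*: forward FFT,
zero every bin whose frequency falls outside the (edge-inclusive) band,
inverse FFT.  No taper is applied — the analysis windows are short (10 s) and
a taper would move the spectral peak locations the mode selector relies on.
The signal mean (DC bin) is always removed before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .emd import IMFSet
from .errors import NoDominantFrequencyError

__all__ = [
    "Spectrum",
    "Band",
    "CARDIAC_BAND",
    "RESPIRATORY_BAND",
    "amplitude_spectrum",
    "dominant_frequency",
    "select_imf",
    "ImfSelection",
    "ideal_bandpass",
]

# relative tolerance for matching FFT grid frequencies to band edges
_EDGE_RTOL = 1e-9


@dataclass(frozen=True)
class Band:
    """Pass band [f_lo, f_hi] in Hz, edges inclusive."""

    f_lo: float
    f_hi: float
    label: Literal["cardiac", "respiratory"] = "cardiac"

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"band requires 0 < f_lo < f_hi, got {self}")

    def validate_for(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band upper edge {self.f_hi} Hz reaches Nyquist for fs={fs}"
            )

    def contains(self, f: float) -> bool:
        tol = _EDGE_RTOL * max(1.0, self.f_hi)
        return (self.f_lo - tol) <= f <= (self.f_hi + tol)

    @property
    def rate_range_per_min(self) -> tuple[float, float]:
        """The band expressed in events/min (60 * f)."""
        return 60.0 * self.f_lo, 60.0 * self.f_hi


#: Heart-pulse band: 1.5–3 Hz = 90–180 beats/min.
CARDIAC_BAND = Band(1.5, 3.0, "cardiac")
#: Breathing band: 0.3–1.5 Hz = 18–90 breaths/min.
RESPIRATORY_BAND = Band(0.3, 1.5, "respiratory")


@dataclass
class Spectrum:
    """One-sided magnitude spectrum on the non-negative frequency half-grid."""

    freqs: np.ndarray
    magnitudes: np.ndarray
    n: int
    fs: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.freqs.shape != self.magnitudes.shape:
            raise ValueError("freqs and magnitudes must have equal shapes")
        if len(self.freqs) and self.freqs[0] != 0.0:
            raise ValueError("spectrum must start at DC")
        if not np.all(np.isfinite(self.magnitudes)):
            raise ValueError("magnitudes contain non-finite values")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"freq_hz": self.freqs, "magnitude": self.magnitudes}
        ).to_csv(path, index=False)


def amplitude_spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """One-sided amplitude spectrum of the mean-removed signal.

    Interior bins are scaled by 2/n so an on-grid unit sinusoid shows
    amplitude 1 at its frequency; DC and (for even n) the Nyquist bin carry
    the 1/n factor only.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    n = len(x)
    spec = np.fft.rfft(x - x.mean())
    mags = np.abs(spec) * (2.0 / n)
    mags[0] *= 0.5
    if n % 2 == 0:
        mags[-1] *= 0.5
    return Spectrum(freqs=np.fft.rfftfreq(n, d=1.0 / fs), magnitudes=mags, n=n, fs=fs)


def dominant_frequency(s: Spectrum, exclude_dc: bool = True) -> float:
    """Frequency of the maximum-magnitude bin; ties go to the lower frequency."""
    mags = s.magnitudes.copy()
    if exclude_dc:
        mags[0] = 0.0
    peak = float(np.max(mags)) if len(mags) else 0.0
    if peak <= 0.0:
        raise NoDominantFrequencyError("spectrum is all-zero; no dominant bin")
    return float(s.freqs[int(np.argmax(mags))])  # argmax takes first (lowest) tie


@dataclass
class ImfSelection:
    """Outcome of in-band mode selection, with per-mode diagnostics."""

    index: Optional[int]  # 0-based index into IMFSet.imfs; None on fallback
    fallback: bool
    band: Band
    dominant_freqs: list[float]  # per-IMF dominant frequency (nan if undefined)
    dominant_mags: list[float]  # magnitude at that bin

    @property
    def imf_number(self) -> Optional[int]:
        """1-based mode number (IMF1 is the fastest), as conventionally reported."""
        return None if self.index is None else self.index + 1


def select_imf(imfset: IMFSet, band: Band, fs: float) -> ImfSelection:
    """Pick the mode whose dominant frequency falls inside the band.

    Among several in-band candidates the one with the largest dominant-bin
    magnitude wins.  If no mode lands in the band the selection is flagged as
    a fallback and the caller should band-pass the raw signal instead.
    """
    if imfset.n_imfs == 0:
        return ImfSelection(None, True, band, [], [])
    freqs: list[float] = []
    mags: list[float] = []
    for imf in imfset.imfs:
        try:
            s = amplitude_spectrum(imf, fs)
            f = dominant_frequency(s)
            m = float(np.max(s.magnitudes[1:])) if len(s.magnitudes) > 1 else 0.0
        except NoDominantFrequencyError:
            f, m = float("nan"), 0.0
        freqs.append(f)
        mags.append(m)
    candidates = [
        k for k, f in enumerate(freqs) if np.isfinite(f) and band.contains(f)
    ]
    if not candidates:
        return ImfSelection(None, True, band, freqs, mags)
    best = max(candidates, key=lambda k: mags[k])
    return ImfSelection(best, False, band, freqs, mags)


def ideal_bandpass(x: np.ndarray, fs: float, band: Band) -> np.ndarray:
    """Ideal frequency-domain band-pass.

    Forward real FFT, zero all bins outside [f_lo, f_hi] (edges inclusive,
    DC always removed), inverse transform.  Conjugate symmetry is implicit in
    the real-FFT representation, so the output is exactly real and the same
    length as the input.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    band.validate_for(fs)
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    tol = _EDGE_RTOL * max(1.0, band.f_hi)
    keep = (freqs >= band.f_lo - tol) & (freqs <= band.f_hi + tol)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n)
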