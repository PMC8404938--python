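import numpy as np
import pytest

from neovitals import (
    Band,
    CARDIAC_BAND,
    IMFSet,
    RESPIRATORY_BAND,
    amplitude_spectrum,
    dominant_frequency,
    ideal_bandpass,
    select_imf,
)
from neovitals.errors import NoDominantFrequencyError

from conftest import FS, tone


def dft_magnitudes(x):
    """O(n^2) discrete-Fourier-sum oracle (one-sided amplitude scaling)."""
    x = np.asarray(x, float) - np.mean(x)
    n = len(x)
    k_max = n // 2
    mags = np.zeros(k_max + 1)
    for k in range(k_max + 1):
        c = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
        scale = 1.0 / n if (k == 0 or (n % 2 == 0 and k == n // 2)) else 2.0 / n
        mags[k] = np.abs(c) * scale
    return mags


def manual_bandpass(x, fs, f_lo, f_hi):
    """Oracle: full complex FFT, zero bins outside the band by hand."""
    x = np.asarray(x, float) - np.mean(x)
    spec = np.fft.fft(x)
    freqs = np.fft.fftfreq(len(x), d=1.0 / fs)
    keep = (np.abs(freqs) >= f_lo - 1e-12) & (np.abs(freqs) <= f_hi + 1e-12)
    spec[~keep] = 0.0
    return np.fft.ifft(spec).real


class TestAmplitudeSpectrum:
    def test_on_grid_tone_hits_single_bin(self):
        s = amplitude_spectrum(tone(2.0), FS)
        k = np.argmax(s.magnitudes)
        assert s.freqs[k] == pytest.approx(2.0)
        assert s.magnitudes[k] == pytest.approx(1.0, abs=1e-9)
        others = np.delete(s.magnitudes, k)
        assert np.max(others) < 1e-9

    def test_constant_signal_is_all_zero(self):
        s = amplitude_spectrum(np.full(100, 3.3), FS)
        assert np.all(s.magnitudes == 0.0)

    def test_two_tone_matches_dft_oracle(self):
        x = tone(1.5, amp=0.8) + tone(4.2, amp=0.3)
        s = amplitude_spectrum(x, FS)
        assert np.allclose(s.magnitudes, dft_magnitudes(x), atol=1e-9)

    def test_invalid_fs_rejected(self):
        with pytest.raises(ValueError):
            amplitude_spectrum(tone(1.0), fs=0.0)


class TestDominantFrequency:
    def test_on_grid_tone(self):
        assert dominant_frequency(amplitude_spectrum(tone(2.4), FS)) == pytest.approx(2.4)

    def test_tie_breaks_toward_lower_frequency(self):
        s = amplitude_spectrum(tone(1.0) + tone(2.0), FS)
        assert dominant_frequency(s) == pytest.approx(1.0)

    def test_larger_amplitude_wins(self):
        x = tone(0.7) + tone(2.0, amp=0.3)
        assert dominant_frequency(amplitude_spectrum(x, FS)) == pytest.approx(0.7)

    def test_all_zero_spectrum_raises(self):
        with pytest.raises(NoDominantFrequencyError):
            dominant_frequency(amplitude_spectrum(np.zeros(64), FS))


class TestSelectImf:
    @staticmethod
    def _imfset():
        modes = [tone(5.0), tone(2.0), tone(0.5)]
        return IMFSet(imfs=modes, residue=np.zeros(300), source_length=300)

    def test_cardiac_band_picks_in_band_mode(self):
        sel = select_imf(self._imfset(), CARDIAC_BAND, FS)
        assert sel.index == 1 and not sel.fallback

    def test_respiratory_band_picks_slow_mode(self):
        sel = select_imf(self._imfset(), RESPIRATORY_BAND, FS)
        assert sel.index == 2 and not sel.fallback

    def test_largest_in_band_magnitude_wins(self):
        modes = [tone(1.8, amp=0.4), tone(2.6, amp=1.0), tone(6.0)]
        s = IMFSet(imfs=modes, residue=np.zeros(300), source_length=300)
        sel = select_imf(s, CARDIAC_BAND, FS)
        assert sel.index == 1

    def test_no_in_band_mode_flags_fallback(self):
        modes = [tone(6.0), tone(0.1)]
        s = IMFSet(imfs=modes, residue=np.zeros(300), source_length=300)
        sel = select_imf(s, CARDIAC_BAND, FS)
        assert sel.fallback and sel.index is None

    def test_diagnostics_list_every_mode(self):
        sel = select_imf(self._imfset(), CARDIAC_BAND, FS)
        assert sel.dominant_freqs == pytest.approx([5.0, 2.0, 0.5])


class TestIdealBandpass:
    def test_in_band_tone_passes_unchanged(self):
        x = tone(2.0)
        assert np.max(np.abs(ideal_bandpass(x, FS, CARDIAC_BAND) - x)) < 1e-6

    def test_stopband_tone_annihilated(self):
        out = ideal_bandpass(tone(0.5), FS, CARDIAC_BAND)
        assert np.max(np.abs(out)) < 1e-6

    def test_superposition_keeps_only_in_band_component(self):
        x = tone(0.5) + tone(2.0)
        out = ideal_bandpass(x, FS, CARDIAC_BAND)
        assert np.max(np.abs(out - tone(2.0))) < 1e-6

    def test_matches_manual_bin_zeroing_oracle(self, rng):
        x = rng.normal(size=300)
        out = ideal_bandpass(x, FS, CARDIAC_BAND)
        assert np.allclose(out, manual_bandpass(x, FS, 1.5, 3.0), atol=1e-9)

    def test_band_edges_inclusive(self):
        for f_edge in (1.5, 3.0):
            x = tone(f_edge)
            assert np.max(np.abs(ideal_bandpass(x, FS, CARDIAC_BAND) - x)) < 1e-6

    def test_idempotent(self, rng):
        x = rng.normal(size=300)
        once = ideal_bandpass(x, FS, CARDIAC_BAND)
        twice = ideal_bandpass(once, FS, CARDIAC_BAND)
        assert np.max(np.abs(twice - once)) < 1e-9

    def test_linear(self, rng):
        a, b = rng.normal(size=300), rng.normal(size=300)
        lhs = ideal_bandpass(2.0 * a - 0.5 * b, FS, CARDIAC_BAND)
        rhs = 2.0 * ideal_bandpass(a, FS, CARDIAC_BAND) - 0.5 * ideal_bandpass(b, FS, CARDIAC_BAND)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_energy_never_increases(self, rng):
        x = rng.normal(size=300)
        out = ideal_bandpass(x, FS, RESPIRATORY_BAND)
        assert np.sum(out**2) <= np.sum((x - x.mean()) ** 2) + 1e-12

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ideal_bandpass(tone(1.0), FS, Band(1.0, 20.0))


class TestBand:
    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            Band(2.0, 1.0)
        with pytest.raises(ValueError):
            Band(0.0, 1.0)

    def test_rate_range(self):
        assert CARDIAC_BAND.rate_range_per_min == (90.0, 180.0)
        assert RESPIRATORY_BAND.rate_range_per_min == (18.0, 90.0)
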