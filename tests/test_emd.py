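import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neovitals import (
    EEMDConfig,
    amplitude_spectrum,
    dominant_frequency,
    eemd,
    emd,
    find_extrema,
    is_imf,
    sift_once,
)
from neovitals.emd import envelope_mean, zero_crossings

from conftest import FS, tone


def random_smooth_signal(seed, n=300, fs=FS, n_tones=4):
    """Band-limited random signal: a few random tones plus a slow trend."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = sum(
        rng.uniform(0.3, 1.5)
        * np.sin(2 * np.pi * rng.uniform(0.3, 6.0) * t + rng.uniform(0, 2 * np.pi))
        for _ in range(n_tones)
    )
    return x + rng.uniform(-1, 1) * t / 10


class TestFindExtrema:
    def test_single_oscillation(self):
        maxima, minima = find_extrema(np.array([0.0, 1.0, 0.0, -1.0, 0.0]))
        assert list(maxima) == [1] and list(minima) == [3]

    def test_monotonic_has_no_interior_extrema(self):
        maxima, minima = find_extrema(np.arange(10.0))
        assert len(maxima) == 0 and len(minima) == 0

    def test_plateau_contributes_midpoint(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, 0.0])
        maxima, minima = find_extrema(x)
        assert list(maxima) == [2] and list(minima) == [5]

    def test_tone_has_one_extremum_pair_per_period(self):
        # 3 Hz over 10 s: 30 cycles, one max and one min per cycle
        maxima, minima = find_extrema(tone(3.0))
        assert len(maxima) == 30 and len(minima) == 30

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_extrema(np.array([1.0, 2.0]))


class TestSiftOnce:
    def test_zero_signal_gives_zero_detail(self):
        d = sift_once(np.zeros(10))
        assert np.allclose(d, 0.0)

    def test_pure_tone_is_its_own_detail(self):
        x = tone(2.0)
        d = sift_once(x)
        r = np.corrcoef(x, d)[0, 1]
        assert r >= 0.99
        # envelope midline of a symmetric tone is near zero
        assert np.abs(envelope_mean(x)).mean() < 0.02

    def test_constant_offset_absorbed_into_envelope_mean(self):
        x = tone(2.0) + 3.0
        m = envelope_mean(x)
        assert np.abs(m - 3.0).mean() < 0.02
        assert np.corrcoef(tone(2.0), x - m)[0, 1] >= 0.99


class TestEmd:
    def test_monotonic_ramp_yields_no_imfs(self):
        t = np.linspace(0, 1, 100)
        s = emd(t)
        assert s.n_imfs == 0
        assert np.array_equal(s.residue, t)

    def test_two_tone_separation(self):
        x = tone(5.0) + tone(0.5)
        s = emd(x)
        assert s.n_imfs >= 2
        doms = [dominant_frequency(amplitude_spectrum(imf, FS)) for imf in s.imfs]
        assert abs(doms[0] - 5.0) <= 0.2
        assert any(abs(d - 0.5) <= 0.2 for d in doms[1:])

    @pytest.mark.parametrize("seed", range(10))
    def test_completeness(self, seed):
        x = random_smooth_signal(seed)
        s = emd(x)
        err = np.max(np.abs(x - s.reconstruct()))
        assert err <= 1e-8 * np.max(np.abs(x))

    @pytest.mark.parametrize("seed", range(10))
    def test_accepted_imfs_satisfy_imf_conditions(self, seed):
        s = emd(random_smooth_signal(seed))
        for imf in s.imfs:
            maxima, minima = find_extrema(imf)
            assert abs(len(maxima) + len(minima) - zero_crossings(imf)) <= 1
            assert is_imf(imf, tol=0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_residue_is_monotonic_or_trend(self, seed):
        s = emd(random_smooth_signal(seed))
        maxima, minima = find_extrema(s.residue)
        assert len(maxima) + len(minima) <= 2

    def test_non_finite_input_rejected(self):
        x = np.ones(50)
        x[3] = np.nan
        with pytest.raises(ValueError):
            emd(x)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_completeness_property(self, seed):
        x = random_smooth_signal(seed, n=200)
        s = emd(x)
        assert np.max(np.abs(x - s.reconstruct())) <= 1e-8 * np.max(np.abs(x))


class TestEemd:
    def test_zero_noise_reduces_to_plain_emd(self):
        x = random_smooth_signal(3)
        plain = emd(x)
        ens = eemd(x, EEMDConfig(ensemble_size=17, noise_std_ratio=0.0))
        assert ens.n_imfs == plain.n_imfs
        for a, b in zip(ens.imfs, plain.imfs):
            assert np.array_equal(a, b)
        assert np.array_equal(ens.residue, plain.residue)

    def test_same_seed_bit_identical(self):
        x = random_smooth_signal(4)
        cfg = EEMDConfig(ensemble_size=10, noise_std_ratio=0.2, master_seed=99)
        a = eemd(x, cfg)
        b = eemd(x, cfg)
        assert a.n_imfs == b.n_imfs
        for u, v in zip(a.imfs + [a.residue], b.imfs + [b.residue]):
            assert np.array_equal(u, v)

    def test_different_seed_differs(self):
        x = random_smooth_signal(4)
        a = eemd(x, EEMDConfig(ensemble_size=5, master_seed=1))
        b = eemd(x, EEMDConfig(ensemble_size=5, master_seed=2))
        assert not np.array_equal(a.imfs[0], b.imfs[0])

    def test_reconstruction_error_shrinks_with_ensemble_size(self):
        # residual ensemble-noise bias scales ~ eps/sqrt(L)
        errors = {}
        for L in (2, 8, 32):
            errs = []
            for rep in range(3):
                x = random_smooth_signal(20 + rep, n=256)
                s = eemd(x, EEMDConfig(ensemble_size=L, noise_std_ratio=0.2, master_seed=rep))
                errs.append(np.max(np.abs(x - s.reconstruct())))
            errors[L] = np.mean(errs)
        assert errors[2] > errors[8] > errors[32]

    def test_invalid_ensemble_size_rejected(self):
        with pytest.raises(ValueError):
            EEMDConfig(ensemble_size=0)


class TestIsImf:
    def test_canonical_tone_is_imf(self):
        assert is_imf(tone(2.0))

    def test_constant_is_not_imf(self):
        assert not is_imf(np.ones(50))

    def test_tone_with_large_offset_is_not_imf(self):
        assert not is_imf(tone(2.0) + 5.0)
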