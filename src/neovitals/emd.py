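"""Empirical mode decomposition (EMD) and its ensemble variant (EEMD).

EMD adaptively splits a non-stationary signal x(t) into intrinsic mode
functions (IMFs) — oscillatory components whose extrema and zero-crossing
counts agree to within one and whose upper/lower envelope mean is near zero —
plus a slow residue, such that

    x(t) = sum_i IMF_i(t) + r_N(t)          (completeness)

Each IMF is obtained by *sifting*: fit cubic-spline envelopes through the
local maxima and minima, subtract the envelope mean m(t) from the current
signal, and repeat until the detail d(t) = x(t) - m(t) is a zero-mean
oscillation.  Sifting stops on the Cauchy-type criterion

    SD = sum (d_{k-1} - d_k)^2 / sum d_{k-1}^2 < sd_threshold

or after ``max_sifts`` iterations.  The outer loop stops when the residue
carries at most two interior extrema (monotonic-or-trend).

EEMD suppresses mode mixing by decomposing L independently noise-perturbed
copies x_m(t) = x(t) + w_m(t) (white Gaussian noise with standard deviation
``noise_std_ratio * std(x)``) and averaging mode-by-mode across the ensemble.
The averaged modes are not themselves guaranteed to satisfy the IMF
conditions — a known property of the ensemble average, documented rather than
enforced.

Envelope end effects on short windows are controlled by mirror-extending a
few extrema beyond each end of the signal before spline fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "EMDConfig",
    "EEMDConfig",
    "IMFSet",
    "find_extrema",
    "sift_once",
    "emd",
    "eemd",
    "is_imf",
    "zero_crossings",
]


@dataclass(frozen=True)
class EMDConfig:
    """Sifting controls.

    sd_threshold : Cauchy stop criterion on consecutive sift iterates.
    max_sifts    : hard cap on sift iterations per IMF.
    boundary     : number of extrema mirrored beyond each end before the
                   envelope spline is fitted.
    """

    sd_threshold: float = 0.2
    max_sifts: int = 50
    boundary: int = 2

    def __post_init__(self) -> None:
        if not self.sd_threshold > 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sifts < 1:
            raise ValueError("max_sifts must be >= 1")
        if self.boundary < 1:
            raise ValueError("boundary must be >= 1")


@dataclass(frozen=True)
class EEMDConfig:
    """Ensemble controls: size L, noise amplitude ratio and master seed."""

    ensemble_size: int = 100
    noise_std_ratio: float = 0.2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.noise_std_ratio < 0:
            raise ValueError("noise_std_ratio must be >= 0")


@dataclass
class IMFSet:
    """Ordered modes IMF1..IMFN plus the residue of one decomposition."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        for k, imf in enumerate(self.imfs):
            if len(imf) != self.source_length:
                raise ValueError(f"IMF{k + 1} length {len(imf)} != {self.source_length}")
        if len(self.residue) != self.source_length:
            raise ValueError("residue length mismatch")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all modes plus the residue."""
        total = self.residue.copy()
        for imf in self.imfs:
            total += imf
        return total

    def to_csv(self, path: str | Path, fs: float = 30.0) -> None:
        """Multi-column CSV: time_s, imf1..imfN, residue."""
        cols = {"time_s": np.arange(self.source_length) / fs}
        for k, imf in enumerate(self.imfs):
            cols[f"imf{k + 1}"] = imf
        cols["residue"] = self.residue
        pd.DataFrame(cols).to_csv(path, index=False)


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    Runs of equal values (plateaus) contribute a single extremum at the
    plateau's midpoint index (floor of the centre), making the result
    deterministic for quantised signals.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 samples to locate extrema, got {n}")
    # run-length compress equal neighbours
    keep = np.empty(n, dtype=bool)
    keep[0] = True
    keep[1:] = x[1:] != x[:-1]
    starts = np.flatnonzero(keep)
    ends = np.append(starts[1:], n) - 1
    mids = (starts + ends) // 2
    vals = x[starts]
    if len(vals) < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(np.diff(vals))
    interior = mids[1:-1]
    maxima = interior[(s[:-1] > 0) & (s[1:] < 0)]
    minima = interior[(s[:-1] < 0) & (s[1:] > 0)]
    return maxima, minima


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes, treating exact zeros as crossings points."""
    x = np.asarray(x, dtype=np.float64)
    s = np.sign(x)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _mirrored_points(
    idx: np.ndarray, x: np.ndarray, n: int, boundary: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extrema (positions, values) mirror-extended about both signal ends."""
    t = idx.astype(np.float64)
    v = x[idx]
    left_sel = idx[idx > 0][:boundary]
    right_sel = idx[idx < n - 1][-boundary:]
    t_left = -left_sel[::-1].astype(np.float64)
    v_left = x[left_sel[::-1]]
    t_right = 2.0 * (n - 1) - right_sel[::-1].astype(np.float64)
    v_right = x[right_sel[::-1]]
    tt = np.concatenate([t_left, t, t_right])
    vv = np.concatenate([v_left, v, v_right])
    # positions must be strictly increasing for the spline
    order = np.argsort(tt, kind="stable")
    tt, vv = tt[order], vv[order]
    uniq = np.empty(len(tt), dtype=bool)
    uniq[0] = True
    uniq[1:] = np.diff(tt) > 0
    return tt[uniq], vv[uniq]


def _envelope(x: np.ndarray, idx: np.ndarray, boundary: int, side: str) -> np.ndarray:
    """Cubic-spline envelope through one family of extrema.

    Degenerate cases fall back gracefully: no extrema on a side gives the
    constant max (upper) / min (lower) of the signal; fewer than four spline
    knots gives linear interpolation.
    """
    n = len(x)
    if len(idx) == 0:
        c = np.max(x) if side == "upper" else np.min(x)
        return np.full(n, c)
    tt, vv = _mirrored_points(idx, x, n, boundary)
    grid = np.arange(n, dtype=np.float64)
    if len(tt) >= 4:
        return CubicSpline(tt, vv)(grid)
    if len(tt) >= 2:
        return np.interp(grid, tt, vv)
    return np.full(n, vv[0])


def envelope_mean(x: np.ndarray, cfg: EMDConfig | None = None) -> np.ndarray:
    """Pointwise mean m(t) of the upper and lower envelopes."""
    cfg = cfg or EMDConfig()
    x = np.asarray(x, dtype=np.float64)
    maxima, minima = find_extrema(x)
    upper = _envelope(x, maxima, cfg.boundary, "upper")
    lower = _envelope(x, minima, cfg.boundary, "lower")
    return 0.5 * (upper + lower)


def sift_once(x: np.ndarray, cfg: EMDConfig | None = None) -> np.ndarray:
    """One sifting pass: candidate detail d(t) = x(t) - m(t)."""
    x = np.asarray(x, dtype=np.float64)
    return x - envelope_mean(x, cfg)


def _can_sift(x: np.ndarray) -> bool:
    """True while the signal still carries an extractable oscillation.

    Requires at least one maximum, one minimum and three interior extrema
    overall; below that the residue is monotonic-or-trend and sifting stops.
    """
    if len(x) < 3:
        return False
    maxima, minima = find_extrema(x)
    return len(maxima) >= 1 and len(minima) >= 1 and len(maxima) + len(minima) >= 3


def _meets_imf_conditions(x: np.ndarray, midline_tol: float = 0.05) -> bool:
    """The two IMF assumptions: (i) extrema and zero-crossing counts differ
    by at most one; (ii) the envelope midline mean is near zero (within
    ``midline_tol`` of the signal's standard deviation)."""
    maxima, minima = find_extrema(x)
    if abs(len(maxima) + len(minima) - zero_crossings(x)) > 1:
        return False
    if len(maxima) >= 1 and len(minima) >= 1:
        midline = envelope_mean(x)
        sigma = float(np.std(x))
        if sigma > 0 and abs(float(np.mean(midline))) > midline_tol * sigma:
            return False
    return True


def _extract_imf(x: np.ndarray, cfg: EMDConfig) -> np.ndarray:
    """Sift one IMF out of x.

    A candidate detail is accepted once it satisfies the extrema/zero-
    crossing count condition *and* the Cauchy SD criterion signals that
    further sifting no longer changes it; ``max_sifts`` bounds the loop.
    """
    h = x.copy()
    for _ in range(cfg.max_sifts):
        if not _can_sift(h):
            break
        d = sift_once(h, cfg)
        denom = float(np.sum(h * h))
        if denom == 0.0:
            h = d
            break
        sd = float(np.sum((h - d) ** 2)) / denom
        h = d
        if sd < cfg.sd_threshold and _meets_imf_conditions(h):
            break
    return h


def emd(x: np.ndarray, cfg: EMDConfig | None = None) -> IMFSet:
    """Full empirical mode decomposition of a 1-D signal.

    Returns modes ordered fast-to-slow plus the residue; the sum of all
    components reproduces the input to floating-point rounding.
    """
    cfg = cfg or EMDConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if len(x) < 4:
        raise ValueError(f"signal too short for decomposition: {len(x)} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    max_imfs = int(np.log2(len(x))) + 4  # safety cap; never binding in practice
    while _can_sift(residue) and len(imfs) < max_imfs:
        imf = _extract_imf(residue, cfg)
        if np.allclose(imf, 0.0, atol=1e-14 * max(1.0, float(np.max(np.abs(x))))):
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, source_length=len(x))


def eemd(
    x: np.ndarray,
    cfg: EEMDConfig | None = None,
    emd_cfg: EMDConfig | None = None,
) -> IMFSet:
    """Ensemble EMD: average the modes of L noise-perturbed decompositions.

    Noise realisation m is drawn from ``default_rng(master_seed + m)`` with
    standard deviation ``noise_std_ratio * std(x)``, so the output is a pure
    function of (x, configs).  Ensemble members whose decompositions yield
    fewer modes than the ensemble maximum are padded with zero modes before
    averaging; residues are averaged likewise.  With ``noise_std_ratio = 0``
    every member is identical and the result coincides exactly with plain
    :func:`emd`.
    """
    cfg = cfg or EEMDConfig()
    emd_cfg = emd_cfg or EMDConfig()
    x = np.asarray(x, dtype=np.float64)
    noise_std = cfg.noise_std_ratio * float(np.std(x))
    if noise_std == 0.0:
        # all ensemble members coincide; their average is a single decomposition
        return emd(x, emd_cfg)

    members: list[IMFSet] = []
    for m in range(1, cfg.ensemble_size + 1):
        rng = np.random.default_rng(cfg.master_seed + m)
        noise = rng.normal(0.0, noise_std, size=len(x))
        members.append(emd(x + noise, emd_cfg))

    n_modes = max(s.n_imfs for s in members)
    n = len(x)
    mean_imfs = [np.zeros(n) for _ in range(n_modes)]
    mean_residue = np.zeros(n)
    for s in members:
        for k in range(n_modes):
            if k < s.n_imfs:
                mean_imfs[k] += s.imfs[k]
        mean_residue += s.residue
    scale = 1.0 / cfg.ensemble_size
    mean_imfs = [imf * scale for imf in mean_imfs]
    mean_residue *= scale
    return IMFSet(imfs=mean_imfs, residue=mean_residue, source_length=n)


def is_imf(x: np.ndarray, tol: float = 0.1) -> bool:
    """Check the two defining IMF conditions.

    True iff (i) the extrema and zero-crossing counts differ by at most one
    and (ii) the mean of the envelope midline is at most ``tol * std(x)`` in
    magnitude.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    maxima, minima = find_extrema(x)
    n_extrema = len(maxima) + len(minima)
    n_zc = zero_crossings(x)
    if abs(n_extrema - n_zc) > 1:
        return False
    if len(maxima) >= 1 and len(minima) >= 1:
        midline = envelope_mean(x)
    else:
        midline = np.full(len(x), float(np.mean(x)))
    return abs(float(np.mean(midline))) <= tol * float(np.std(x))
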