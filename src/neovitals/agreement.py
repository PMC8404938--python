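"""Method-comparison statistics for measured versus reference rate series.

Implements the standard agreement toolkit: Pearson correlation, ordinary
least-squares regression of measured on reference, Bland–Altman analysis
(mean bias, bias ± 1.96·SD limits of agreement, reproducibility coefficient
RPC = 1.96·SD of the paired differences), RMSE and MAE.  The SD of the
differences uses the n−1 denominator.  The percentage form of the RPC uses
the pooled grand mean of both series as denominator (the convention is not
universal; the choice is recorded in the output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedRates",
    "AgreementStats",
    "agreement_stats",
    "bland_altman_table",
    "plot_bland_altman",
    "plot_correlation",
]

LOA_MULTIPLIER = 1.96


@dataclass
class PairedRates:
    """Aligned measured/reference rate pairs (events per minute)."""

    measured: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=np.float64)
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.measured.shape != self.reference.shape or self.measured.ndim != 1:
            raise ValueError("measured and reference must be equal-length 1-D arrays")
        if len(self.measured) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.measured)) and np.all(np.isfinite(self.reference))):
            raise ValueError("rates contain non-finite values")

    @property
    def n(self) -> int:
        return len(self.measured)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedRates":
        """Read a two-column CSV with 'measured' and 'reference' headers
        (falling back to the first two columns)."""
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "measured" in cols and "reference" in cols:
            m, r = df[cols["measured"]], df[cols["reference"]]
        else:
            m, r = df.iloc[:, 0], df.iloc[:, 1]
        return cls(measured=m.to_numpy(float), reference=r.to_numpy(float))


@dataclass
class AgreementStats:
    """All agreement statistics for one measured-vs-reference pairing."""

    n: int
    pcc: float
    slope: float
    intercept: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    rpc: float
    rpc_percent: float
    rmse: float
    mae: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            "Method agreement summary",
            "------------------------",
            f"n pairs            {self.n}",
            f"Pearson r          {self.pcc:.4f}",
            f"OLS slope          {self.slope:.4f}",
            f"OLS intercept      {self.intercept:.4f}",
            f"mean bias          {self.bias:.3f} per min",
            f"limits of agreement [{self.loa_lower:.3f}, {self.loa_upper:.3f}]",
            f"RPC (1.96 SD)      {self.rpc:.3f} per min ({self.rpc_percent:.1f}%)",
            f"RMSE               {self.rmse:.3f} per min",
            f"MAE                {self.mae:.3f} per min",
        ]
        return "\n".join(lines)


def agreement_stats(p: PairedRates) -> AgreementStats:
    """Compute the full agreement panel.

    A constant reference leaves the correlation and regression undefined;
    those fields come back NaN with a warning while the difference-based
    statistics are still computed.
    """
    m, r = p.measured, p.reference
    diffs = m - r
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    rpc = LOA_MULTIPLIER * sd
    grand_mean = float(np.mean(np.concatenate([m, r])))
    rpc_percent = 100.0 * rpc / grand_mean if grand_mean != 0 else float("nan")
    rmse = float(np.sqrt(np.mean(diffs**2)))
    mae = float(np.mean(np.abs(diffs)))

    if np.ptp(r) == 0:
        warnings.warn(
            "reference series is constant: correlation and regression undefined",
            stacklevel=2,
        )
        pcc = slope = intercept = float("nan")
    else:
        if np.ptp(m) == 0:
            pcc = float("nan")  # zero-variance measured series
        else:
            pcc = float(sps.pearsonr(m, r).statistic)
        reg = sps.linregress(r, m)  # measured on reference
        slope, intercept = float(reg.slope), float(reg.intercept)

    return AgreementStats(
        n=p.n,
        pcc=pcc,
        slope=slope,
        intercept=intercept,
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - rpc,
        loa_upper=bias + rpc,
        rpc=rpc,
        rpc_percent=rpc_percent,
        rmse=rmse,
        mae=mae,
    )


def bland_altman_table(p: PairedRates) -> pd.DataFrame:
    """Per-pair Bland–Altman coordinates: mean (m+r)/2 and difference m−r."""
    return pd.DataFrame(
        {
            "mean": (p.measured + p.reference) / 2.0,
            "difference": p.measured - p.reference,
        }
    )


def plot_bland_altman(p: PairedRates, ax=None):
    """Bland–Altman scatter with bias and limits-of-agreement lines."""
    import matplotlib.pyplot as plt

    stats = agreement_stats(p)
    table = bland_altman_table(p)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(table["mean"], table["difference"], s=18)
    for y, style, label in [
        (stats.bias, "-", f"bias {stats.bias:.2f}"),
        (stats.loa_lower, "--", f"-1.96 SD {stats.loa_lower:.2f}"),
        (stats.loa_upper, "--", f"+1.96 SD {stats.loa_upper:.2f}"),
    ]:
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.annotate(label, (table["mean"].max(), y), fontsize=8, va="bottom")
    ax.set_xlabel("mean of methods (per min)")
    ax.set_ylabel("difference (per min)")
    return ax


def plot_correlation(p: PairedRates, ax=None):
    """Measured-vs-reference scatter with the OLS fit line."""
    import matplotlib.pyplot as plt

    stats = agreement_stats(p)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(p.reference, p.measured, s=18)
    if np.isfinite(stats.slope):
        xs = np.array([p.reference.min(), p.reference.max()])
        ax.plot(xs, stats.slope * xs + stats.intercept, "k-", linewidth=1)
        ax.set_title(f"r = {stats.pcc:.4f}")
    ax.set_xlabel("reference (per min)")
    ax.set_ylabel("measured (per min)")
    return ax
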