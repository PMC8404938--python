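"""Raw cardiac and respiratory signals by spatial averaging over the ROI.

The cardiac path averages the green channel — the channel with the strongest
pulsatile (blood-volume) component in skin video — giving one sample per
frame:

    pG(t) = sum_{i,j in ROI} G(i, j, t) / |ROI|

The respiratory path works on intensity rather than colour: frames are taken
to YIQ and the NTSC luminance channel Y = 0.299 R + 0.587 G + 0.114 B is
averaged over the ROI, so cyclic body motion that shifts bright/dark structure
through the box modulates the mean:

    pY(t) = sum_{i,j in ROI} Y(i, j, t) / |ROI|

No detrending or normalisation happens here; raw signals are exactly the
spatial means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .video import FrameSequence, ROIBox

__all__ = ["RawSignal", "green_mean", "luminance_mean", "NTSC_LUMA"]

#: NTSC luminance row of the RGB -> YIQ transform.
NTSC_LUMA = np.array([0.299, 0.587, 0.114])

SignalKind = Literal["cardiac", "respiratory"]


@dataclass
class RawSignal:
    """1-D real time series sampled once per frame."""

    values: np.ndarray
    fs: float
    kind: SignalKind = "cardiac"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("signal values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV (time_s, value); header records kind and fs."""
        df = pd.DataFrame({"time_s": self.times(), "value": self.values})
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} fs={self.fs}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RawSignal":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        meta = dict(
            item.split("=") for item in header.lstrip("#").split() if "=" in item
        )
        return cls(
            values=df["value"].to_numpy(),
            fs=float(meta.get("fs", 30.0)),
            kind=meta.get("kind", "cardiac"),
        )


def _roi_view(seq: FrameSequence, roi: ROIBox) -> np.ndarray:
    """(T, h, w, 3) view of ROI pixels — no copy, no re-validation."""
    roi.validate_for(seq.height, seq.width)
    return seq.frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1, :]


def green_mean(seq: FrameSequence, roi: ROIBox) -> RawSignal:
    """Raw cardiac signal pG(t): green channel averaged over the ROI."""
    pixels = _roi_view(seq, roi)
    return RawSignal(
        values=pixels[..., 1].mean(axis=(1, 2)), fs=seq.fps, kind="cardiac"
    )


def luminance_mean(seq: FrameSequence, roi: ROIBox) -> RawSignal:
    """Raw respiratory signal pY(t): NTSC luminance averaged over the ROI.

    Only the Y row of the YIQ transform is evaluated; the chrominance
    channels are never needed.
    """
    pixels = _roi_view(seq, roi)
    luma = pixels @ NTSC_LUMA
    return RawSignal(values=luma.mean(axis=(1, 2)), fs=seq.fps, kind="respiratory")
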