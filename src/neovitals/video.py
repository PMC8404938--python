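"""Video ingest, region-of-interest handling and cropping.

A recording is held as a :class:`FrameSequence`: an ``(T, H, W, 3)`` float
array of RGB frames normalised to ``[0, 1]`` plus a frame rate.  The region of
interest (ROI) over which pixels are spatially averaged is a
:class:`ROIBox` — a half-open rectangle ``[x0, x1) x [y0, y1)`` in 0-based
pixel coordinates, selected once on the first frame and held fixed for the
whole analysis window.

ROI selection is pluggable: any callable mapping the first frame to an
``ROIBox`` can serve as a detector (the hook where a trained infant detector
would plug in); the package bundles only a trivial static-box detector and a
structured-text ROI file reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Protocol, runtime_checkable

import numpy as np
import yaml

from .errors import DetectionError, EmptyVideoError, VideoDecodeError

__all__ = [
    "ROIBox",
    "FrameSequence",
    "DetectorPlugin",
    "StaticBoxDetector",
    "full_frame_detector",
    "read_video",
    "write_video",
    "select_roi",
    "crop",
    "CODEC_TOLERANCE",
]

#: Maximum per-pixel absolute round-trip error declared for the lossless
#: uint8 writer/reader pair (8-bit quantisation half-step).
CODEC_TOLERANCE = 0.5 / 255.0


@dataclass(frozen=True)
class ROIBox:
    """Rectangular region ``[x0, x1) x [y0, y1)``, 0-based pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "x1", "y1"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"ROI coordinate {name}={v!r} is not an integer")
            object.__setattr__(self, name, int(v))
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI coordinates must be non-negative, got {self}")
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"ROI must satisfy x0 < x1 and y0 < y1, got {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        """Pixel count |ROI| — the spatial-averaging denominator."""
        return self.width * self.height

    def validate_for(self, height: int, width: int) -> None:
        """Raise ``ValueError`` unless the box fits a ``height x width`` frame."""
        if self.x1 > width or self.y1 > height:
            raise ValueError(
                f"ROI {self} exceeds frame bounds {width}x{height} (WxH)"
            )

    def compose(self, inner: "ROIBox") -> "ROIBox":
        """Box equivalent to cropping to ``self`` then to ``inner``."""
        return ROIBox(
            x0=self.x0 + inner.x0,
            y0=self.y0 + inner.y0,
            x1=self.x0 + inner.x1,
            y1=self.y0 + inner.y1,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ROIBox":
        """Load a box from a YAML/JSON mapping with keys x0, y0, x1, y1."""
        with open(path) as fh:
            record = yaml.safe_load(fh)
        if not isinstance(record, dict):
            raise ValueError(f"ROI file {path} must contain a mapping")
        missing = {"x0", "y0", "x1", "y1"} - set(record)
        if missing:
            raise ValueError(f"ROI file {path} missing keys {sorted(missing)}")
        return cls(x0=record["x0"], y0=record["y0"], x1=record["x1"], y1=record["y1"])

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"x0": self.x0, "y0": self.y0, "x1": self.x1, "y1": self.y1}, fh
            )


@dataclass
class FrameSequence:
    """Ordered RGB frames with a fixed frame rate.

    ``frames`` has shape ``(T, H, W, 3)`` with values in ``[0, 1]``.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (T, H, W, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] == 0:
            raise EmptyVideoError("frame sequence contains zero frames")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite pixel values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (first frame at t = 0)."""
        return np.arange(self.n_frames) / self.fps


@runtime_checkable
class DetectorPlugin(Protocol):
    """ROI detector contract: map the first frame to an :class:`ROIBox`.

    Implementations receive the first frame as an ``(H, W, 3)`` float array
    and return a valid box, or raise :class:`DetectionError`.
    """

    def __call__(self, first_frame: np.ndarray) -> ROIBox: ...


@dataclass(frozen=True)
class StaticBoxDetector:
    """Detector stub returning a fixed, pre-computed box."""

    box: ROIBox

    def __call__(self, first_frame: np.ndarray) -> ROIBox:
        return self.box


def full_frame_detector(first_frame: np.ndarray) -> ROIBox:
    """Detector stub selecting the whole frame."""
    h, w = first_frame.shape[:2]
    return ROIBox(0, 0, w, h)


def _normalize(frames: np.ndarray) -> np.ndarray:
    """Scale integer pixel values to [0, 1]; floats are assumed pre-scaled."""
    if np.issubdtype(frames.dtype, np.integer):
        info = np.iinfo(frames.dtype)
        return frames.astype(np.float64) / float(info.max)
    return np.clip(frames.astype(np.float64), 0.0, 1.0)


def read_video(
    path: str | Path,
    fps: Optional[float] = None,
    normalize: bool = True,
) -> FrameSequence:
    """Read a video file into a :class:`FrameSequence`.

    Suffix dispatch: ``.npy``/``.npz`` are raw frame stacks, ``.tif``/``.tiff``
    multi-page TIFF (the lossless interchange format used throughout the test
    suite), anything else goes through ``imageio`` and decodes if a suitable
    plugin is available.  ``fps`` overrides container metadata; formats
    without timing metadata (TIFF, npy) default to the 30 fps of consumer
    video when ``fps`` is not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_fps: Optional[float] = None
    suffix = path.suffix.lower()
    try:
        if suffix in {".npy", ".npz"}:
            loaded = np.load(path)
            frames = loaded["frames"] if isinstance(loaded, np.lib.npyio.NpzFile) else loaded
            if isinstance(loaded, np.lib.npyio.NpzFile) and "fps" in loaded:
                meta_fps = float(loaded["fps"])
        elif suffix in {".tif", ".tiff"}:
            import tifffile

            frames = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            frames = iio.imread(path)
            try:
                meta = iio.immeta(path)
                if meta.get("fps"):
                    meta_fps = float(meta["fps"])
            except Exception:
                meta_fps = None
    except FileNotFoundError:
        raise
    except Exception as exc:  # backend-specific decode failures
        raise VideoDecodeError(f"could not decode {path}: {exc}") from exc

    frames = np.asarray(frames)
    if frames.ndim == 3 and frames.shape[-1] == 3:
        frames = frames[np.newaxis]  # single frame
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise VideoDecodeError(
            f"{path} decoded to shape {frames.shape}, expected (T, H, W, 3)"
        )
    if frames.shape[0] == 0:
        raise EmptyVideoError(f"{path} contains zero frames")
    if normalize:
        frames = _normalize(frames)
    else:
        frames = frames.astype(np.float64)
    return FrameSequence(frames=frames, fps=float(fps or meta_fps or 30.0))


def write_video(seq: FrameSequence, path: str | Path) -> None:
    """Write a frame sequence: ``.npy`` exact float64, ``.tif`` 8-bit lossless.

    The 8-bit path quantises; round-trip error is bounded by
    :data:`CODEC_TOLERANCE` per pixel.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, seq.frames)
    elif suffix == ".npz":
        np.savez(path, frames=seq.frames, fps=seq.fps)
    elif suffix in {".tif", ".tiff"}:
        import tifffile

        data = np.clip(np.round(seq.frames * 255.0), 0, 255).astype(np.uint8)
        tifffile.imwrite(path, data, photometric="rgb")
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


def select_roi(
    first_frame: np.ndarray,
    roi_file: Optional[str | Path] = None,
    detector: Optional[Callable[[np.ndarray], ROIBox]] = None,
) -> ROIBox:
    """Resolve the ROI from exactly one source and validate it.

    The box is determined once, on the first frame, and is intended to be
    held fixed over the analysis window.
    """
    if (roi_file is None) == (detector is None):
        raise ValueError("supply exactly one of roi_file or detector")
    if roi_file is not None:
        box = ROIBox.from_file(roi_file)
    else:
        box = detector(first_frame)
        if box is None:
            raise DetectionError("detector returned no bounding box")
        if not isinstance(box, ROIBox):
            raise DetectionError(f"detector returned {type(box).__name__}, not ROIBox")
    h, w = first_frame.shape[:2]
    box.validate_for(h, w)
    return box


def crop(seq: FrameSequence, roi: ROIBox) -> FrameSequence:
    """Crop every frame to the ROI; fps and frame count are preserved."""
    roi.validate_for(seq.height, seq.width)
    return FrameSequence(
        frames=seq.frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1, :].copy(),
        fps=seq.fps,
    )
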