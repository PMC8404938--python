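"""Ground-truthed synthetic signals and scenes.

Because no clinical recordings accompany the method, validation relies on
synthetic inputs that emulate its two measurement mechanisms:

* colour: a skin-coloured elliptical patch whose *green* channel oscillates
  sinusoidally at the cardiac frequency (blood-volume colour modulation);
* motion: the patch's vertical position oscillates at the respiratory
  frequency, so the NTSC-luminance mean over a fixed ROI is modulated by the
  patch edge sweeping through it.

Additive per-pixel Gaussian noise and a linear illumination drift model
sensor noise and slow lighting change.  Every generator is a pure function
of its :class:`SceneConfig` (all randomness flows from ``seed``), and each
output is accompanied by a ground-truth record carrying the planted rates.

Scenes are deliberately simple — one sinusoid per vital, no harmonics, no
photorealism — so recovered rates can be compared against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .extraction import RawSignal
from .video import FrameSequence, ROIBox, write_video

__all__ = ["SceneConfig", "synth_signal", "synth_video", "write_scene"]

# Scene palette (RGB, [0,1]): muted grey background, warm skin tone.
_BACKGROUND = np.array([0.35, 0.35, 0.35])
_SKIN = np.array([0.80, 0.60, 0.50])
# Softness of the elliptical patch edge (sigmoid steepness on the normalised
# radius); keeps the luminance response to sub-pixel motion smooth.
_EDGE_STEEPNESS = 12.0
# Luminance modulation depth per pixel of respiratory motion, for the 1-D
# signal generator (matches the default scene's edge contrast per pixel).
_RESP_DEPTH_PER_PX = 0.01


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic recording.

    Defaults mirror a typical bedside acquisition: 30 fps, 10 s windows, a
    desk-speed 240x320 frame with a generous body ROI, heart rate 120
    beats/min and respiratory rate 40 breaths/min (mid-range for infants).
    ``cardiac_amp`` is the green-channel modulation depth in [0,1] pixel
    units; ``resp_motion_px`` the vertical displacement amplitude in pixels.
    """

    fps: float = 30.0
    duration_s: float = 10.0
    frame_size: tuple[int, int] = (240, 320)  # (height, width)
    roi: ROIBox = field(default_factory=lambda: ROIBox(100, 60, 220, 180))
    hr_bpm: float = 120.0
    rr_bpm: float = 40.0
    cardiac_amp: float = 0.01
    resp_motion_px: float = 4.0
    noise_std: float = 0.0
    drift: float = 0.0  # illumination slope, [0,1] units per second
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        nyquist = self.fps / 2.0
        if self.hr_bpm / 60.0 >= nyquist or self.rr_bpm / 60.0 >= nyquist:
            raise ValueError(
                f"rates {self.hr_bpm}/{self.rr_bpm} per min exceed Nyquist for fps={self.fps}"
            )
        if min(self.cardiac_amp, self.resp_motion_px, self.noise_std) < 0:
            raise ValueError("amplitudes must be non-negative")
        h, w = self.frame_size
        self.roi.validate_for(h, w)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def _ellipse(self) -> tuple[float, float, float, float]:
        """Patch geometry (cx, cy0, a, b): a torso ellipse centred
        horizontally in the ROI, shifted toward its lower edge so the upper
        contour lies inside the box and the body extends below it."""
        roi = self.roi
        cx = (roi.x0 + roi.x1 - 1) / 2.0
        cy0 = (roi.y0 + roi.y1 - 1) / 2.0 + 0.30 * roi.height
        return cx, cy0, 0.40 * roi.width, 0.55 * roi.height

    @property
    def respiratory_roi(self) -> ROIBox:
        """Recommended motion ROI: the configured box, containing the
        breathing contour."""
        return self.roi

    @property
    def cardiac_roi(self) -> ROIBox:
        """Recommended colour ROI: an interior skin region that stays inside
        the patch throughout the breathing excursion.

        Averaging the green channel over pure skin keeps the pulse-colour
        tone free of motion leakage — the same reason pulse extraction from
        real video uses a box in the interior of a skin area rather than one
        straddling a moving edge.
        """
        cx, cy0, a, b = self._ellipse()
        m = self.resp_motion_px
        x0 = int(np.ceil(cx - 0.5 * a))
        x1 = int(np.floor(cx + 0.5 * a))
        y0 = int(np.ceil(cy0 - 0.4 * b + m))
        y1 = int(np.floor(min(self.roi.y1, cy0 + 0.4 * b - m)))
        return ROIBox(x0, y0, x1, y1)

    def ground_truth(self) -> dict:
        """Manifest record: planted rates plus a config echo."""
        return {
            "hr_bpm": self.hr_bpm,
            "rr_bpm": self.rr_bpm,
            "hr_hz": self.hr_bpm / 60.0,
            "rr_hz": self.rr_bpm / 60.0,
            "seed": self.seed,
            "config": {
                "fps": self.fps,
                "duration_s": self.duration_s,
                "frame_size": list(self.frame_size),
                "roi": [self.roi.x0, self.roi.y0, self.roi.x1, self.roi.y1],
                "cardiac_amp": self.cardiac_amp,
                "resp_motion_px": self.resp_motion_px,
                "noise_std": self.noise_std,
                "drift": self.drift,
            },
        }


def synth_signal(
    kind: Literal["cardiac", "respiratory"], cfg: SceneConfig
) -> tuple[RawSignal, dict]:
    """1-D surrogate of a raw extracted signal with exact known rate.

    value(t) = baseline + amp * sin(2 pi f t) + drift * t + noise, with
    f = rate/60.  The cardiac depth is ``cardiac_amp``; the respiratory depth
    scales with ``resp_motion_px`` at the default scene's per-pixel edge
    contrast.
    """
    if kind not in ("cardiac", "respiratory"):
        raise ValueError(f"unknown signal kind: {kind}")
    rate = cfg.hr_bpm if kind == "cardiac" else cfg.rr_bpm
    f = rate / 60.0
    if f >= cfg.fps / 2:
        raise ValueError(f"{kind} frequency {f} Hz exceeds Nyquist")
    amp = cfg.cardiac_amp if kind == "cardiac" else _RESP_DEPTH_PER_PX * cfg.resp_motion_px
    t = np.arange(cfg.n_frames) / cfg.fps
    baseline = 0.5
    rng = np.random.default_rng(cfg.seed)
    values = (
        baseline
        + amp * np.sin(2.0 * np.pi * f * t)
        + cfg.drift * t
        + rng.normal(0.0, cfg.noise_std, size=len(t))
    )
    truth = cfg.ground_truth() | {"kind": kind, "rate_bpm": rate, "freq_hz": f}
    return RawSignal(values=values, fs=cfg.fps, kind=kind), truth


def _patch_mask(
    height: int, width: int, cx: float, cy: float, a: float, b: float
) -> np.ndarray:
    """Soft elliptical membership mask in [0, 1]."""
    xx = np.arange(width, dtype=np.float64)
    yy = np.arange(height, dtype=np.float64)
    d = ((xx - cx) / a) ** 2 + (((yy - cy) / b) ** 2)[:, None]
    return 1.0 / (1.0 + np.exp(_EDGE_STEEPNESS * np.clip(d - 1.0, -60.0, 60.0)))


def synth_video(cfg: SceneConfig) -> tuple[FrameSequence, dict]:
    """Render a synthetic scene with planted cardiac and respiratory tones.

    A skin-toned soft-edged torso ellipse fills the lower part of the
    configured ROI; its green channel oscillates at hr_bpm/60 Hz and its
    vertical position at rr_bpm/60 Hz with amplitude ``resp_motion_px``.
    Seeded Gaussian noise is added per pixel per frame and a linear
    illumination drift is applied to all channels.  Pixels are clipped to
    [0, 1].  Use :attr:`SceneConfig.cardiac_roi` /
    :attr:`SceneConfig.respiratory_roi` as the per-vital analysis boxes.
    """
    h, w = cfg.frame_size
    # vertical motion sweeps the patch's upper contour through the ROI and
    # modulates its mean luminance; a patch wholly inside the box would leave
    # the spatial mean unchanged to first order
    cx, cy0, a, b = cfg._ellipse()

    f_hr = cfg.hr_bpm / 60.0
    f_rr = cfg.rr_bpm / 60.0
    t = np.arange(cfg.n_frames) / cfg.fps
    rng = np.random.default_rng(cfg.seed)

    # horizontal profile is time-invariant; only the vertical centre moves
    dx2 = (((np.arange(w, dtype=np.float64) - cx) / a) ** 2)[None, :]
    ygrid = np.arange(h, dtype=np.float64)
    frames = np.empty((cfg.n_frames, h, w, 3), dtype=np.float64)
    for k in range(cfg.n_frames):
        cy = cy0 + cfg.resp_motion_px * np.sin(2.0 * np.pi * f_rr * t[k])
        d = dx2 + (((ygrid - cy) / b) ** 2)[:, None]
        mask = 1.0 / (1.0 + np.exp(_EDGE_STEEPNESS * np.clip(d - 1.0, -60.0, 60.0)))
        skin = _SKIN.copy()
        skin[1] += cfg.cardiac_amp * np.sin(2.0 * np.pi * f_hr * t[k])
        frame = _BACKGROUND + mask[:, :, None] * (skin - _BACKGROUND)
        frame += cfg.drift * t[k]
        if cfg.noise_std > 0:
            frame += rng.normal(0.0, cfg.noise_std, size=frame.shape)
        frames[k] = frame
    np.clip(frames, 0.0, 1.0, out=frames)
    return FrameSequence(frames=frames, fps=cfg.fps), cfg.ground_truth()


def write_scene(
    cfg: SceneConfig, video_path: str | Path, manifest_path: str | Path
) -> dict:
    """Render a scene to disk plus its ground-truth manifest (YAML)."""
    seq, truth = synth_video(cfg)
    write_video(seq, video_path)
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return truth
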