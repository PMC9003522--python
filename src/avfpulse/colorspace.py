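"""RGB-to-scalar channel conversion and waveform amplitude comparison.

The pulse wave can in principle be read from luminance, hue or
saturation variation; in practice luminance carries the displacement
signal while hue/saturation stay nearly constant for a fixed skin
chromaticity, which is why luminance is the default channel throughout
the pipeline.  ``peak_to_peak`` is the amplitude measure used for that
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ScalarStack", "to_channel", "peak_to_peak", "LUMA_WEIGHTS"]

#: ITU-style luminance weights for (R, G, B).  The acquisition hardware
#: never defines its luminance computation, so a fixed documented
#: formula is used; pass ``weights=(0, 0, 1)`` for a blue-channel-only
#: reading (relevant when the scene is lit with a blue illuminator).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_CHANNEL_KINDS = ("luminance", "hue", "saturation")


@dataclass
class ScalarStack:
    """Single-channel time-ordered frames.

    ``values`` has shape ``(t, row, col)``.  Ranges: luminance in
    [0, 255], saturation in [0, 1], hue in [0, 360) degrees.
    """

    values: np.ndarray
    channel_kind: str
    fps: float
    pixel_pitch: float = 0.08

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be (t, row, col); got {self.values.shape}")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]

    def trace(self, row: int, col: int) -> np.ndarray:
        """Time series of one pixel."""
        return self.values[:, row, col]

    def to_tiff(self, path) -> Path:
        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        return path

    def trace_to_csv(self, path, pixels: list[tuple[int, int]]):
        import pandas as pd

        data = {"frame": np.arange(self.n_frames)}
        for r, c in pixels:
            data[f"r{r}_c{c}"] = self.trace(r, c)
        pd.DataFrame(data).to_csv(path, index=False)
        return Path(path)


def to_channel(stack, channel_kind: str, weights=None) -> ScalarStack:
    """Convert an RGB :class:`~avfpulse.video_io.FrameStack` to one scalar channel.

    Luminance is the weighted RGB sum ``LUMA_WEIGHTS`` (overridable via
    *weights*); hue and saturation come from the standard hexcone (HSV)
    conversion, with hue reported in degrees and set to 0 for
    achromatic pixels so no NaN reaches the spectral analysis.
    """
    if channel_kind not in _CHANNEL_KINDS:
        raise ValueError(
            f"unknown channel_kind {channel_kind!r}; expected one of {_CHANNEL_KINDS}"
        )
    frames = np.asarray(stack.frames, dtype=np.float64)
    if channel_kind == "luminance":
        w = np.asarray(weights if weights is not None else LUMA_WEIGHTS, dtype=float)
        if w.shape != (3,):
            raise ValueError("weights must be a length-3 sequence")
        values = frames @ w
    else:
        from skimage.color import rgb2hsv

        hsv = rgb2hsv(frames / 255.0)
        if channel_kind == "hue":
            values = hsv[..., 0] * 360.0
            values[hsv[..., 1] == 0] = 0.0  # hue undefined for achromatic pixels
        else:
            values = hsv[..., 1]
    return ScalarStack(
        values=values,
        channel_kind=channel_kind,
        fps=stack.fps,
        pixel_pitch=stack.pixel_pitch,
    )


def peak_to_peak(trace) -> float:
    """Max minus min of a waveform (accepts an array or a PixelTrace)."""
    samples = np.asarray(getattr(trace, "samples", trace), dtype=float)
    if samples.size == 0:
        raise ValueError("empty trace")
    return float(samples.max() - samples.min())
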