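"""256-level color mapping of luminance change into hemodynamic video.

Band-passed luminance change is quantized to 256 levels and painted
with a diverging palette — blue at the positive (tense, vessel
distended) end, red at the negative (relaxed) end — so the pulse wave's
spatial propagation can be watched frame by frame.  Scaling is fixed
across a sequence: the same luminance change maps to the same color in
every frame, which is what makes frames comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .colorspace import ScalarStack

__all__ = ["ColorMap256", "build_colormap", "render_sequence", "save_frames_png"]


@dataclass
class ColorMap256:
    """Ordered table of 256 distinct RGB levels over [vmin, vmax].

    Quantization is linear with round-half-up on the 0–255 level scale;
    out-of-domain values clamp to the end levels.
    """

    colors: np.ndarray  # (256, 3) uint8
    vmin: float
    vmax: float
    name: str = "blue-red"

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.uint8)
        if self.colors.shape != (256, 3):
            raise ValueError(f"need 256 RGB levels; got shape {self.colors.shape}")
        if len({tuple(c) for c in self.colors}) != 256:
            raise ValueError(f"palette {self.name!r} has duplicate 8-bit levels")
        if not self.vmin < self.vmax:
            raise ValueError(f"need vmin < vmax; got [{self.vmin}, {self.vmax}]")

    def level(self, values) -> np.ndarray:
        """Level index (0..255) per value; round-half-up, clamped ends."""
        scaled = (np.asarray(values, float) - self.vmin) / (self.vmax - self.vmin)
        idx = np.floor(scaled * 255.0 + 0.5)
        return np.clip(idx, 0, 255).astype(np.intp)

    def apply(self, values) -> np.ndarray:
        """RGB uint8 array with one extra trailing axis of length 3."""
        return self.colors[self.level(values)]


def _blue_red_palette() -> np.ndarray:
    # red (low) -> light center -> blue (high); the red channel falls by
    # exactly 1 per level, which guarantees 256 distinct triplets
    i = np.arange(256)
    return np.stack(
        [255 - i, 255 - np.abs(2 * i - 255), i], axis=1
    ).astype(np.uint8)


def build_colormap(palette: str = "blue-red", vmin: float = -1.0,
                   vmax: float = 1.0) -> ColorMap256:
    """Linear 256-level colormap over [vmin, vmax].

    ``"blue-red"`` is the built-in diverging palette; any matplotlib
    colormap name is also accepted (rejected if 8-bit quantization
    collapses two of its 256 levels).
    """
    if palette == "blue-red":
        colors = _blue_red_palette()
    else:
        import matplotlib.pyplot as plt

        cmap = plt.get_cmap(palette)
        colors = np.rint(cmap(np.linspace(0, 1, 256))[:, :3] * 255).astype(np.uint8)
    return ColorMap256(colors=colors, vmin=vmin, vmax=vmax, name=palette)


def render_sequence(
    stack: ScalarStack,
    cmap: ColorMap256 | None = None,
    t_range: tuple[int, int] | None = None,
    palette: str = "blue-red",
) -> np.ndarray:
    """Color-map a (band-passed) luminance-change stack into RGB frames.

    When *cmap* is omitted the domain defaults to the sequence-global
    amplitude symmetrized about zero (vmin = -vmax = max |value|), so
    zero change sits at the palette center.  *t_range* is a half-open
    frame-index interval; returns uint8 frames of shape (t, row, col, 3).
    """
    values = stack.values
    if t_range is not None:
        lo, hi = t_range
        if not (0 <= lo < hi <= values.shape[0]):
            raise ValueError(f"t_range {t_range} outside recording of "
                             f"{values.shape[0]} frames")
        values = values[lo:hi]
    if values.shape[0] == 0:
        raise ValueError("empty time range")
    if cmap is None:
        vmax = float(np.abs(values).max())
        if vmax == 0.0:
            vmax = 1.0  # all-zero stack: everything maps to the center level
        cmap = build_colormap(palette, vmin=-vmax, vmax=vmax)
    return cmap.apply(values)


def save_frames_png(frames: np.ndarray, directory, prefix: str = "frame") -> list[Path]:
    """Write each RGB frame as ``<prefix>_<i>.png``; returns the paths."""
    from imageio.v2 import imwrite

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.asarray(frames, dtype=np.uint8)):
        out = directory / f"{prefix}_{i:04d}.png"
        imwrite(out, frame)
        paths.append(out)
    return paths
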