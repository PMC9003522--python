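"""Spatial moving-average filtering and the kernel-size sweep.

Each frame is correlated with an N x M kernel of weights h(m, n)
(uniform 1/(N*M) by default), sliding one pixel at a time in raster
order.  Averaging K in-phase pixels leaves the pulse amplitude intact
while cutting i.i.d. noise variance by 1/K — the same mechanism as
additive averaging of repeated sweeps in evoked-potential work — so the
kernel size is the single denoising knob the SNR statistic optimizes.

Only fully interior pixels are produced by default (valid-region
convention); a reflect-padding mode is available but off by default
because padded borders would bias the SNR near frame edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import oaconvolve

from .colorspace import ScalarStack

__all__ = [
    "Kernel",
    "SmoothedStack",
    "moving_average",
    "kernel_sweep_sizes",
    "kernel_extent",
]


@dataclass
class Kernel:
    """N x M weight matrix; N, M odd so the window has a centre pixel."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValueError("kernel weights must be a 2-D matrix")
        n, m = self.weights.shape
        if n % 2 == 0 or m % 2 == 0 or n < 1 or m < 1:
            raise ValueError(f"kernel dimensions must be odd and >= 1; got {n}x{m}")

    @classmethod
    def uniform(cls, n: int, m: int | None = None) -> "Kernel":
        """Uniform averaging kernel with weights 1/(N*M)."""
        m = n if m is None else m
        if n < 1 or m < 1 or n % 2 == 0 or m % 2 == 0:
            raise ValueError(f"kernel dimensions must be odd and >= 1; got {n}x{m}")
        return cls(np.full((n, m), 1.0 / (n * m)))

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def m(self) -> int:
        return self.weights.shape[1]

    @property
    def is_uniform(self) -> bool:
        return bool(np.allclose(self.weights, 1.0 / (self.n * self.m)))


@dataclass
class SmoothedStack:
    """Filter output over the valid region.

    ``origin_offset`` maps valid-region coordinates back to source
    coordinates: source (r, c) = valid (r, c) + offset.
    """

    values: np.ndarray  # (t, row, col)
    kernel_size: int
    origin_offset: tuple[int, int]
    fps: float
    pixel_pitch: float = 0.08

    def trace(self, row: int, col: int, source_coords: bool = True) -> np.ndarray:
        """Time series at one output point; (row, col) in source coordinates
        by default."""
        if source_coords:
            row -= self.origin_offset[0]
            col -= self.origin_offset[1]
        t, h, w = self.values.shape
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(
                f"point ({row}, {col}) lies outside the valid region {h}x{w}"
            )
        return self.values[:, row, col]


def moving_average(stack, kernel: Kernel | int, mode: str = "valid") -> SmoothedStack:
    """Apply the moving-average filter frame by frame.

    *stack* is a :class:`~avfpulse.colorspace.ScalarStack` or a
    ``(t, row, col)`` array; *kernel* a :class:`Kernel` or an odd int
    (shorthand for the uniform N x N kernel).  ``mode="valid"`` keeps
    interior pixels only; ``mode="reflect"`` pads to preserve shape.
    """
    if isinstance(kernel, (int, np.integer)):
        kernel = Kernel.uniform(int(kernel))
    values = stack.values if isinstance(stack, ScalarStack) else np.asarray(stack, float)
    if values.ndim != 3:
        raise ValueError("input must be a (t, row, col) stack")
    t, h, w = values.shape
    n, m = kernel.n, kernel.m
    if n > h or m > w:
        raise ValueError(f"kernel {n}x{m} larger than frame {h}x{w}")
    if mode == "reflect":
        values = np.pad(values, ((0, 0), (n // 2, n // 2), (m // 2, m // 2)),
                        mode="reflect")
        offset = (0, 0)
    elif mode == "valid":
        offset = (n // 2, m // 2)
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")
    # Correlation == convolution with the kernel flipped; identical for
    # the symmetric uniform kernel but kept general for arbitrary h(m,n).
    out = oaconvolve(values, kernel.weights[None, ::-1, ::-1], mode="valid")
    fps = stack.fps if isinstance(stack, ScalarStack) else float("nan")
    pitch = stack.pixel_pitch if isinstance(stack, ScalarStack) else 0.08
    return SmoothedStack(
        values=out, kernel_size=n, origin_offset=offset, fps=fps, pixel_pitch=pitch
    )


def kernel_sweep_sizes(n_min: int = 1, n_max: int = 201, step: int = 2) -> list[int]:
    """Ordered odd kernel sizes for the SNR sweep (default 1, 3, ..., 201)."""
    if n_min % 2 == 0 or n_max % 2 == 0:
        raise ValueError("sweep bounds must be odd")
    if n_min > n_max or step < 1:
        raise ValueError("need n_min <= n_max and step >= 1")
    return list(range(n_min, n_max + 1, step))


def kernel_extent(n: int, pixel_pitch: float = 0.08) -> float:
    """Physical extent of an N-pixel kernel (N * pixel_pitch scale units)."""
    return n * pixel_pitch
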