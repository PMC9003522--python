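"""Frame-stack container and video I/O.

A recording is a time-ordered stack of RGB frames plus the acquisition
metadata needed downstream (frames per second, physical pixel pitch).
Three on-disk representations are supported:

``tiff``
    Multi-page TIFF, one RGB page per frame, metadata stored as a JSON
    blob in the ImageDescription tag.  Lossless.
``raw``
    A bare binary dump of the pixel array (uint8, C order: frame-major,
    then row-major, channel-interleaved) next to a YAML sidecar
    ``<stem>.yaml`` holding ``n_frames/height/width/fps/pixel_pitch``.
    Lossless; the byte layout is exactly ``frames.tobytes()``.
``video``
    AVI/MP4 through imageio.  Requires an ffmpeg-capable imageio
    backend; typical codecs are lossy, so pixel round-trips are not
    guaranteed and the reader attaches ``meta["lossy"] = True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["FrameStack", "read_frame_stack", "write_frame_stack"]

#: Default physical scale of one pixel (scale units per pixel).
DEFAULT_PIXEL_PITCH = 0.08

_RAW_SUFFIX = ".rgb"
_SIDECAR_SUFFIX = ".yaml"


@dataclass
class FrameStack:
    """Time-ordered RGB frames with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(t, row, col, 3)``.  uint8 for camera data;
        float is tolerated (values still within [0, 255]) so that
        noise-free synthetic stacks can carry unquantized intensities.
    fps
        Acquisition rate in frames per second.
    pixel_pitch
        Physical length per pixel, a dimensionless scale unit.  The
        default 0.08 matches the published acquisition geometry (the
        source prints the unit as "nm", almost certainly a typo, so the
        value is treated as a bare scale factor).
    """

    frames: np.ndarray
    fps: float
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.validate()

    def validate(self) -> None:
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (t, row, col, 3); got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("frame count must be >= 1")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive; got {self.fps}")
        if not self.pixel_pitch > 0:
            raise ValueError(f"pixel_pitch must be positive; got {self.pixel_pitch}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"pixel values outside [0, 255]: range [{lo}, {hi}]")

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
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.fps

    def _metadata_dict(self) -> dict:
        return {
            "fps": float(self.fps),
            "pixel_pitch": float(self.pixel_pitch),
            "subject_id": self.subject_id,
            "meta": self.meta,
        }


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "tiff"
    if suffix == _RAW_SUFFIX:
        return "raw"
    if suffix in {".avi", ".mp4", ".mov", ".mkv"}:
        return "video"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass fmt explicitly")


def write_frame_stack(stack: FrameStack, path, fmt: str | None = None) -> Path:
    """Write *stack* to *path*; returns the path written.

    ``tiff`` and ``raw`` round-trip losslessly through
    :func:`read_frame_stack`; ``video`` depends on the codec.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    frames = stack.frames
    if frames.dtype != np.uint8:
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    if fmt == "tiff":
        tifffile.imwrite(
            path,
            frames,
            photometric="rgb",
            description=json.dumps(stack._metadata_dict()),
        )
    elif fmt == "raw":
        path.write_bytes(frames.tobytes())
        sidecar = {
            "n_frames": stack.n_frames,
            "height": stack.height,
            "width": stack.width,
            "dtype": "uint8",
            "layout": "t-major, row-major, RGB-interleaved",
            **stack._metadata_dict(),
        }
        path.with_suffix(_SIDECAR_SUFFIX).write_text(yaml.safe_dump(sidecar))
    elif fmt == "video":
        _write_video(path, frames, stack.fps)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_frame_stack(
    path,
    fmt: str | None = None,
    fps: float | None = None,
    pixel_pitch: float | None = None,
) -> FrameStack:
    """Read a frame stack; *fps*/*pixel_pitch* override or supply metadata.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` for
    inconsistent frame geometry or when no fps is available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tiff":
        frames, info = _read_tiff(path)
    elif fmt == "raw":
        frames, info = _read_raw(path)
    elif fmt == "video":
        frames, info = _read_video(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    eff_fps = fps if fps is not None else info.get("fps")
    if eff_fps is None:
        raise ValueError(f"{path}: no fps in metadata and no default supplied")
    eff_pitch = pixel_pitch if pixel_pitch is not None else info.get("pixel_pitch")
    return FrameStack(
        frames=frames,
        fps=float(eff_fps),
        pixel_pitch=float(eff_pitch) if eff_pitch is not None else DEFAULT_PIXEL_PITCH,
        subject_id=info.get("subject_id", ""),
        meta=info.get("meta", {}) or {},
    )


def _read_tiff(path: Path):
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: inconsistent frame geometry {sorted(shapes)}")
        frames = tif.asarray()
        desc = tif.pages[0].description
    if frames.ndim == 3:  # single page
        frames = frames[None]
    info: dict = {}
    if desc:
        try:
            info = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            info = {}
    return frames, info


def _read_raw(path: Path):
    sidecar_path = path.with_suffix(_SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"raw stack {path} has no sidecar {sidecar_path}")
    info = yaml.safe_load(sidecar_path.read_text())
    t, h, w = int(info["n_frames"]), int(info["height"]), int(info["width"])
    buf = path.read_bytes()
    expected = t * h * w * 3
    if len(buf) != expected:
        raise ValueError(
            f"{path}: inconsistent frame geometry — sidecar implies {expected} bytes, "
            f"file holds {len(buf)}"
        )
    frames = np.frombuffer(buf, dtype=np.uint8).reshape(t, h, w, 3)
    return frames, info


def _read_video(path: Path):
    import imageio.v2 as iio

    try:
        reader = iio.get_reader(path)
    except Exception as exc:  # missing ffmpeg backend, unsupported container
        raise ValueError(
            f"cannot open video container {path}: {exc}; an ffmpeg-capable "
            "imageio backend is required for AVI/MP4"
        ) from exc
    with reader:
        frames = [np.asarray(frame)[..., :3] for frame in reader]
        meta = reader.get_meta_data()
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"{path}: inconsistent frame geometry {sorted(shapes)}")
    info = {"fps": meta.get("fps"), "meta": {"lossy": True}}
    return np.stack(frames), info


def _write_video(path: Path, frames: np.ndarray, fps: float) -> None:
    import imageio.v2 as iio

    try:
        iio.mimwrite(path, list(frames), fps=fps)
    except Exception as exc:
        raise ValueError(
            f"cannot write video container {path}: {exc}; an ffmpeg-capable "
            "imageio backend is required for AVI/MP4"
        ) from exc
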