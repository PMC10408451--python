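"""Full-reference video quality metric.

The image metric is applied frame-by-frame and the per-frame scores are
averaged.  Two preprocessing steps precede the per-frame comparison:

* **Frame-rate alignment** — when the distorted video has fewer frames than
  the reference, either reference frames are dropped (default; performs
  better empirically) or distorted frames are duplicated, so both sequences
  have equal length.
* **Kernel scaling** — the three Gaussian widths are multiplied by
  ``f = frame_width / base_width`` (``base_width`` defaults to 512, the
  width of the images the parameters were optimized on); ``lambda`` is kept
  unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._exceptions import (
    ConfigurationError,
    InvalidInputError,
    InvalidParameterError,
    ShapeMismatchError,
)
from .core import INRFParams
from .iqa import inrf_iqa, load_image

__all__ = [
    "VideoSequence",
    "AlignmentPlan",
    "ScaledParams",
    "VQAResult",
    "scale_params",
    "plan_alignment",
    "inrf_vqa",
    "read_video",
]

DEFAULT_BASE_WIDTH = 512
STRATEGIES = ("drop_reference", "duplicate_distorted")


@dataclass
class VideoSequence:
    """Ordered frames plus frame rate.

    Frames are numpy arrays sharing one shape: ``(H, W)`` luminance or
    ``(H, W, 3)`` RGB.
    """

    frames: list
    fps: float

    def __post_init__(self):
        if not self.frames:
            raise InvalidInputError("a video needs at least one frame")
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise InvalidParameterError(f"fps must be > 0, got {self.fps}")
        shape = np.asarray(self.frames[0]).shape
        for i, f in enumerate(self.frames):
            if np.asarray(f).shape != shape:
                raise ShapeMismatchError(
                    f"frame {i} has shape {np.asarray(f).shape}, expected {shape}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def height(self) -> int:
        return np.asarray(self.frames[0]).shape[0]

    @property
    def width(self) -> int:
        return np.asarray(self.frames[0]).shape[1]


@dataclass(frozen=True)
class AlignmentPlan:
    """Equal-length pairing of reference and distorted frame indices."""

    strategy: str
    ref_indices: tuple
    dist_indices: tuple

    def __post_init__(self):
        if len(self.ref_indices) != len(self.dist_indices):
            raise InvalidParameterError("index lists must have equal length")


@dataclass(frozen=True)
class ScaledParams(INRFParams):
    """Transform parameters after resolution-dependent kernel scaling."""

    scale_factor: float = 1.0


def scale_params(
    base: INRFParams | None = None,
    frame_width: int = DEFAULT_BASE_WIDTH,
    base_width: int = DEFAULT_BASE_WIDTH,
) -> ScaledParams:
    """Scale the Gaussian widths by ``f = frame_width / base_width``.

    A 1920-wide (2K) frame against the 512-wide base gives ``f = 3.75``.
    ``lambda`` (and the sigmoid, truncation, level count) are unchanged.
    """
    base = base or INRFParams()
    if frame_width < 1 or base_width < 1:
        raise InvalidParameterError(
            f"widths must be >= 1, got frame_width={frame_width}, base_width={base_width}"
        )
    f = frame_width / base_width
    return ScaledParams(
        sigma_m=base.sigma_m * f,
        sigma_w=base.sigma_w * f,
        sigma_g=base.sigma_g * f,
        lam=base.lam,
        sigmoid=base.sigmoid,
        truncate=base.truncate,
        n_levels=base.n_levels,
        scale_factor=f,
    )


def plan_alignment(n_ref: int, n_dist: int, strategy: str = "drop_reference") -> AlignmentPlan:
    """Build the frame pairing that equalizes the two sequence lengths.

    ``drop_reference`` keeps every distorted frame and picks reference frame
    ``floor(i * n_ref / n_dist)`` for pair ``i`` (uniform decimation starting
    at frame 0).  ``duplicate_distorted`` keeps every reference frame and
    repeats distorted frame ``floor(i * n_dist / n_ref)``.  Only
    ``n_ref >= n_dist`` is supported (lower-rate distorted videos).
    """
    if strategy not in STRATEGIES:
        raise InvalidParameterError(
            f"unknown strategy {strategy!r}; known: {STRATEGIES}"
        )
    if n_ref < 1 or n_dist < 1:
        raise InvalidInputError("frame counts must be >= 1")
    if n_dist > n_ref:
        raise InvalidInputError(
            f"distorted video has more frames ({n_dist}) than reference ({n_ref}); "
            "only lower-rate distorted videos are supported"
        )
    if strategy == "drop_reference":
        ref_idx = tuple(i * n_ref // n_dist for i in range(n_dist))
        dist_idx = tuple(range(n_dist))
    else:
        ref_idx = tuple(range(n_ref))
        dist_idx = tuple(i * n_dist // n_ref for i in range(n_ref))
    return AlignmentPlan(strategy=strategy, ref_indices=ref_idx, dist_indices=dist_idx)


@dataclass(frozen=True)
class VQAResult:
    """Pooled score plus per-frame diagnostics."""

    value: float
    per_frame: tuple
    plan: AlignmentPlan
    params: ScaledParams

    def __float__(self) -> float:
        return self.value


def inrf_vqa(
    ref: VideoSequence,
    dist: VideoSequence,
    base: INRFParams | None = None,
    strategy: str = "drop_reference",
    *,
    base_width: int = DEFAULT_BASE_WIDTH,
    luminance: str = "luma601",
    exact: bool = False,
) -> VQAResult:
    """Video score: mean of per-frame image scores over the aligned pairing."""
    if (ref.height, ref.width) != (dist.height, dist.width):
        raise ShapeMismatchError(
            f"resolution mismatch: reference {ref.height}x{ref.width} vs "
            f"distorted {dist.height}x{dist.width}"
        )
    plan = plan_alignment(len(ref), len(dist), strategy)
    params = scale_params(base, frame_width=ref.width, base_width=base_width)
    scores = tuple(
        inrf_iqa(
            ref.frames[i],
            dist.frames[j],
            params,
            luminance=luminance,
            exact=exact,
        )
        for i, j in zip(plan.ref_indices, plan.dist_indices)
    )
    return VQAResult(
        value=float(np.mean(scores)), per_frame=scores, plan=plan, params=params
    )


# ---------------------------------------------------------------------------
# Video ingestion
# ---------------------------------------------------------------------------

_FRAME_EXTS = (".png", ".pgm", ".bmp", ".tif", ".tiff", ".ppm", ".jpg", ".jpeg")


def read_video(source, layout: str | None = None, *, width=None, height=None,
               fps=None, pix_fmt: str = "yuv420p") -> VideoSequence:
    """Load a video from a frame directory, a Y4M file, or raw planar YUV.

    Raw YUV needs geometry either as keyword arguments or via a JSON sidecar
    ``<source>.json`` with keys ``width``, ``height``, ``fps`` and optionally
    ``pix_fmt`` (``yuv420p`` or ``yuv444p``).  For YUV sources the Y plane is
    used directly as luminance, rescaled to [0, 1].
    """
    path = Path(source)
    if layout is None:
        if path.is_dir():
            layout = "frames"
        elif path.suffix.lower() == ".y4m":
            layout = "y4m"
        elif path.suffix.lower() in (".yuv", ".raw"):
            layout = "yuv"
        else:
            raise ConfigurationError(f"cannot infer video layout for {source}")
    if layout == "frames":
        return _read_frame_dir(path, fps or 30.0)
    if layout == "y4m":
        return _read_y4m(path)
    if layout == "yuv":
        return _read_raw_yuv(path, width, height, fps, pix_fmt)
    raise ConfigurationError(f"unknown video layout {layout!r}")


def _read_frame_dir(path: Path, fps: float) -> VideoSequence:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS)
    if not files:
        raise InvalidInputError(f"no frame images found in {path}")
    frames = [load_image(p) for p in files]
    return VideoSequence(frames=frames, fps=fps)


def _parse_y4m_header(line: bytes):
    tokens = line.decode("ascii", "replace").strip().split(" ")
    if not tokens or tokens[0] != "YUV4MPEG2":
        raise InvalidInputError("not a YUV4MPEG2 stream")
    width = height = None
    fps = 30.0
    chroma = "420"
    for tok in tokens[1:]:
        if not tok:
            continue
        key, val = tok[0], tok[1:]
        if key == "W":
            width = int(val)
        elif key == "H":
            height = int(val)
        elif key == "F":
            num, den = val.split(":")
            fps = int(num) / int(den)
        elif key == "C":
            chroma = val
    if width is None or height is None:
        raise InvalidInputError("Y4M header missing W or H")
    return width, height, fps, chroma


def _chroma_plane_size(chroma: str, width: int, height: int) -> int:
    if chroma.startswith("420"):
        return (width // 2) * (height // 2)
    if chroma.startswith("422"):
        return (width // 2) * height
    if chroma.startswith("444"):
        return width * height
    if chroma.startswith("mono"):
        return 0
    raise InvalidInputError(f"unsupported Y4M chroma subsampling C{chroma}")


def _read_y4m(path: Path) -> VideoSequence:
    with open(path, "rb") as fh:
        header = fh.readline()
        width, height, fps, chroma = _parse_y4m_header(header)
        y_size = width * height
        c_size = _chroma_plane_size(chroma, width, height)
        frames = []
        while True:
            marker = fh.readline()
            if not marker:
                break
            if not marker.startswith(b"FRAME"):
                raise InvalidInputError(f"corrupt Y4M frame marker in {path}")
            data = fh.read(y_size + 2 * c_size)
            if len(data) < y_size + 2 * c_size:
                raise InvalidInputError(f"truncated Y4M frame in {path}")
            y = np.frombuffer(data[:y_size], dtype=np.uint8).reshape(height, width)
            frames.append(y.astype(np.float64) / 255.0)
    if not frames:
        raise InvalidInputError(f"Y4M file {path} contains no frames")
    return VideoSequence(frames=frames, fps=fps)


def _read_raw_yuv(path: Path, width, height, fps, pix_fmt) -> VideoSequence:
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        width = width or meta.get("width")
        height = height or meta.get("height")
        fps = fps or meta.get("fps")
        pix_fmt = meta.get("pix_fmt", pix_fmt)
    if not (width and height and fps):
        raise ConfigurationError(
            f"raw YUV {path} needs width/height/fps (kwargs or {sidecar.name})"
        )
    width, height = int(width), int(height)
    if pix_fmt == "yuv420p":
        frame_bytes = width * height * 3 // 2
    elif pix_fmt == "yuv444p":
        frame_bytes = width * height * 3
    else:
        raise ConfigurationError(f"unsupported pixel format {pix_fmt!r}")
    data = path.read_bytes()
    if len(data) % frame_bytes:
        raise InvalidInputError(
            f"raw YUV size {len(data)} is not a multiple of the frame size {frame_bytes}"
        )
    n = len(data) // frame_bytes
    if n == 0:
        raise InvalidInputError(f"raw YUV file {path} contains no frames")
    frames = []
    for i in range(n):
        off = i * frame_bytes
        y = np.frombuffer(data[off : off + width * height], dtype=np.uint8)
        frames.append(y.reshape(height, width).astype(np.float64) / 255.0)
    return VideoSequence(frames=frames, fps=float(fps))
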