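"""Deterministic synthetic fixtures: images, distortions, videos, datasets.

Everything here is seeded and self-contained (no filesystem or network
reads), so the metric, the video pipeline and the evaluation protocol can
all be exercised without downloading any benchmark dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._exceptions import InvalidParameterError
from .core import INRFParams
from .evaluation import Logistic4Params, logistic4
from .iqa import inrf_iqa
from .vqa import VideoSequence

__all__ = [
    "DistortionSpec",
    "make_image",
    "apply_distortion",
    "make_video",
    "make_scored_dataset",
    "save_frames",
    "write_y4m",
]

IMAGE_KINDS = ("ramp", "disk", "sinusoid", "filtered_noise")
DISTORTION_KINDS = (
    "gaussian_noise",
    "gaussian_blur",
    "contrast_change",
    "quantization",
    "block_artifact",
)


@dataclass(frozen=True)
class DistortionSpec:
    """A parametric distortion: kind, strength and noise seed.

    ``level=0`` reproduces the input exactly; larger levels distort more.
    Units are kind-specific: noise standard deviation, blur sigma in pixels,
    contrast-compression strength, quantization step size, block-blend
    fraction.
    """

    kind: str
    level: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in DISTORTION_KINDS:
            raise InvalidParameterError(
                f"unknown distortion kind {self.kind!r}; known: {DISTORTION_KINDS}"
            )
        if self.level < 0:
            raise InvalidParameterError(f"level must be >= 0, got {self.level}")


def make_image(kind: str, size: int = 64, seed: int = 0) -> np.ndarray:
    """Deterministic grayscale test image with values in [0, 1].

    ``filtered_noise`` has an approximately 1/f amplitude spectrum, the
    standard natural-image surrogate.
    """
    if kind not in IMAGE_KINDS:
        raise InvalidParameterError(f"unknown image kind {kind!r}; known: {IMAGE_KINDS}")
    if size < 8:
        raise InvalidParameterError(f"size must be >= 8, got {size}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    if kind == "ramp":
        return np.tile(np.linspace(0.0, 1.0, size), (size, 1))
    if kind == "disk":
        cy = size / 2 + rng.uniform(-size / 16, size / 16)
        cx = size / 2 + rng.uniform(-size / 16, size / 16)
        r = size / 4
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        # soft 1-px edge to avoid pure aliasing
        img = 0.25 + 0.5 * np.clip(r + 0.5 - dist, 0.0, 1.0)
        return img
    if kind == "sinusoid":
        theta = rng.uniform(0, np.pi)
        cycles = rng.integers(3, 8)
        phase = rng.uniform(0, 2 * np.pi)
        u = np.cos(theta) * xx + np.sin(theta) * yy
        return 0.5 + 0.4 * np.sin(2 * np.pi * cycles * u / size + phase)
    # filtered_noise
    white = rng.standard_normal((size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    freq = np.sqrt(fy**2 + fx**2)
    freq[0, 0] = 1.0  # leave DC untouched
    spectrum = np.fft.fft2(white) / freq
    img = np.real(np.fft.ifft2(spectrum))
    img -= img.min()
    img /= img.max()
    return img


def apply_distortion(image, spec: DistortionSpec) -> np.ndarray:
    """Apply a seeded parametric distortion; output is clipped to [0, 1]."""
    arr = np.asarray(image, dtype=np.float64)
    if spec.level == 0:
        return arr.copy()
    if spec.kind == "gaussian_noise":
        rng = np.random.default_rng(spec.seed)
        out = arr + rng.normal(0.0, spec.level, size=arr.shape)
    elif spec.kind == "gaussian_blur":
        out = ndimage.gaussian_filter(arr, sigma=spec.level, mode="reflect")
    elif spec.kind == "contrast_change":
        # compress contrast about the mean; level -> infinity flattens fully
        mean = arr.mean()
        out = mean + (arr - mean) / (1.0 + spec.level)
    elif spec.kind == "quantization":
        # level is the quantization step; distinct values <= 1/level + 1
        n = max(1, int(round(1.0 / spec.level)))
        out = np.round(arr * n) / n
    else:  # block_artifact
        block = 8
        h, w = arr.shape[:2]
        ph = (-h) % block
        pw = (-w) % block
        padded = np.pad(arr, ((0, ph), (0, pw)), mode="edge")
        hb, wb = padded.shape[0] // block, padded.shape[1] // block
        means = padded.reshape(hb, block, wb, block).mean(axis=(1, 3))
        blocky = np.repeat(np.repeat(means, block, axis=0), block, axis=1)[:h, :w]
        a = min(spec.level, 1.0)
        out = (1.0 - a) * arr + a * blocky
    return np.clip(out, 0.0, 1.0)


def make_video(
    base, n_frames: int = 8, motion: str = "static", fps: float = 30.0, shift: int = 1
) -> VideoSequence:
    """Video from a base frame: identical frames, or a wrap-around pan."""
    if n_frames < 1:
        raise InvalidParameterError(f"n_frames must be >= 1, got {n_frames}")
    if motion not in ("static", "pan"):
        raise InvalidParameterError(f"unknown motion {motion!r}")
    arr = np.asarray(base, dtype=np.float64)
    if motion == "static":
        frames = [arr.copy() for _ in range(n_frames)]
    else:
        frames = [np.roll(arr, i * shift, axis=1) for i in range(n_frames)]
    return VideoSequence(frames=frames, fps=fps)


# Orientation of the planted opinion scores: a *decreasing* logistic of the
# metric (larger distance -> lower opinion), like real MOS data.
_MOS_HIGH = 5.0
_MOS_LOW = 1.0


def make_scored_dataset(
    n_contents: int = 3,
    levels: int = 4,
    planted_params: INRFParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    size: int = 48,
):
    """Scored image-pair dataset with a planted metric-opinion relationship.

    References are ``filtered_noise`` images; each content is distorted by a
    cycling distortion kind at ``levels`` increasing strengths.  Subjective
    scores are a fixed monotone-decreasing four-parameter logistic of the
    metric value under ``planted_params``, plus seeded Gaussian noise.

    Returns ``(pairs, subjective)`` where ``pairs`` is a list of
    ``(reference, distorted)`` arrays.
    """
    if n_contents < 2 or levels < 2:
        raise InvalidParameterError("need n_contents >= 2 and levels >= 2")
    planted_params = planted_params or INRFParams()
    rng = np.random.default_rng(seed)

    level_grids = {
        "gaussian_noise": np.linspace(0.03, 0.25, levels),
        "gaussian_blur": np.linspace(0.6, 4.0, levels),
        "contrast_change": np.linspace(0.5, 4.0, levels),
        "quantization": 1.0 / np.linspace(24, 3, levels),
        "block_artifact": np.linspace(0.25, 1.0, levels),
    }
    kinds = list(level_grids)

    pairs = []
    for c in range(n_contents):
        ref = make_image("filtered_noise", size=size, seed=1000 + c)
        kind = kinds[c % len(kinds)]
        for i, lvl in enumerate(level_grids[kind]):
            spec = DistortionSpec(kind=kind, level=float(lvl), seed=2000 + 10 * c + i)
            pairs.append((ref, apply_distortion(ref, spec)))

    metric = np.array([inrf_iqa(r, d, planted_params) for r, d in pairs])
    beta = Logistic4Params(
        beta1=_MOS_LOW,
        beta2=_MOS_HIGH,
        beta3=float(np.median(metric)),
        beta4=float(np.std(metric)) or 1.0,
    )
    subjective = logistic4(metric, beta)
    if noise_sd > 0:
        subjective = subjective + rng.normal(0.0, noise_sd, size=subjective.shape)
    return pairs, subjective


# ---------------------------------------------------------------------------
# Fixture writers (plain-text-friendly formats: PNG frames, Y4M)
# ---------------------------------------------------------------------------


def _to_uint8(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.dtype == np.uint8:
        return arr
    return np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)


def save_frames(video: VideoSequence, directory, prefix: str = "") -> list:
    """Write frames as zero-padded numbered PNGs; returns the paths."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(video.frames):
        p = directory / f"{prefix}{i:05d}.png"
        iio.imwrite(p, _to_uint8(frame))
        paths.append(p)
    return paths


def write_y4m(video: VideoSequence, path) -> None:
    """Write grayscale frames as a YUV4MPEG2 (C420, neutral chroma) stream."""
    path = Path(path)
    h, w = video.height, video.width
    if h % 2 or w % 2:
        raise InvalidParameterError("Y4M C420 requires even frame dimensions")
    fps_num = int(round(video.fps * 1000))
    header = f"YUV4MPEG2 W{w} H{h} F{fps_num}:1000 Ip A1:1 C420jpeg\n"
    chroma = np.full(((h // 2) * (w // 2),), 128, dtype=np.uint8).tobytes()
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for frame in video.frames:
            y = _to_uint8(np.asarray(frame)[..., 0] if np.asarray(frame).ndim == 3 else frame)
            fh.write(b"FRAME\n")
            fh.write(y.tobytes())
            fh.write(chroma)
            fh.write(chroma)
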