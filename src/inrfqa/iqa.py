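"""Full-reference image quality metric.

Both images are mapped through the nonlinear receptive-field transform and
compared by mean squared error in the transformed domain:

    score(I_ref, I_dist) = MSE(O_ref, O_dist)

Higher scores mean larger perceptual distance (worse quality).
"""

from __future__ import annotations

import numpy as np

from ._exceptions import InvalidInputError, ShapeMismatchError
from .core import INRFParams, inrf_transform, inrf_transform_naive

__all__ = ["to_luminance", "inrf_iqa", "load_image"]

# Rec. 601 luma coefficients; the conventional choice for legacy IQA datasets.
_LUMA601 = np.array([0.299, 0.587, 0.114])
# Rec. 709 / sRGB relative-luminance coefficients (applied on gamma-encoded
# channels here, i.e. Rec. 709 luma; exposed as the "y" alternative).
_LUMA709 = np.array([0.2126, 0.7152, 0.0722])


def _rescale(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def to_luminance(image, standard: str = "luma601") -> np.ndarray:
    """Reduce a 1- or 3-channel image to a [0, 1] luminance plane.

    8-bit (and 16-bit) integer inputs are rescaled; float inputs are assumed
    to already lie in [0, 1].  3-channel input is combined with Rec. 601 luma
    weights by default (``standard="y"`` selects Rec. 709 weights).
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim == 2:
        return _rescale(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = _rescale(arr[:, :, :3])
        if standard == "luma601":
            coeff = _LUMA601
        elif standard == "y":
            coeff = _LUMA709
        else:
            raise InvalidInputError(f"unknown luminance standard {standard!r}")
        return rgb @ coeff
    raise InvalidInputError(
        f"expected a 2D grayscale or HxWx3 color image, got shape {arr.shape}"
    )


def inrf_iqa(
    ref,
    dist,
    params: INRFParams | None = None,
    *,
    luminance: str = "luma601",
    exact: bool = False,
    root: bool = False,
) -> float:
    """Perceptual distance between a reference image and a distorted one.

    Parameters
    ----------
    ref, dist
        Aligned images of identical shape (grayscale or RGB).  No resizing or
        registration is attempted; a shape mismatch raises.
    params
        Transform parameters; defaults to the published optimum.
    exact
        Use the naive per-pixel transform instead of the level-set fast path.
    root
        Return RMSE instead of MSE.  Rank correlations are invariant to the
        choice; MSE is the default definition.
    """
    params = params or INRFParams()
    a = np.asarray(ref)
    b = np.asarray(dist)
    if a.shape != b.shape:
        raise ShapeMismatchError(
            f"reference shape {a.shape} != distorted shape {b.shape}"
        )
    lum_ref = to_luminance(a, standard=luminance)
    lum_dist = to_luminance(b, standard=luminance)
    transform = inrf_transform_naive if exact else inrf_transform
    o_ref = transform(lum_ref, params)
    o_dist = transform(lum_dist, params)
    mse = float(np.mean((o_ref - o_dist) ** 2))
    return float(np.sqrt(mse)) if root else mse


def load_image(path) -> np.ndarray:
    """Read an image file (PNG/PGM/BMP/TIFF/...) as a numpy array."""
    import imageio.v3 as iio

    try:
        return iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc
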