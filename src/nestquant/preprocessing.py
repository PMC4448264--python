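"""Image preprocessing and stain separation for HE histopathology frames.

The preprocessing chain is median denoising (3x3), percentile contrast
stretching, and color normalization against a reference image, followed by
Beer-Lambert color deconvolution into hematoxylin and eosin optical-density
(OD) channels.  All operations are deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage import color as skcolor

logger = logging.getLogger(__name__)

#: Unit-norm HE stain OD vectors (rows: hematoxylin, eosin, residual).
#: Standard published values; the residual is the normalized cross product.
HE_STAIN_MATRIX = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.072, 0.990, 0.105],
        [0.0, 0.0, 0.0],  # filled below
    ]
)
_res = np.cross(HE_STAIN_MATRIX[0], HE_STAIN_MATRIX[1])
HE_STAIN_MATRIX[2] = _res / np.linalg.norm(_res)
HE_STAIN_MATRIX[0] /= np.linalg.norm(HE_STAIN_MATRIX[0])
HE_STAIN_MATRIX[1] /= np.linalg.norm(HE_STAIN_MATRIX[1])

#: Intensity floor for the log transform: 8-bit intensities are treated as
#: lying in [1, 255], capping the representable OD at log10(255) per channel
#: so saturated-black pixels cannot produce unbounded densities.
_I_MIN = 1.0


@dataclass
class StainChannels:
    """Per-stain optical densities from color deconvolution.

    Attributes
    ----------
    hematoxylin_od, eosin_od : (H, W) float arrays, nonnegative.
    residual_od : (H, W) float array, third (residual) channel.
    stain_matrix : (3, 3) array of unit-norm stain OD vectors (rows).
    """

    hematoxylin_od: np.ndarray
    eosin_od: np.ndarray
    residual_od: np.ndarray
    stain_matrix: np.ndarray


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if image.shape[0] < 16 or image.shape[1] < 16:
        raise ValueError("image smaller than 16 x 16 px")
    return image


def median_filter_3x3(image: np.ndarray) -> np.ndarray:
    """Per-channel 3x3 median filter with edge replication at borders."""
    image = _check_rgb(image)
    out = np.empty_like(image)
    for c in range(3):
        out[..., c] = median_filter(image[..., c], size=3, mode="nearest")
    return out


def contrast_stretch(
    image: np.ndarray, p_low: float = 1.0, p_high: float = 99.0
) -> np.ndarray:
    """Linear per-channel rescale mapping percentiles to the full 8-bit range.

    The ``p_low`` percentile maps to 0 and ``p_high`` to 255; values outside
    are clipped.  A constant channel is returned unchanged with a warning.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError("require 0 <= p_low < p_high <= 100")
    image = _check_rgb(image)
    out = np.empty_like(image, dtype=np.uint8)
    for c in range(3):
        ch = image[..., c].astype(float)
        lo, hi = np.percentile(ch, [p_low, p_high])
        if hi <= lo:
            warnings.warn(f"channel {c} is constant at percentiles; left unchanged")
            out[..., c] = image[..., c]
            continue
        stretched = (ch - lo) * (255.0 / (hi - lo))
        out[..., c] = np.clip(np.rint(stretched), 0, 255).astype(np.uint8)
    return out


def color_normalize(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Match per-channel Lab mean/std of ``image`` to ``reference``.

    Reinhard-style statistics transfer in CIELAB: each Lab channel of the
    image is z-scored and re-expressed with the reference channel's mean and
    standard deviation, then converted back to 8-bit RGB.  Idempotent when
    ``image is reference`` up to rounding.
    """
    image = _check_rgb(image)
    reference = _check_rgb(reference)
    lab = skcolor.rgb2lab(image)
    ref_lab = skcolor.rgb2lab(reference)
    out = np.empty_like(lab)
    for c in range(3):
        mu, sd = lab[..., c].mean(), lab[..., c].std()
        rmu, rsd = ref_lab[..., c].mean(), ref_lab[..., c].std()
        if rsd <= 1e-9:
            raise ValueError(f"reference Lab channel {c} has zero variance")
        if sd <= 1e-9:
            # degenerate source channel: shift only
            out[..., c] = lab[..., c] - mu + rmu
        else:
            out[..., c] = (lab[..., c] - mu) * (rsd / sd) + rmu
    rgb = skcolor.lab2rgb(out)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Beer-Lambert absorbance: OD = -log10(I / 255) per channel."""
    arr = np.maximum(np.asarray(image, dtype=float), _I_MIN)
    return -np.log10(arr / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, back to 8-bit intensities."""
    return np.clip(np.rint(255.0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)


def color_deconvolve(
    image: np.ndarray, stain_matrix: np.ndarray | None = None
) -> StainChannels:
    """Unmix an RGB image into per-stain optical densities.

    Solves OD = C @ M for stain concentrations C, where rows of M are the
    unit-norm stain OD vectors.  Negative densities (numerical leakage into
    the wrong stain) are clipped to zero.
    """
    image = _check_rgb(image)
    M = HE_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix, float)
    if M.shape != (3, 3):
        raise ValueError("stain matrix must be 3 x 3")
    if abs(np.linalg.det(M)) < 1e-8:
        raise ValueError("singular stain matrix")
    od = rgb_to_od(image).reshape(-1, 3)
    conc = od @ np.linalg.inv(M)
    conc = np.clip(conc, 0.0, None).reshape(image.shape)
    return StainChannels(
        hematoxylin_od=conc[..., 0],
        eosin_od=conc[..., 1],
        residual_od=conc[..., 2],
        stain_matrix=M,
    )


def reconstruct_rgb(channels: StainChannels) -> np.ndarray:
    """Render stain concentrations back to RGB via Beer-Lambert."""
    conc = np.stack(
        [channels.hematoxylin_od, channels.eosin_od, channels.residual_od], axis=-1
    )
    od = conc.reshape(-1, 3) @ channels.stain_matrix
    return od_to_rgb(od.reshape(conc.shape))


def preprocess(
    image: np.ndarray,
    reference: np.ndarray | None = None,
    p_low: float = 1.0,
    p_high: float = 99.0,
) -> np.ndarray:
    """Full preprocessing chain: median filter, contrast stretch, optional
    color normalization against ``reference``."""
    out = median_filter_3x3(image)
    out = contrast_stretch(out, p_low, p_high)
    if reference is not None:
        out = color_normalize(out, reference)
    return out
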