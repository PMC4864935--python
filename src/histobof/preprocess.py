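"""RGB histology image -> masked, equalized haematoxylin-intensity image.

The preprocessing chain mirrors routine whole-slide handling: a Gaussian
pyramid brings a 40x scan down to a 2.5x-equivalent working resolution
(4 pyramid levels, factor 16 per axis), tissue is located by adaptive
thresholding of the green channel followed by morphological clean-up, and the
haematoxylin channel is separated by colour deconvolution in optical-density
space (Ruifrok & Johnston stain vectors).  Contrast is finally adjusted with
contrast-limited adaptive histogram equalization (CLAHE).

All downstream texture analysis operates on the resulting H-image only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure, filters, morphology

from .exceptions import DegenerateInputError

# Standard Ruifrok & Johnston H&E optical-density unit vectors (R, G, B).
# The residual axis completes an invertible basis (normalized cross product).
STAIN_H = np.array([0.650, 0.704, 0.286])
STAIN_E = np.array([0.072, 0.990, 0.105])


def _stain_matrix() -> np.ndarray:
    h = STAIN_H / np.linalg.norm(STAIN_H)
    e = STAIN_E / np.linalg.norm(STAIN_E)
    r = np.cross(h, e)
    r /= np.linalg.norm(r)
    return np.stack([h, e, r])  # rows: stain OD unit vectors


#: 3x3 matrix whose rows are the H, E and residual OD unit vectors.
HE_STAIN_MATRIX = _stain_matrix()

#: epsilon added to 8-bit intensities before the log, in intensity levels
OD_EPS = 1.0

#: optical density of the darkest representable pixel, used to scale
#: haematoxylin concentration into [0, 1]
OD_MAX = float(-np.log10(OD_EPS / 255.0))


@dataclasses.dataclass
class HImage:
    """Single-channel haematoxylin-intensity image at working resolution.

    Attributes
    ----------
    intensity
        Float raster in [0, 1]; higher = more haematoxylin (darker nuclei).
    mask
        Boolean tissue mask of the same shape; background pixels of
        ``intensity`` are held at 0.
    scale_factor
        Total downsampling factor applied relative to the source image.
    """

    intensity: np.ndarray
    mask: np.ndarray
    scale_factor: int = 1

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.shape != self.mask.shape:
            raise DegenerateInputError("intensity and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def masked(self) -> "HImage":
        """Return a copy with background pixels forced to 0."""
        out = self.intensity.copy()
        out[~self.mask] = 0.0
        return HImage(out, self.mask, self.scale_factor)


def downscale_pyramid(img: np.ndarray, levels: int) -> np.ndarray:
    """Gaussian-pyramid downscaling by ``levels`` halvings.

    Each level Gaussian-smooths the image (sigma = 1 px) and subsamples every
    other pixel; output dimensions are floor(d / 2) per level.  Four levels
    turn a 40x scan into its 2.5x equivalent (factor 16 per axis).
    """
    if levels < 0:
        raise DegenerateInputError("levels must be >= 0")
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h < 2**levels or w < 2**levels:
        raise DegenerateInputError(
            f"image {h}x{w} smaller than 2^{levels} in some dimension"
        )
    if levels == 0:
        return img.copy()
    was_int = np.issubdtype(img.dtype, np.integer)
    out = img.astype(float)
    for _ in range(levels):
        if out.ndim == 3:
            sm = ndi.gaussian_filter(out, sigma=(1.0, 1.0, 0.0), mode="reflect")
        else:
            sm = ndi.gaussian_filter(out, sigma=1.0, mode="reflect")
        hh, ww = sm.shape[:2]
        out = sm[0 : 2 * (hh // 2) : 2, 0 : 2 * (ww // 2) : 2]
    if was_int:
        out = np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out


def tissue_mask(
    img: np.ndarray,
    block_size: int = 65,
    offset: float = 10.0,
    erosion_radius: int = 13,
    min_size: int = 500,
) -> np.ndarray:
    """Locate tissue in an RGB image at 2.5x-equivalent scale.

    Pipeline (order fixed): local-mean adaptive threshold on the green channel
    (pixels darker than local mean − offset are candidate tissue) →
    binary erosion with a disk of radius ``erosion_radius`` → hole filling →
    removal of objects below ``min_size`` pixels.
    """
    img = np.asarray(img)
    green = img[..., 1].astype(float) if img.ndim == 3 else img.astype(float)
    thr = filters.threshold_local(green, block_size=block_size, method="mean", offset=offset)
    mask = green < thr
    mask = ndi.binary_erosion(mask, structure=morphology.disk(erosion_radius).astype(bool))
    mask = ndi.binary_fill_holes(mask)
    labelled, n = ndi.label(mask)
    sizes = np.bincount(labelled.ravel())
    keep = np.flatnonzero(sizes >= min_size)
    mask = np.isin(labelled, keep[keep > 0])
    return mask


def separate_stains(img: np.ndarray, eps: float = OD_EPS) -> np.ndarray:
    """Colour deconvolution: 8-bit RGB -> (H, E, residual) concentrations.

    Per pixel the optical density OD = −log10((v + eps) / 255) is projected
    onto the H&E stain basis; concentrations are linear in OD space, so a
    pixel whose OD vector equals the unit haematoxylin vector has H
    concentration 1.
    """
    rgb = np.asarray(img, dtype=float)
    od = -np.log10((rgb + eps) / 255.0)
    return od @ np.linalg.inv(HE_STAIN_MATRIX)


def reconstruct_rgb(concentrations: np.ndarray, eps: float = OD_EPS) -> np.ndarray:
    """Invert :func:`separate_stains`: concentrations -> 8-bit RGB."""
    od = np.asarray(concentrations, dtype=float) @ HE_STAIN_MATRIX
    v = 255.0 * 10.0 ** (-od) - eps
    return np.clip(np.rint(v), 0, 255).astype(np.uint8)


def deconvolve_haematoxylin(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    eps: float = OD_EPS,
    scale_factor: int = 1,
) -> HImage:
    """Extract the haematoxylin channel as an :class:`HImage` in [0, 1].

    The H concentration is clipped to [0, OD_MAX] and divided by OD_MAX so
    that a pure-white pixel maps to 0 and the darkest representable
    full-haematoxylin pixel maps to 1.
    """
    conc = separate_stains(img, eps=eps)
    h = np.clip(conc[..., 0], 0.0, OD_MAX) / OD_MAX
    if mask is None:
        mask = np.ones(h.shape, dtype=bool)
    h = h.copy()
    h[~mask] = 0.0
    return HImage(h, mask, scale_factor)


def equalize_adaptive(
    him: HImage, clip_limit: float = 0.01, ntiles: int = 8
) -> HImage:
    """Contrast-limited adaptive histogram equalization of an H-image.

    CLAHE runs over an ``ntiles`` x ``ntiles`` tile grid with the given clip
    limit; background pixels are re-masked to 0 afterwards, so equalization
    sees the full raster but the output honours the tissue mask.
    """
    h, w = him.shape
    kernel = (max(1, h // ntiles), max(1, w // ntiles))
    eq = exposure.equalize_adapthist(
        np.clip(him.intensity, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit
    )
    eq[~him.mask] = 0.0
    return HImage(eq, him.mask, him.scale_factor)


def preprocess_image(
    img: np.ndarray,
    levels: int = 4,
    mask_mode: str = "adaptive",
    clip_limit: float = 0.01,
) -> HImage:
    """Full preprocessing chain: downscale -> mask -> deconvolve -> equalize.

    ``mask_mode='full'`` treats every pixel as tissue (useful for synthetic
    images that have no background).
    """
    small = downscale_pyramid(img, levels)
    if mask_mode == "full":
        mask = np.ones(small.shape[:2], dtype=bool)
    elif mask_mode == "adaptive":
        mask = tissue_mask(small)
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    him = deconvolve_haematoxylin(small, mask=mask, scale_factor=2**levels)
    return equalize_adaptive(him, clip_limit=clip_limit)
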