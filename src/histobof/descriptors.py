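"""Gabor filter bank and 48-value local texture descriptors.

Each w x w neighbourhood of the H-image is convolved with a bank of 24
complex Gabor wavelets

    G(x, y; nu, theta, sigma) = exp(-(x^2 + y^2) / (2 sigma^2))
                                * exp(2 pi nu j (x cos theta + y sin theta))

with an isotropic Gaussian envelope (no coordinate rotation inside the
Gaussian) and no DC correction — the equation is implemented exactly as
stated.  The default parameter grid sigma in {1, 2*sqrt(2)}, theta in
{0, pi/4, pi/2, 3pi/4}, nu in {3/4, 3/8, 3/16} yields 24 filters.  For every
filter the mean and standard deviation of the response magnitude over the
patch are recorded, giving a 48-value descriptor (24 means then 24 SDs).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import DegenerateInputError, EmptyTissueError, ParameterError
from .preprocess import HImage

DEFAULT_SIGMAS: tuple[float, ...] = (1.0, 2.0 * math.sqrt(2.0))
DEFAULT_THETAS: tuple[float, ...] = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
DEFAULT_NUS: tuple[float, ...] = (3 / 4, 3 / 8, 3 / 16)


class GaborParams(NamedTuple):
    nu: float
    theta: float
    sigma: float


def gabor_kernel(
    nu: float, theta: float, sigma: float, halfwidth: int | None = None
) -> np.ndarray:
    """Complex Gabor kernel sampled on x, y in [-halfwidth, halfwidth].

    ``halfwidth`` defaults to ceil(3 sigma), beyond which the Gaussian
    envelope is effectively zero.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    min_hw = math.ceil(3 * sigma)
    if halfwidth is None:
        halfwidth = min_hw
    elif halfwidth < min_hw:
        raise ParameterError(f"halfwidth must be >= ceil(3*sigma) = {min_hw}")
    coords = np.arange(-halfwidth, halfwidth + 1)
    x, y = np.meshgrid(coords, coords)  # x varies along columns, y along rows
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    phase = np.exp(2j * np.pi * nu * (x * np.cos(theta) + y * np.sin(theta)))
    return envelope * phase


@dataclasses.dataclass
class GaborBank:
    """Ordered bank of complex Gabor kernels (sigma-major, then theta, then nu)."""

    kernels: list[np.ndarray]
    params: list[GaborParams]

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def descriptor_length(self) -> int:
        return 2 * len(self.kernels)


def build_bank(
    sigmas: Sequence[float] = DEFAULT_SIGMAS,
    thetas: Sequence[float] = DEFAULT_THETAS,
    nus: Sequence[float] = DEFAULT_NUS,
    halfwidth: int | None = None,
) -> GaborBank:
    """Build the Gabor bank over the Cartesian parameter grid.

    The deterministic ordering is sigma-major, then theta, then nu; the
    default grid gives exactly 24 filters.
    """
    if len(sigmas) == 0 or len(thetas) == 0 or len(nus) == 0:
        raise ParameterError("parameter sets must be non-empty")
    kernels, params = [], []
    for sigma in sigmas:
        for theta in thetas:
            for nu in nus:
                kernels.append(gabor_kernel(nu, theta, sigma, halfwidth))
                params.append(GaborParams(nu, theta, sigma))
    return GaborBank(kernels, params)


def describe_patches(
    patches: np.ndarray, bank: GaborBank, reduction: str = "magnitude"
) -> np.ndarray:
    """Descriptors for a stack of patches, shape (n, w, w) -> (n, 2*|bank|).

    Each patch is convolved ('same' size, reflective padding) with every
    kernel; the mean and population SD of the reduced response form the
    descriptor, ordered as all means then all SDs.  ``reduction`` selects how
    the complex response is reduced: ``"magnitude"`` (default; phase-invariant
    texture energy) or ``"real"`` (the real part; exactly invariant in SD to
    constant intensity shifts).
    """
    if reduction not in ("magnitude", "real"):
        raise ParameterError("reduction must be 'magnitude' or 'real'")
    patches = np.asarray(patches, dtype=float)
    if patches.ndim == 2:
        patches = patches[None]
    n, h, w = patches.shape
    if h < 4 or w < 4:
        raise DegenerateInputError("patches must be at least 4 px in each dimension")
    nk = len(bank)
    means = np.empty((n, nk))
    sds = np.empty((n, nk))
    for i, kernel in enumerate(bank.kernels):
        hw = (kernel.shape[0] - 1) // 2
        padded = np.pad(patches, ((0, 0), (hw, hw), (hw, hw)), mode="reflect")
        resp = fftconvolve(padded, kernel[None, :, :], mode="valid", axes=(1, 2))
        red = np.abs(resp) if reduction == "magnitude" else resp.real
        means[:, i] = red.mean(axis=(1, 2))
        sds[:, i] = red.std(axis=(1, 2))
    return np.hstack([means, sds])


def patch_descriptor(
    patch: np.ndarray, bank: GaborBank, reduction: str = "magnitude"
) -> np.ndarray:
    """48-value descriptor (24 means, 24 SDs) of a single patch."""
    return describe_patches(np.asarray(patch)[None], bank, reduction)[0]


def descriptor_names(bank: GaborBank) -> list[str]:
    nk = len(bank)
    return [f"m_{i:02d}" for i in range(nk)] + [f"s_{i:02d}" for i in range(nk)]


def _window_tissue_fraction(mask: np.ndarray, w: int) -> np.ndarray:
    """Tissue fraction of every w x w window via a summed-area table."""
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1))
    ii[1:, 1:] = np.cumsum(np.cumsum(mask.astype(float), axis=0), axis=1)
    s = ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w]
    return s / (w * w)


def sample_patches(
    him: HImage,
    n: int = 3000,
    w: int = 32,
    min_tissue_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample up to ``n`` random w x w patches from the tissue region.

    Patch origins are drawn uniformly without replacement among windows whose
    tissue fraction is at least ``min_tissue_fraction``; reproducible under
    ``seed``.  Returns (patches, origins) where origins are 0-based (row, col)
    top-left corners.  A warning is emitted if fewer than ``n`` admissible
    windows exist.
    """
    h, wid = him.shape
    if h < w or wid < w:
        raise DegenerateInputError(f"image {h}x{wid} smaller than patch size {w}")
    frac = _window_tissue_fraction(him.mask, w)
    rows, cols = np.nonzero(frac >= min_tissue_fraction)
    if rows.size == 0:
        raise EmptyTissueError("no admissible tissue window in image")
    if rows.size < n:
        warnings.warn(
            f"only {rows.size} admissible windows for {n} requested patches",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    take = min(n, rows.size)
    idx = rng.choice(rows.size, size=take, replace=False)
    origins = np.stack([rows[idx], cols[idx]], axis=1)
    patches = np.stack([him.intensity[r : r + w, c : c + w] for r, c in origins])
    return patches, origins
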