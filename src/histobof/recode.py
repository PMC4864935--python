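"""Recode an H-image against a codebook into the 6K representation.

The image is tiled into non-overlapping w x w tiles; each tissue tile is
assigned the nearest codeblock in descriptor space.  The representation
concatenates the K codeblock relative frequencies (the standard
bag-of-features histogram) with, for each codeblock, five statistics of the
spatial distribution of its assigned regions: the binary image of tiles
assigned to codeblock k is decomposed into 4-connected components, and over
the component areas we take the median, the maximum, the ratio of maximum to
total area, the skewness, and the mean compactness (perimeter^2 / area).
Areas and perimeters are measured on the tile grid (1 unit = one tile);
the perimeter is the count of exposed unit edges.

Total length: 6K per image (K frequencies + 5K spatial statistics).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial.distance import cdist
from scipy.stats import skew

from .codebook import Codebook
from .descriptors import GaborBank, build_bank, describe_patches
from .exceptions import DegenerateInputError
from .preprocess import HImage

#: 4-neighbour connectivity structure for component labelling
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: names of the five spatial statistics, in representation order
EXT_STAT_NAMES = ("med_area", "max_area", "max_ratio", "skew", "compact")


@dataclasses.dataclass
class CodeblockMap:
    """Per-tile codeblock assignment: labels in {1..K}, background = -1."""

    labels: np.ndarray
    w: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


@dataclasses.dataclass
class RegionStats:
    """Areas and compactness indices of one codeblock's connected regions."""

    areas: np.ndarray
    compactness: np.ndarray


@dataclasses.dataclass
class ImageRepresentation:
    """The 6K feature vector of one image: frequencies + K x 5 extension."""

    image_id: str
    frequencies: np.ndarray
    ext: np.ndarray  # K x 5, columns ordered as EXT_STAT_NAMES
    category: str = ""

    @property
    def K(self) -> int:
        return len(self.frequencies)

    @property
    def values(self) -> np.ndarray:
        """Length-6K vector: frequencies, then per-statistic blocks."""
        return np.concatenate([self.frequencies, self.ext.T.ravel()])

    def feature_names(self) -> list[str]:
        width = max(2, len(str(self.K)))
        blocks = [f"C.{i + 1:0{width}d}" for i in range(self.K)]
        names = [f"freq_{b}" for b in blocks]
        for stat in EXT_STAT_NAMES:
            names.extend(f"{stat}_{b}" for b in blocks)
        return names

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.feature_names(),
                         name=self.image_id)


def label_image(
    him: HImage,
    cb: Codebook,
    w: int = 32,
    bank: GaborBank | None = None,
    min_tissue_fraction: float = 0.5,
) -> CodeblockMap:
    """Assign every tissue tile of the image to its nearest codeblock.

    The image is split into non-overlapping w x w tiles; tiles with at least
    ``min_tissue_fraction`` of mask pixels are described with the Gabor bank
    and labelled with the index (1-based) of the nearest center in squared
    Euclidean distance (ties -> lowest index); other tiles get -1.
    """
    h, wid = him.shape
    nr, nc = h // w, wid // w
    if nr < 1 or nc < 1:
        raise DegenerateInputError(f"image {h}x{wid} smaller than one {w}x{w} tile")
    if bank is None:
        bank = build_bank()
    labels = np.full((nr, nc), -1, dtype=int)
    tiles, pos = [], []
    for r in range(nr):
        for c in range(nc):
            sl = (slice(r * w, (r + 1) * w), slice(c * w, (c + 1) * w))
            if him.mask[sl].mean() >= min_tissue_fraction:
                tiles.append(him.intensity[sl])
                pos.append((r, c))
    if tiles:
        desc = describe_patches(np.stack(tiles), bank)
        d2 = cdist(desc, cb.centers, metric="sqeuclidean")
        nearest = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
        for (r, c), k in zip(pos, nearest):
            labels[r, c] = int(k) + 1
    return CodeblockMap(labels, w)


def codeblock_histogram(cm: CodeblockMap, K: int) -> np.ndarray:
    """Relative codeblock frequencies over tissue tiles (sum 1, or all 0)."""
    tissue = cm.labels[cm.labels > 0]
    counts = np.bincount(tissue, minlength=K + 1)[1 : K + 1].astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


def _object_perimeters(labelled: np.ndarray, n_obj: int) -> np.ndarray:
    """Exposed-unit-edge perimeter of each labelled object on the grid."""
    perims = np.zeros(n_obj)
    for axis in (0, 1):
        a = labelled
        b = np.roll(labelled, -1, axis=axis)
        # interior adjacencies within the same object (exclude wrap-around)
        sl = [slice(None), slice(None)]
        sl[axis] = slice(0, -1)
        same = (a[tuple(sl)] == b[tuple(sl)]) & (a[tuple(sl)] > 0)
        adj = np.bincount(a[tuple(sl)][same], minlength=n_obj + 1)[1:]
        perims -= 2 * adj
    areas = np.bincount(labelled.ravel(), minlength=n_obj + 1)[1:]
    perims += 4 * areas
    return perims


def region_stats(cm: CodeblockMap, k: int) -> RegionStats:
    """Per-object area and compactness for codeblock ``k`` (1-based).

    4-connected components of the binary tile map define the objects; area is
    the tile count, the perimeter counts exposed unit edges, and compactness
    is perimeter^2 / area (16 for a single tile or any solid square).
    """
    binary = cm.labels == k
    labelled, n_obj = ndi.label(binary, structure=FOUR_CONN)
    if n_obj == 0:
        return RegionStats(np.array([]), np.array([]))
    areas = np.bincount(labelled.ravel(), minlength=n_obj + 1)[1:].astype(float)
    perims = _object_perimeters(labelled, n_obj)
    return RegionStats(areas, perims**2 / areas)


def extended_features(rs: RegionStats) -> np.ndarray:
    """The five spatial statistics of one codeblock's regions.

    (median area, max area, max/total area ratio, skewness of areas, mean
    compactness); skewness is the adjusted Fisher-Pearson sample coefficient,
    defined as 0 when fewer than 3 objects or zero variance; an absent
    codeblock yields all zeros.
    """
    areas = np.asarray(rs.areas, dtype=float)
    if areas.size == 0:
        return np.zeros(5)
    if areas.size >= 3 and np.var(areas) > 0:
        sk = float(skew(areas, bias=False))
    else:
        sk = 0.0
    return np.array([
        float(np.median(areas)),
        float(areas.max()),
        float(areas.max() / areas.sum()),
        sk,
        float(np.mean(rs.compactness)),
    ])


def representation_from_map(
    cm: CodeblockMap, K: int, image_id: str = ""
) -> ImageRepresentation:
    """Build the 6K representation from a codeblock assignment map."""
    freqs = codeblock_histogram(cm, K)
    ext = np.stack([extended_features(region_stats(cm, k + 1)) for k in range(K)])
    return ImageRepresentation(image_id, freqs, ext)


def recode_image(
    him: HImage,
    cb: Codebook,
    w: int = 32,
    bank: GaborBank | None = None,
    image_id: str = "",
    min_tissue_fraction: float = 0.5,
) -> ImageRepresentation:
    """Full recoding: tile assignment -> histogram + spatial statistics (6K)."""
    cm = label_image(him, cb, w=w, bank=bank,
                     min_tissue_fraction=min_tissue_fraction)
    return representation_from_map(cm, cb.K, image_id=image_id)


def representation_frame(reps: Sequence[ImageRepresentation]) -> pd.DataFrame:
    """Stack representations into an images x 6K feature DataFrame."""
    return pd.DataFrame([r.to_series() for r in reps])
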