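"""Codebook learning and size selection via the Psi(K) objective.

A codebook is the set of K cluster centers from k-means clustering of patch
descriptors.  Its size K is chosen to maximize

    Psi(K) = log(n_c (n_c - 1) / 2) - log J(K) - log sqrt(D(K)) - 0.75 log K

where, over a corpus of reference tissue-category images, J(K) is the total
Jaccard index of codeblock-usage sets between images of different categories,
D(K) is the total within-cluster sum of squared distances of the k-means fit,
and n_c is the number of reference categories.  Maximizing Psi favours a
representation in which categories share few codeblocks (small J), clusters
are tight (small D) and the codebook is sparse (the 0.75 log K penalty).
All logarithms are natural.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .exceptions import DataError, ParameterError

#: floor applied to J or D inside psi to keep the objective finite at
#: perfect separation
PSI_FLOOR = 1e-12


@dataclasses.dataclass
class Codebook:
    """K cluster centers in descriptor space with fit provenance.

    Row ``i`` of ``centers`` is codeblock ``C.{i+1:02d}`` (1-based index).
    """

    centers: np.ndarray
    K: int
    seed: int
    params: dict = dataclasses.field(default_factory=dict)
    assignments: np.ndarray | None = None
    inertia: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.K < 1:
            raise ParameterError("K must be >= 1")
        if self.centers.shape[0] != self.K:
            raise ParameterError("centers row count must equal K")
        if not np.all(np.isfinite(self.centers)):
            raise DataError("codebook centers must be finite")

    def codeblock_names(self) -> list[str]:
        width = max(2, len(str(self.K)))
        return [f"C.{i + 1:0{width}d}" for i in range(self.K)]

    def save(self, stem: str | Path) -> None:
        """Serialize as <stem>.json (provenance) + <stem>.csv (centers)."""
        stem = Path(stem)
        meta = {"K": self.K, "seed": self.seed, "params": self.params,
                "inertia": self.inertia}
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame(self.centers, index=self.codeblock_names()).to_csv(
            stem.with_suffix(".csv")
        )

    @classmethod
    def load(cls, stem: str | Path) -> "Codebook":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        centers = pd.read_csv(stem.with_suffix(".csv"), index_col=0).to_numpy()
        return cls(centers, meta["K"], meta["seed"], meta.get("params", {}),
                   inertia=meta.get("inertia"))


@dataclasses.dataclass(frozen=True)
class CodingSet:
    """The set of codeblocks (1-based indices) used in coding one image."""

    image_id: str
    category: str
    used: frozenset[int]


@dataclasses.dataclass
class PsiCurve:
    """Psi(K) evaluation over a grid of codebook sizes."""

    grid: np.ndarray
    J: np.ndarray
    D: np.ndarray
    psi: np.ndarray
    n_c: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.grid, "J": self.J, "D": self.D,
                             "psi": self.psi})


def fit_codebook(
    descriptors: np.ndarray,
    K: int,
    seed: int,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> Codebook:
    """Vector-quantize descriptors with k-means (k-means++ seeding).

    Deterministic under ``seed``; 10 random restarts by default; descriptors
    are clustered raw (no standardization).
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2:
        raise ParameterError("descriptors must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise DataError("descriptors must be finite")
    if X.shape[0] < K:
        raise ParameterError(f"need at least K={K} descriptors, got {X.shape[0]}")
    km = KMeans(
        n_clusters=K, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=seed,
    ).fit(X)
    return Codebook(
        centers=km.cluster_centers_, K=K, seed=seed,
        params={"n_init": n_init, "max_iter": max_iter, "tol": tol},
        assignments=km.labels_, inertia=float(km.inertia_),
    )


def coding_set(rep, threshold: float = 0.0) -> CodingSet:
    """Codeblocks used in coding an image: frequency strictly above threshold."""
    freqs = np.asarray(rep.frequencies, dtype=float)
    used = frozenset(int(j + 1) for j in np.nonzero(freqs > threshold)[0])
    return CodingSet(image_id=rep.image_id, category=getattr(rep, "category", ""),
                     used=used)


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    if union == 0:
        return 0.0  # empty-vs-empty pair contributes nothing
    return len(a & b) / union


def total_jaccard(sets: Sequence[CodingSet]) -> float:
    """Total Jaccard index over unordered cross-category image pairs.

    J = 0.5 * sum_{(i, j): category_i != category_j} |y_i ∩ y_j| / |y_i ∪ y_j|
    """
    if len({s.category for s in sets}) < 2:
        raise ParameterError("total_jaccard needs images from >= 2 categories")
    total = 0.0
    for a, b in itertools.combinations(sets, 2):
        if a.category != b.category:
            total += _jaccard(a.used, b.used)
    return 0.5 * total


def within_cluster_ss(
    descriptors: np.ndarray, assignments: np.ndarray, centers: np.ndarray
) -> float:
    """Total within-cluster sum of squared Euclidean distances."""
    X = np.asarray(descriptors, dtype=float)
    centers = np.asarray(centers, dtype=float)
    diffs = X - centers[np.asarray(assignments, dtype=int)]
    return float(np.sum(diffs * diffs))


def psi(J: float, D: float, K: int, n_c: int) -> float:
    """The codebook-size objective; natural logs throughout.

    J or D of exactly 0 (possible at perfect category separation) is floored
    at 1e-12 with a warning, which preserves the argmax semantics.
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    if n_c < 2:
        raise ParameterError("n_c must be >= 2")
    if J < 0 or D < 0:
        raise ParameterError("J and D must be non-negative")
    if J == 0 or D == 0:
        warnings.warn("J or D is 0; flooring at 1e-12 inside psi", stacklevel=2)
        J = max(J, PSI_FLOOR)
        D = max(D, PSI_FLOOR)
    return (
        float(np.log(n_c * (n_c - 1) / 2.0))
        - float(np.log(J))
        - 0.5 * float(np.log(D))
        - 0.75 * float(np.log(K))
    )


def select_codebook_size(
    model_descriptors: np.ndarray,
    reference_images: Iterable[tuple],
    grid: Sequence[int],
    seed: int,
    w: int = 32,
    usage_threshold: float = 0.0,
) -> tuple[int, PsiCurve, dict[int, Codebook]]:
    """Choose K maximizing Psi(K) over a grid.

    For each K: fit a codebook on ``model_descriptors``, densely recode every
    reference image, and evaluate J(K) (cross-category coding-set overlap),
    D(K) (k-means inertia) and Psi(K).  ``reference_images`` is an iterable of
    (HImage, category) pairs spanning at least two categories.  Ties in the
    argmax go to the smallest K (grid is sorted ascending first).

    Returns (K*, PsiCurve, {K: Codebook}).
    """
    from .recode import recode_image  # local import to avoid a cycle

    grid = sorted(int(k) for k in grid)
    if not grid:
        raise ParameterError("grid must be non-empty")
    refs = list(reference_images)
    categories = {c for _, c in refs}
    if len(categories) < 2:
        raise ParameterError("reference images must span >= 2 categories")
    n_c = len(categories)
    Js, Ds, psis = [], [], []
    books: dict[int, Codebook] = {}
    for K in grid:
        cb = fit_codebook(model_descriptors, K, seed)
        books[K] = cb
        sets = []
        for i, (him, cat) in enumerate(refs):
            rep = recode_image(him, cb, w=w, image_id=f"ref_{i}")
            rep.category = cat
            sets.append(coding_set(rep, threshold=usage_threshold))
        J = total_jaccard(sets)
        D = float(cb.inertia)
        Js.append(J)
        Ds.append(D)
        psis.append(psi(J, D, K, n_c))
    curve = PsiCurve(np.array(grid), np.array(Js), np.array(Ds),
                     np.array(psis), n_c)
    best = int(curve.grid[int(np.argmax(curve.psi))])
    return best, curve, books


def cluster_codeblocks(
    cb: Codebook, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical clustering of the codeblocks.

    Returns (labels in 1..n_groups per codeblock, linkage matrix with K-1
    merges).
    """
    if n_groups > cb.K:
        raise ParameterError("n_groups cannot exceed K")
    Z = linkage(cb.centers, method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return labels, Z
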