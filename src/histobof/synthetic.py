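"""Synthetic fixtures with known ground truth for every pipeline stage.

Two families of generators are provided:

* **texture images** — tissue-like rasters in which each region carries an
  oriented sinusoidal grating plus Gaussian noise.  Gratings are used instead
  of richer texture models because their Gabor-bank responses (hence their
  separability in descriptor space) are analytically predictable: the noise
  SD is the single difficulty dial.  The generators emulate the reference
  tissue-category corpus (five single-texture categories by default) and
  carry the true region map as the oracle for tile-assignment accuracy.

* **joint tables** — per-sample image-feature / gene-expression /
  clinical / survival tables with planted Pearson correlations and planted
  per-IQR hazard ratios.  Features and genes are multivariate normal with the
  requested correlation structure; survival times are exponential with
  hazard proportional to exp(sum beta_j x_j / 1.349) (1.349 = the IQR of a
  standard normal), so proportional hazards holds by construction and a Cox
  fit on sample-IQR-standardized covariates targets the planted HR directly.
  Censoring is independent exponential with its rate tuned numerically to
  the requested censoring fraction.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ParameterError
from .mining import JointDataset
from .preprocess import HImage, OD_MAX, reconstruct_rgb
from .recode import CodeblockMap

#: population interquartile range of the standard normal
NORMAL_IQR = 1.3489795003921634


@dataclasses.dataclass
class TextureSpec:
    """Parameters of one oriented-grating texture class."""

    label: int
    orientation: float          # radians
    frequency: float            # cycles / pixel, in (0, 0.5)
    noise_sd: float = 0.05
    base: float = 0.5           # base intensity in [0, 1]
    amplitude: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency < 0.5:
            raise ParameterError("frequency must be in (0, 0.5) cycles/pixel")
        if self.noise_sd < 0:
            raise ParameterError("noise SD must be >= 0")


def gen_texture_image(
    layout: np.ndarray,
    specs: Mapping[int, TextureSpec],
    seed: int = 0,
    as_rgb: bool = False,
) -> tuple[HImage | np.ndarray, np.ndarray]:
    """Fill each region of ``layout`` with its class's grating texture.

    ``layout`` is an integer map of class labels covering the image; every
    label must have a :class:`TextureSpec`.  Returns (image, ground-truth
    region map).  With ``as_rgb`` the H-intensity is mapped back through the
    stain model to an H&E-like 8-bit RGB image (so the preprocessing chain
    can be exercised end to end).
    """
    layout = np.asarray(layout, dtype=int)
    labels = np.unique(layout)
    missing = [int(l) for l in labels if l not in specs]
    if missing:
        raise ParameterError(f"no TextureSpec for labels {missing}")
    rng = np.random.default_rng(seed)
    h, w = layout.shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w))
    for lab in labels:
        sp = specs[int(lab)]
        phase = 2 * np.pi * sp.frequency * (
            xx * math.cos(sp.orientation) + yy * math.sin(sp.orientation)
        )
        tex = sp.base + sp.amplitude * np.sin(phase)
        sel = layout == lab
        img[sel] = tex[sel]
    img += rng.normal(0.0, 1.0, size=img.shape) * _noise_map(layout, specs)
    img = np.clip(img, 0.0, 1.0)
    if as_rgb:
        conc = np.zeros((h, w, 3))
        conc[..., 0] = img * OD_MAX * 0.5  # mid-range H staining depth
        return reconstruct_rgb(conc), layout.copy()
    return HImage(img, np.ones_like(img, dtype=bool)), layout.copy()


def _noise_map(layout: np.ndarray, specs: Mapping[int, TextureSpec]) -> np.ndarray:
    out = np.zeros(layout.shape)
    for lab in np.unique(layout):
        out[layout == lab] = specs[int(lab)].noise_sd
    return out


def default_texture_specs(n_classes: int = 5, noise_sd: float = 0.05) -> dict[int, TextureSpec]:
    """Well-separated grating classes: staggered orientations and frequencies."""
    if n_classes < 2:
        raise ParameterError("need at least 2 texture classes")
    freqs = np.geomspace(0.4, 0.05, n_classes)
    return {
        i + 1: TextureSpec(
            label=i + 1,
            orientation=(i * math.pi / n_classes) % math.pi,
            frequency=float(freqs[i]),
            noise_sd=noise_sd,
        )
        for i in range(n_classes)
    }


def gen_reference_corpus(
    n_per_class: int = 3,
    n_classes: int = 5,
    size: tuple[int, int] = (128, 128),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[tuple[HImage, str]]:
    """Single-texture images per category, for codebook-size selection.

    Emulates a reference corpus of ``n_classes`` tissue categories (five by
    default) with ``n_per_class`` images each; categories are labelled
    ``class_1`` .. ``class_{n_classes}``.
    """
    specs = default_texture_specs(n_classes, noise_sd=noise_sd)
    corpus = []
    for c in range(1, n_classes + 1):
        layout = np.full(size, c, dtype=int)
        for r in range(n_per_class):
            him, _ = gen_texture_image(layout, specs,
                                       seed=seed + 1000 * c + r)
            corpus.append((him, f"class_{c}"))
    return corpus


def gen_fig1a_layouts(count: int = 16, grid: tuple[int, int] = (12, 12),
                      w: int = 32) -> list[CodeblockMap]:
    """Four codeblock maps with identical histograms but distinct geometry.

    Each map places exactly ``count`` tiles of codeblock 1 on a background of
    codeblock 2, arranged as (a) one compact square blob, (b) scattered
    singleton tiles, (c) two medium blobs, and (d) a hollow square ring.
    The frequency component of the representation cannot distinguish them;
    the spatial statistics can.  ``count`` must be an even perfect-square-
    friendly size that fits the grid (default 16 on a 12 x 12 grid).
    """
    side = int(round(math.sqrt(count)))
    if side * side != count or count % 2:
        raise ParameterError("count must be an even perfect square (e.g. 16)")
    h, wgrid = grid
    ring_side = count // 4 + 1  # perimeter of a ring_side^2 square = count
    if h < 2 * side + 2 or wgrid < 2 * side + 2 or h < ring_side or wgrid < ring_side:
        raise ParameterError("grid too small for the requested layouts")

    maps = []
    # (a) one compact side x side blob
    m = np.full(grid, 2, dtype=int)
    m[1 : 1 + side, 1 : 1 + side] = 1
    maps.append(CodeblockMap(m, w))
    # (b) scattered singletons on a stride-2 lattice
    m = np.full(grid, 2, dtype=int)
    placed = 0
    for r in range(0, h, 2):
        for c in range(0, wgrid, 2):
            if placed < count:
                m[r, c] = 1
                placed += 1
    if placed < count:
        raise ParameterError("grid too small to scatter all singleton tiles")
    maps.append(CodeblockMap(m, w))
    # (c) two (side x side/2) blobs, well separated
    m = np.full(grid, 2, dtype=int)
    m[1 : 1 + side, 1 : 1 + side // 2] = 1
    m[h - 1 - side : h - 1, wgrid - 1 - side // 2 : wgrid - 1] = 1
    maps.append(CodeblockMap(m, w))
    # (d) hollow ring: boundary of a ring_side x ring_side square
    m = np.full(grid, 2, dtype=int)
    sq = np.zeros(grid, dtype=bool)
    sq[1 : 1 + ring_side, 1 : 1 + ring_side] = True
    inner = np.zeros(grid, dtype=bool)
    inner[2 : ring_side, 2 : ring_side] = True
    m[sq & ~inner] = 1
    maps.append(CodeblockMap(m, w))

    for cm in maps:
        assert int((cm.labels == 1).sum()) == count
    return maps


@dataclasses.dataclass
class PlantedJointSpec:
    """Ground truth for a synthetic joint feature/expression/survival table.

    ``feature_gene_corr`` plants Pearson correlations between named feature
    and gene columns; ``hazard_ratios`` plants per-IQR hazard ratios on named
    columns (features, genes or ``genomic_score``); ``clinical_shift`` adds a
    mean shift (in SD units) to named features for samples in the high
    T-stage group, creating a detectable t-test association.
    """

    n: int = 65
    n_features: int = 10
    n_genes: int = 8
    feature_gene_corr: Sequence[tuple[int, int, float]] = ()
    hazard_ratios: Mapping[str, float] = dataclasses.field(default_factory=dict)
    clinical_shift: Mapping[str, float] = dataclasses.field(default_factory=dict)
    censoring: float = 0.3
    baseline_hazard: float = 0.2    # events per year at covariates = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for _, _, r in self.feature_gene_corr:
            if not abs(r) < 1:
                raise ParameterError("planted correlations must have |rho| < 1")
        for hr in self.hazard_ratios.values():
            if hr <= 0:
                raise ParameterError("hazard ratios must be positive")
        if not 0 <= self.censoring < 1:
            raise ParameterError("censoring fraction must be in [0, 1)")


def _feature_names(p: int) -> list[str]:
    width = max(2, len(str(p)))
    return [f"freq_C.{i + 1:0{width}d}" for i in range(p)]


def _gene_names(q: int) -> list[str]:
    return [f"gene_{i + 1:02d}" for i in range(q)]


def gen_joint_dataset(spec: PlantedJointSpec) -> JointDataset:
    """Draw a joint dataset with the planted correlation and hazard structure.

    Features and genes are jointly multivariate normal (unit marginals) with
    the planted cross-correlations; an extra independent N(0, 1) column plays
    the precomputed genomic score.  Survival times are exponential with
    hazard ``baseline_hazard * exp(sum log(HR_v) * x_v / NORMAL_IQR)``;
    censoring is independent exponential with rate solved to match the
    requested censoring fraction.  T stage and grade are drawn categorically,
    and ``clinical_shift`` features are shifted for the {T3, T4} group.
    """
    rng = np.random.default_rng(spec.seed)
    p, q = spec.n_features, spec.n_genes
    cov = np.eye(p + q)
    for fi, gi, r in spec.feature_gene_corr:
        cov[fi, p + gi] = cov[p + gi, fi] = r
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ParameterError("target correlation matrix is not positive "
                             "definite") from err
    Z = rng.standard_normal((spec.n, p + q)) @ chol.T
    idx = pd.Index([f"s{i + 1:04d}" for i in range(spec.n)], name="sample_id")
    features = pd.DataFrame(Z[:, :p], index=idx, columns=_feature_names(p))
    expression = pd.DataFrame(Z[:, p:], index=idx, columns=_gene_names(q))
    genomic = pd.Series(rng.standard_normal(spec.n), index=idx,
                        name="genomic_score")

    t_stage = pd.Series(rng.choice(["T1", "T2", "T3", "T4"], size=spec.n,
                                   p=[0.25, 0.35, 0.25, 0.15]), index=idx)
    grade = pd.Series(rng.choice(["G1", "G2", "G3"], size=spec.n,
                                 p=[0.25, 0.45, 0.30]), index=idx)
    high_t = t_stage.isin(["T3", "T4"]).to_numpy()
    for col, shift in spec.clinical_shift.items():
        features.loc[high_t, col] = features.loc[high_t, col] + shift
    clinical = pd.DataFrame({"T": t_stage, "G": grade})

    def col(name: str) -> np.ndarray:
        if name == "genomic_score":
            return genomic.to_numpy()
        if name in features.columns:
            return features[name].to_numpy()
        if name in expression.columns:
            return expression[name].to_numpy()
        raise ParameterError(f"hazard on unknown column {name!r}")

    eta = np.zeros(spec.n)
    for name, hr in spec.hazard_ratios.items():
        eta += math.log(hr) * col(name) / NORMAL_IQR
    rate = spec.baseline_hazard * np.exp(eta)
    times = rng.exponential(1.0 / rate)
    event = np.ones(spec.n, dtype=int)
    if spec.censoring > 0:
        c_rate = _censoring_rate(rate, spec.censoring)
        ctimes = rng.exponential(1.0 / c_rate, size=spec.n)
        event = (times <= ctimes).astype(int)
        times = np.minimum(times, ctimes)
    survival = pd.DataFrame({"time": times, "event": event}, index=idx)
    return JointDataset(features, expression, clinical, survival, genomic)


def _censoring_rate(event_rates: np.ndarray, target: float) -> float:
    """Rate c of an independent exponential censorer with E[P(C < T)] = target.

    For exponential event time with rate lambda_i, P(censored) = c/(c+lambda_i);
    the population-average probability is solved for c by bisection.
    """

    def f(c: float) -> float:
        return float(np.mean(c / (c + event_rates))) - target

    lo, hi = 1e-10, 1e6
    return float(brentq(f, lo, hi))
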