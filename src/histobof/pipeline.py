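"""End-to-end pipeline runner with content-addressed artifact caching.

Stages run in order: preprocess -> descriptors -> codebook -> recode ->
mine.  Each stage writes its artifact plus a small meta JSON recording the
cache key (hash of the relevant config fields and of the upstream stage's
key), the package version and the seed; a rerun with an unchanged key reuses
the artifact and logs a cache hit, while changing e.g. the seed invalidates
the codebook stage and everything downstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codebook import Codebook, fit_codebook, select_codebook_size
from .config import PipelineConfig
from .descriptors import build_bank, describe_patches, sample_patches
from .exceptions import DataError
from .mining import (JointDataset, correlate_features_genes, cox_univariate,
                     image_score)
from .preprocess import HImage, preprocess_image
from .recode import recode_image, representation_frame

log = logging.getLogger("histobof.pipeline")

PREPROC_FIELDS = ("levels", "mask_mode", "clahe_clip_limit", "clahe_ntiles")
DESC_FIELDS = PREPROC_FIELDS + ("w", "n_patches", "min_tissue_fraction",
                                "sigmas", "thetas", "nus", "seed")
CODEBOOK_FIELDS = DESC_FIELDS + ("k_grid", "usage_threshold")
RECODE_FIELDS = CODEBOOK_FIELDS
MINE_FIELDS = RECODE_FIELDS + ("rho_min", "alpha", "score_components")


def _meta_path(artifact: Path) -> Path:
    return artifact.with_suffix(artifact.suffix + ".meta.json")


def _is_cached(artifact: Path, key: str) -> bool:
    mp = _meta_path(artifact)
    if not (artifact.exists() and mp.exists()):
        return False
    try:
        return json.loads(mp.read_text())["key"] == key
    except (json.JSONDecodeError, KeyError):
        return False


def _write_meta(artifact: Path, key: str, stage: str) -> None:
    _meta_path(artifact).write_text(json.dumps(
        {"key": key, "stage": stage, "version": __version__}))


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    codebook: Codebook
    features: pd.DataFrame
    associations: pd.DataFrame | None = None
    survival_models: dict | None = None


def run_pipeline(
    config: PipelineConfig,
    model_images: list[np.ndarray],
    reference_images: list[tuple[np.ndarray, str]],
    mining_images: list[tuple[np.ndarray, str]],
    out_dir: str | Path,
    expression: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
    genomic_score: pd.Series | None = None,
    fixed_K: int | None = None,
) -> PipelineResult:
    """Run every stage on in-memory RGB images, caching artifacts on disk.

    ``model_images`` feed descriptor sampling and codebook fitting;
    ``reference_images`` (image, category) drive Psi(K) size selection unless
    ``fixed_K`` is given; ``mining_images`` (image, image_id) are recoded
    into the 6K feature matrix.  If expression/clinical/survival tables are
    provided the mining stage runs as well.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    cfg.save(out / "config.json")

    # --- preprocess + descriptors --------------------------------------
    desc_key = cfg.hash(DESC_FIELDS)
    desc_path = out / "descriptors.csv"
    bank = build_bank(cfg.sigmas, cfg.thetas, cfg.nus)
    if _is_cached(desc_path, desc_key):
        log.info("cache hit: descriptors (%s)", desc_key)
        descriptors = pd.read_csv(desc_path).to_numpy()
    else:
        rows = []
        for i, img in enumerate(model_images):
            him = preprocess_image(img, levels=cfg.levels,
                                   mask_mode=cfg.mask_mode,
                                   clip_limit=cfg.clahe_clip_limit)
            patches, _ = sample_patches(
                him, n=cfg.n_patches, w=cfg.w,
                min_tissue_fraction=cfg.min_tissue_fraction,
                seed=cfg.seed + i,
            )
            rows.append(describe_patches(patches, bank))
        descriptors = np.vstack(rows)
        pd.DataFrame(descriptors).to_csv(desc_path, index=False)
        _write_meta(desc_path, desc_key, "descriptors")

    # --- codebook -------------------------------------------------------
    cb_key = cfg.hash(CODEBOOK_FIELDS) + (f"-K{fixed_K}" if fixed_K else "")
    cb_stem = out / "codebook"
    psi_path = out / "psi_curve.csv"
    if _is_cached(cb_stem.with_suffix(".json"), cb_key):
        log.info("cache hit: codebook (%s)", cb_key)
        cb = Codebook.load(cb_stem)
    else:
        if fixed_K is not None:
            cb = fit_codebook(descriptors, fixed_K, cfg.seed)
        else:
            refs = [
                (preprocess_image(img, levels=cfg.levels, mask_mode=cfg.mask_mode,
                                  clip_limit=cfg.clahe_clip_limit), cat)
                for img, cat in reference_images
            ]
            K, curve, books = select_codebook_size(
                descriptors, refs, cfg.k_grid, cfg.seed, w=cfg.w,
                usage_threshold=cfg.usage_threshold,
            )
            curve.to_frame().to_csv(psi_path, index=False)
            cb = books[K]
        cb.save(cb_stem)
        _write_meta(cb_stem.with_suffix(".json"), cb_key, "codebook")

    # --- recode ----------------------------------------------------------
    rec_key = cb_key + "-" + cfg.hash(RECODE_FIELDS)
    feat_path = out / "features.csv"
    if _is_cached(feat_path, rec_key):
        log.info("cache hit: features (%s)", rec_key)
        features = pd.read_csv(feat_path, index_col=0)
    else:
        reps = []
        for img, image_id in mining_images:
            him = preprocess_image(img, levels=cfg.levels, mask_mode=cfg.mask_mode,
                                   clip_limit=cfg.clahe_clip_limit)
            reps.append(recode_image(him, cb, w=cfg.w, bank=bank,
                                     image_id=image_id))
        features = representation_frame(reps)
        features.to_csv(feat_path)
        _write_meta(feat_path, rec_key, "recode")

    result = PipelineResult(cfg, cb, features)

    # --- mine ------------------------------------------------------------
    if expression is not None and survival is not None:
        if clinical is None:
            clinical = pd.DataFrame({"T": "T2", "G": "G2"},
                                    index=features.index)
        try:
            ds = JointDataset(features, expression, clinical, survival,
                              genomic_score)
        except DataError:
            raise
        assoc = correlate_features_genes(ds, rho_min=cfg.rho_min,
                                         alpha=cfg.alpha)
        assoc.to_csv(out / "associations.csv", index=False)
        result.associations = assoc
        try:
            score = image_score(ds, cfg.score_components)
        except Exception:  # score components absent at this K
            score = None
        models = {}
        if score is not None and _nonzero_iqr(score):
            res = cox_univariate(ds, score)
            models["image_score"] = {
                "hr": float(res.hazard_ratios.iloc[0]),
                "p": res.p_value,
            }
        (out / "models.json").write_text(json.dumps(models, indent=2))
        result.survival_models = models
    return result


def _nonzero_iqr(x: pd.Series) -> bool:
    return float(x.quantile(0.75) - x.quantile(0.25)) > 0
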