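"""Pipeline configuration: every tunable, its default, and serialization.

Defaults follow the published protocol of the method: 4 Gaussian-pyramid
levels (40x -> 2.5x), 32 x 32 patches, 3000 sampled patches per model image,
the 24-filter Gabor grid, the codebook-size grid K = 10, 20, ..., 1000, and
the mining thresholds rho_min = 0.5 and alpha = 0.05.  A config round-trips
losslessly through JSON, and its SHA-256 hash keys the pipeline's artifact
cache.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

from .mining import DEFAULT_SCORE_COMPONENTS


@dataclasses.dataclass
class PipelineConfig:
    # preprocessing
    levels: int = 4
    mask_mode: str = "adaptive"
    clahe_clip_limit: float = 0.01
    clahe_ntiles: int = 8
    # descriptors
    w: int = 32
    n_patches: int = 3000
    min_tissue_fraction: float = 0.5
    sigmas: tuple[float, ...] = (1.0, 2.0 * math.sqrt(2.0))
    thetas: tuple[float, ...] = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
    nus: tuple[float, ...] = (3 / 4, 3 / 8, 3 / 16)
    # codebook
    k_grid: tuple[int, ...] = tuple(range(10, 1001, 10))
    usage_threshold: float = 0.0
    # mining
    rho_min: float = 0.5
    alpha: float = 0.05
    score_components: tuple[str, ...] = DEFAULT_SCORE_COMPONENTS
    # randomness (mandatory for every stochastic stage)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        for key in ("sigmas", "thetas", "nus", "k_grid", "score_components"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def hash(self, fields: tuple[str, ...] | None = None) -> str:
        """SHA-256 of the (sub)config; used as the artifact cache key."""
        d = dataclasses.asdict(self)
        if fields is not None:
            d = {k: d[k] for k in fields}
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
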