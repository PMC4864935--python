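"""Shared fixtures: Gabor bank, synthetic corpora and joint datasets."""

import numpy as np
import pytest

from histobof import PlantedJointSpec, build_bank, gen_joint_dataset
from histobof.descriptors import describe_patches, sample_patches
from histobof.synthetic import default_texture_specs, gen_texture_image


@pytest.fixture(scope="session")
def bank():
    return build_bank()


@pytest.fixture(scope="session")
def three_band_image():
    """192x192 image with three 64-row texture bands aligned to 32-px tiles."""
    specs = default_texture_specs(3, noise_sd=0.05)
    layout = np.zeros((192, 192), dtype=int)
    layout[:64] = 1
    layout[64:128] = 2
    layout[128:] = 3
    him, gt = gen_texture_image(layout, specs, seed=42)
    return him, gt, specs


@pytest.fixture(scope="session")
def three_class_descriptors(bank, three_band_image):
    """Descriptors sampled from the three-texture image (shared k-means input)."""
    him, _, _ = three_band_image
    patches, _ = sample_patches(him, n=400, w=32, seed=7)
    return describe_patches(patches, bank)


@pytest.fixture()
def joint_ds():
    """n = 300 joint dataset with a planted correlation and hazard."""
    spec = PlantedJointSpec(
        n=300, seed=11,
        feature_gene_corr=[(0, 0, 0.6)],
        hazard_ratios={"freq_C.01": 2.0},
        censoring=0.3,
    )
    return gen_joint_dataset(spec)
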