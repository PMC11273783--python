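import numpy as np
import pytest

from pathomics.stains import tile_to_stains
from pathomics.synthetic import CohortSpec, render_tile


@pytest.fixture(scope="session")
def clean_tile():
    """One low-noise 128 px tile with 14 nuclei, no folds, plus ground truth."""
    spec = CohortSpec(tile_size=128, nuclei_per_tile=14, nucleus_radius_mean=5.0,
                      nucleus_eccentricity=0.5, texture_noise_sd=0.02,
                      fold_probability=0.0, background_fraction=0.3, seed=42)
    rng = np.random.default_rng(42)
    tile, truth = render_tile(spec, "responder", rng, keep_concentrations=True)
    return tile, truth


@pytest.fixture(scope="session")
def clean_pair(clean_tile):
    tile, _ = clean_tile
    return tile_to_stains(tile.pixels)


@pytest.fixture(scope="session")
def segmented(clean_tile, clean_pair):
    from pathomics.segmentation import segment_tile

    return segment_tile(clean_pair, min_fold_area=250, min_diameter=6,
                        max_diameter=30)
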