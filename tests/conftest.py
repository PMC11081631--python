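import numpy as np
import pytest

from pigcorr.simulate import (
    ImageSimParams,
    PlantedSetConfig,
    StudyConfig,
    pigment_to_ynorm,
)

#: Small canvas used wherever full 400x330x21 geometry would be wasteful.
SMALL_IMAGE = ImageSimParams(
    canvas_width=80,
    canvas_height=66,
    n_planes=5,
    cell_center=(39.0, 33.0),
    cell_radius=12.0,
)


@pytest.fixture(scope="session")
def cohort_ynorm():
    """Analytic Ynorm for a 500-cell cohort with uniform pigment levels."""
    rng = np.random.default_rng(20240901)
    return pigment_to_ynorm(rng.uniform(0.1, 0.9, 500))


@pytest.fixture(scope="session")
def small_study_config():
    """A miniature three-lineage study with images, for pipeline/CLI tests."""
    return StudyConfig(
        cells_per_lineage=24,
        n_genes=300,
        planted_sets=(PlantedSetConfig(name="PIGMENT_RESPONSE", n_genes=15),),
        n_decoy_sets=8,
        decoy_size_range=(15, 40),
        image=SMALL_IMAGE,
        with_images=True,
    )
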