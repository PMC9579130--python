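import dataclasses

import pytest

from prftuning import pipeline, synthetic


@pytest.fixture(scope="session")
def fixture_table():
    """Miniature vertex table: 2 participants x (V1, V3ab) x 200 vertices."""
    return pipeline.make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_config():
    """Tiny generator config for fast end-to-end tests."""
    return dataclasses.replace(
        synthetic.GroundTruthConfig(),
        n_participants=2,
        rois=("V1", "V3ab"),
        n_vertices_per_roi=150,
        seed=3,
    )


@pytest.fixture(scope="session")
def full_table():
    """One full-size synthetic dataset (9 participants, 6 ROIs)."""
    return synthetic.generate_vertex_table(synthetic.GroundTruthConfig(seed=1))
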