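import numpy as np
import pytest

from lncannot import core_io, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """4 genes x 6 samples with hand-pickable values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            [1.0, 4.0, 2.0, 8.0, 5.0, 7.0],
        ]
    )
    return core_io.ExpressionMatrix(
        ["G_UP", "G_DOWN", "G_FLAT", "G_NOISY"],
        [f"S{i}" for i in range(6)],
        values,
        core_io.MatrixKind.LOG_NORMALIZED,
    )


@pytest.fixture(scope="session")
def small_synth():
    """A fast synthetic cohort with strong planted structure (one seed)."""
    cfg = synthetic.SyntheticConfig(
        n_genes=600,
        n_samples=200,
        planted_sets=[
            synthetic.PlantedSet("NEG_SET", 30, -0.8),
            synthetic.PlantedSet("POS_SET", 30, +0.8),
        ],
        n_decoy_sets=5,
        decoy_set_size=30,
        seed=7,
    )
    matrix, truth = synthetic.generate_expression(cfg)
    factors = core_io.estimate_size_factors(matrix)
    logged = core_io.log_transform(core_io.normalize(matrix, factors))
    return cfg, matrix, logged, truth
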