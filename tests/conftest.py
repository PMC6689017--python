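import numpy as np
import pytest

from todrhythm.datatypes import OMEGA, ExpressionMatrix
from todrhythm.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noise_matrix(rng):
    """Pure-noise log2cpm-like matrix: 50 genes x 40 subjects."""
    values = rng.normal(6.0, 1.0, size=(50, 40))
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"G{i:03d}" for i in range(50)],
        subject_ids=[f"S{j:03d}" for j in range(40)],
        scale_tag="log2cpm",
    )


@pytest.fixture
def uniform_zt(rng):
    return rng.uniform(-6.0, 18.0, size=40)


@pytest.fixture
def small_cohort():
    """Small mixed cohort with shared/gain/loss rhythm classes."""
    spec = CohortSpec(n_ctrl=30, n_case=30, n_genes=120,
                      f_shared=0.1, f_gain=0.1, f_loss=0.1,
                      amplitude=2.0, noise_sd=0.8, tod_mode="uniform",
                      seed=7)
    return generate_cohort(spec)


def sinusoid(t, A, p, b):
    return A * np.sin(OMEGA * np.asarray(t, float) + p) + b
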