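import numpy as np
import pytest

from pcrtsig.cohorts import SampleAnnotation
from pcrtsig.nanostring import CountMatrix
from pcrtsig.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic study shared across read-only tests."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced panel for tests that run the whole pipeline."""
    cfg = SimulationConfig(
        seed=11, n_endogenous=150, n_training=60, n_validation=60,
        effect_log2fc=1.2,
    )
    return generate_cohort(cfg)


def make_matrix(counts, gene_ids=None, classes=None, sample_ids=None):
    counts = np.asarray(counts, dtype=float)
    n_g, n_s = counts.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_g)]
    classes = classes or ["endogenous"] * n_g
    sample_ids = sample_ids or [f"S{j}" for j in range(n_s)]
    return CountMatrix(gene_ids, classes, sample_ids, counts)


@pytest.fixture
def annotation_factory():
    def make(sample_id="S1", trg=1, cohort="training", **kw):
        defaults = dict(
            gender="male", clin_T="T3", clin_N="N1", clin_M="M0",
            path_T="T2", path_N="N0", path_M="M0", differentiation="moderate",
        )
        defaults.update(kw)
        return SampleAnnotation(sample_id=sample_id, trg=trg, cohort=cohort, **defaults)

    return make
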