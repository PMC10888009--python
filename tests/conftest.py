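import numpy as np
import pytest

from morphnet.io_formats import ROISampleSet, aal90_labels
from morphnet.kls_network import build_similarity_matrix
from morphnet.synthetic_cohort import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def aal():
    return aal90_labels()


@pytest.fixture(scope="session")
def micro_cohort():
    """Small deterministic cohort shared across test modules."""
    design = CohortDesign(n_per_group={"HC": 3, "MDD": 3}, seed=11)
    return generate_cohort(design)


@pytest.fixture(scope="session")
def one_subject(micro_cohort):
    return micro_cohort[1][0]


@pytest.fixture(scope="session")
def one_matrix(one_subject):
    return build_similarity_matrix(one_subject)


@pytest.fixture(scope="session")
def micro_matrices(micro_cohort):
    records, sample_sets = micro_cohort
    return {ss.subject_id: build_similarity_matrix(ss) for ss in sample_sets}


def gaussian_sample_set(subject_id: str, means, sds, n=100, seed=0) -> ROISampleSet:
    """Build an ROISampleSet over the full AAL-90 from per-region Gaussians."""
    labels = aal90_labels()
    rng = np.random.default_rng(seed)
    samples = [rng.normal(m, s, n) for m, s in zip(means, sds)]
    return ROISampleSet(subject_id=subject_id, region_labels=labels, samples=samples)
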