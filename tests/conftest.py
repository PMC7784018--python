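import numpy as np
import pytest

from peachsv.cohort import CohortSpec, generate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, shared across the suite."""
    return generate_study(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    from peachsv.cohort import write_study

    d = tmp_path_factory.mktemp("study")
    manifest = write_study(study, d)
    return d, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
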