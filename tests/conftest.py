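import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def locus_truth():
    from sgselect.simulate import LocusSpec, generate_locus

    return generate_locus(LocusSpec(seed=11, background_length=12_000))


@pytest.fixture
def fixture_dir(tmp_path, locus_truth):
    from sgselect.simulate import write_fixture

    return write_fixture(locus_truth, tmp_path / "fix")
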