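import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_spec():
    """A scaled-down simulation spec for fast unit tests."""
    from telokit import SimulationSpec

    return SimulationSpec(seed=11, n_datasets=3, decoys_per_dataset=40)


def random_primitive_motifs(rng, n, min_len=5, max_len=15):
    """n random primitive ACGT units (helper shared across test modules)."""
    from telokit.motif import TelomereMotif, minimal_period

    bases = np.array(list("ACGT"))
    out = []
    while len(out) < n:
        L = int(rng.integers(min_len, max_len + 1))
        unit = "".join(rng.choice(bases, size=L))
        if minimal_period(unit) == L:
            out.append(TelomereMotif(unit))
    return out
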