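import numpy as np
import pytest

from cnva.grid import GridSpec
from cnva.prep import standardize
from cnva.stack import ClimateStack
from cnva.synthetic import SpeciesSpec, WorldSpec, generate_climate, generate_species


@pytest.fixture(scope="session")
def world64():
    """A 64x64 synthetic world with both emission scenarios."""
    spec = WorldSpec(n_rows=64, n_cols=64, seed=42)
    current, futures = generate_climate(spec)
    return spec, current, futures


@pytest.fixture(scope="session")
def std_current(world64):
    _, current, _ = world64
    return standardize(current)


@pytest.fixture(scope="session")
def occurrences64(world64):
    """Occurrences of a moderately marginal, specialized species."""
    _, current, _ = world64
    spec = SpeciesSpec(
        name="demo",
        niche_center=np.full(6, 0.5),
        niche_sd=np.full(6, 0.6),
        n_occurrences=60,
        seed=7,
    )
    return generate_species(spec, current)


def random_stack(n_rows=30, n_cols=30, n_vars=3, seed=0, names=None):
    """Plain white-noise climate stack helper for unit tests."""
    rng = np.random.default_rng(seed)
    names = names or [f"v{i}" for i in range(n_vars)]
    return ClimateStack(
        grid=GridSpec(n_rows, n_cols, 0.1),
        variables=names,
        values=rng.standard_normal((n_vars, n_rows, n_cols)),
        mask=np.ones((n_rows, n_cols), dtype=bool),
    )
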