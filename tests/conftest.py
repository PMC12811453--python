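import numpy as np
import pytest
from hypothesis import settings

from microprog import SensitivityField, build_grid

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_field(grid, default=20, overrides=None, **kwargs) -> SensitivityField:
    """Uniform field with per-position overrides keyed by (x, y) degrees."""
    values = {l.id: default for l in grid.loci}
    for (x, y), v in (overrides or {}).items():
        values[grid.locus_at(x, y).id] = v
    return SensitivityField(values=values, **kwargs)


@pytest.fixture
def field_factory(grid):
    def _make(default=20, overrides=None, **kwargs):
        return make_field(grid, default, overrides, **kwargs)

    return _make
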