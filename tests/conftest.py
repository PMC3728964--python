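import numpy as np
import pytest

from vitalrecon import (
    KernelParams,
    SamplingConfig,
    SizeMesh,
    make_dataset,
)
from vitalrecon.simulator import default_intervals, draw_species


@pytest.fixture(scope="session")
def mesh():
    return SizeMesh(0.0, 5.0, 50)


@pytest.fixture(scope="session")
def fine_mesh():
    return SizeMesh(0.0, 5.0, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tame_params():
    """A hand-picked, well-behaved species: survival rises with size and
    falls slowly with time, growth is incremental, fecundity modest."""
    return KernelParams(
        surv_icpt=0.8, surv_size=0.3, surv_time=-0.004, surv_size_time=0.0008,
        grow_icpt=0.25, grow_size=0.85, grow_time=-0.001, grow_size_time=0.0002,
        grow_sd=0.25,
        fec_icpt=-1.5, fec_size=0.3, fec_time=-0.004, fec_size_time=0.0005,
        off_icpt=0.5, off_time=0.001, off_sd=0.25,
    )


@pytest.fixture(scope="session")
def intervals():
    return default_intervals("standard")


@pytest.fixture(scope="session")
def species(mesh, intervals):
    """One random viable artificial species (fixed seed)."""
    return draw_species(intervals, np.random.default_rng(7), mesh=mesh)


@pytest.fixture(scope="session")
def dataset(species, mesh):
    """Standard noisy observation dataset for the fixed species."""
    return make_dataset(
        species,
        SamplingConfig(seed=7),
        rng=np.random.default_rng(8),
        mesh=mesh,
    )
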