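import numpy as np
import pytest

from psmap.evaluate import Episode
from psmap.synthetic import Scenario, make_cylinder_mesh, synth_phase_sequence


@pytest.fixture(scope="session")
def small_domain():
    """A 16 x 32 cylinder (512 nodes) for fast unit tests."""
    return make_cylinder_mesh(rows=16, cols=32)


@pytest.fixture(scope="session")
def full_domain():
    """The 32 x 64 cylinder (2048 nodes) matching a clinical non-contact map."""
    return make_cylinder_mesh()


@pytest.fixture(scope="session")
def capped_domain():
    return make_cylinder_mesh(capped=True)


@pytest.fixture(scope="session")
def spiral_episode(full_domain):
    mesh, proj = full_domain
    scenario = Scenario(kind="spiral", frames=8)
    seq, ann = synth_phase_sequence(scenario, mesh, proj)
    return Episode(phase=seq, annotations=ann, mesh=mesh, projection=proj)


def _make_episode(mesh, proj, *, kind="spiral", frames=8, noise_sd=0.0, seed=0, cores=None,
                  chirality=None):
    kwargs = {}
    if cores is not None:
        kwargs["cores"] = cores
        kwargs["chirality"] = chirality or [1] * len(cores)
    scenario = Scenario(kind=kind, frames=frames, noise_sd=noise_sd, seed=seed, **kwargs)
    seq, ann = synth_phase_sequence(scenario, mesh, proj)
    return Episode(phase=seq, annotations=ann, mesh=mesh, projection=proj)


@pytest.fixture(scope="session")
def make_episode():
    """Factory building an annotated synthetic episode on a given domain."""
    return _make_episode
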