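import numpy as np
import pytest

from tubekin.synthetic import (
    CellFieldSpec,
    Constriction,
    TubeSpec,
    make_cell_tessellation,
    make_constricting_tube,
    make_sphere_sequence,
)


@pytest.fixture(scope="session")
def cylinder_seq():
    """Static-ish cylinder (two timepoints, no constriction): R=30, L=200."""
    spec = TubeSpec(R0=30.0, L0=200.0, constrictions=[], n_s=48, n_phi=32, n_t=2)
    return make_constricting_tube(spec)


@pytest.fixture(scope="session")
def cylinder_surface(cylinder_seq):
    return cylinder_seq[0][0]


@pytest.fixture(scope="session")
def tube_seq():
    """Constricting tube: one Gaussian neck ramping to 0.6*R0 over 20 min."""
    spec = TubeSpec(
        R0=30.0,
        L0=200.0,
        constrictions=[Constriction(center=100.0, depth=18.0, width=12.0)],
        n_s=64,
        n_phi=32,
        dt=1.0,
        n_t=20,
    )
    return make_constricting_tube(spec)


@pytest.fixture(scope="session")
def sphere_static():
    return make_sphere_sequence(lambda t: 10.0, n_t=2, subdivisions=3)


@pytest.fixture(scope="session")
def shrinking_sphere():
    return make_sphere_sequence(lambda t: 10.0 * (1.0 - 0.01 * t), n_t=5, subdivisions=3)


@pytest.fixture(scope="session")
def circumferential_cells(cylinder_surface):
    """~600 circumferentially elongated cells (target a/b = 2.5) on a cylinder."""
    spec = CellFieldSpec(n_cells=600, aspect_profile=2.5, jitter=0.1, seed=7)
    return make_cell_tessellation(spec, cylinder_surface)


@pytest.fixture(scope="session")
def measured_circumferential(circumferential_cells, cylinder_surface):
    from tubekin.cells import measure_cells

    return measure_cells(circumferential_cells, cylinder_surface)


def regular_polygon(n, a=1.0, b=1.0, angle=0.0, center=(0.0, 0.0)):
    """Sampled ellipse (or regular polygon for a=b) as an (n, 2) array."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return xy @ R.T + np.asarray(center)
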