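import numpy as np
import pytest

from wssbench import (BC, BCSpec, DiscretizationConfig, FluidProperties,
                      StabilizationWeights, build_cylinder_mesh,
                      build_unit_square_mesh, poiseuille_exact,
                      solve_stokes, stokes2d_exact)
from wssbench.benchmarks import poiseuille_config, stokes2d_config
from wssbench.meshing import TaggedMesh


@pytest.fixture(scope="session")
def exact2d():
    return stokes2d_exact()


@pytest.fixture(scope="session")
def exact_pois():
    return poiseuille_exact()


def make_square_bcs(exact):
    return BCSpec(regions={t: BC("dirichlet", exact.velocity)
                           for t in (1, 2, 3, 4)})


def make_poiseuille_bcs(exact):
    zero = lambda x: np.zeros_like(np.atleast_2d(x))
    return BCSpec(regions={
        1: BC("dirichlet", exact.velocity),
        2: BC("zero_tangential_velocity"),
        3: BC("dirichlet", zero),
    })


@pytest.fixture(scope="session")
def stokes2d_sol_p2p1(exact2d):
    mesh = build_unit_square_mesh(16)
    props = FluidProperties(kinematic_viscosity=1.0)
    return solve_stokes(mesh, props, stokes2d_config("p2p1"),
                        make_square_bcs(exact2d))


@pytest.fixture(scope="session")
def stokes2d_sol_p1p1(exact2d):
    mesh = build_unit_square_mesh(16)
    props = FluidProperties(kinematic_viscosity=1.0)
    return solve_stokes(mesh, props, stokes2d_config("p1p1"),
                        make_square_bcs(exact2d))


@pytest.fixture(scope="session")
def poiseuille_sol_p1p1(exact_pois):
    mesh = build_cylinder_mesh(1e-3, 2e-3, 3e-4)
    props = FluidProperties(kinematic_viscosity=4e-3, density=1.0)
    return solve_stokes(mesh, props, poiseuille_config("p1p1"),
                        make_poiseuille_bcs(exact_pois))


@pytest.fixture(scope="session")
def poiseuille_sol_p2p1(exact_pois):
    mesh = build_cylinder_mesh(1e-3, 2e-3, 3e-4)
    props = FluidProperties(kinematic_viscosity=4e-3, density=1.0)
    return solve_stokes(mesh, props, poiseuille_config("p2p1"),
                        make_poiseuille_bcs(exact_pois))


def single_triangle_mesh():
    """One reference triangle; edges tagged 1 (bottom), 2 (hypotenuse),
    3 (left)."""
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    cells = np.array([[0, 1, 2]])

    def tag(c):
        if c[1] < 1e-12:
            return 1
        if c[0] < 1e-12:
            return 3
        return 2

    return TaggedMesh(verts, cells, tag, {1: "bottom", 2: "hyp", 3: "left"})


def two_tet_mesh(scale=1.0):
    """Two tetrahedra sharing the face (0,1,2)."""
    verts = scale * np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.3, 0.3, 1.0],
         [0.4, 0.2, -1.0]]
    )
    cells = np.array([[0, 1, 2, 3], [0, 1, 2, 4]])
    return TaggedMesh(verts, cells, lambda c: 1, {1: "boundary"})
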