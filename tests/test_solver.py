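"""Flow solver tests: Stokes convergence, gauge fixing, enforcement
variants, and the steady Navier-Stokes pseudo-time march."""

import numpy as np
import pytest

from wssbench import (BC, BCSpec, DiscretizationConfig, FluidProperties,
                      PseudoTimeConfig, StabilizationWeights,
                      build_cylinder_mesh, build_unit_square_mesh,
                      l2_error_volume, solve_navier_stokes_steady,
                      solve_stokes)
from wssbench.benchmarks import poiseuille_config, stokes2d_config
from wssbench.fem import assemble as asm

from conftest import make_poiseuille_bcs, make_square_bcs


def _zero_bcs(tags):
    zero = lambda x: np.zeros_like(np.atleast_2d(x))
    return BCSpec(regions={t: BC("dirichlet", zero) for t in tags})


class TestStokes2D:
    def test_null_data_gives_zero_solution(self):
        mesh = build_unit_square_mesh(4)
        props = FluidProperties(kinematic_viscosity=1.0)
        for pair in ("p2p1", "p1p1"):
            sol = solve_stokes(mesh, props, stokes2d_config(pair),
                               _zero_bcs((1, 2, 3, 4)))
            assert np.abs(sol.v).max() < 1e-12
            assert np.abs(sol.p).max() < 1e-10

    @pytest.mark.parametrize("pair,vrate,prate", [
        ("p2p1", 3.0, 2.0), ("p1p1", 2.0, 1.66),
    ])
    def test_manufactured_rates_preasymptotic(self, exact2d, pair, vrate,
                                              prate):
        props = FluidProperties(kinematic_viscosity=1.0)
        errs_v, errs_p = [], []
        for n in (8, 16, 32):
            mesh = build_unit_square_mesh(n)
            sol = solve_stokes(mesh, props, stokes2d_config(pair),
                               make_square_bcs(exact2d))
            errs_v.append(l2_error_volume(sol.Vv, sol.v, exact2d.velocity,
                                          mesh, 8))
            errs_p.append(l2_error_volume(sol.Qp, sol.p, exact2d.pressure,
                                          mesh, 8))
        rv = np.polyfit(np.log([1 / 8, 1 / 16, 1 / 32]), np.log(errs_v), 1)[0]
        rp = np.polyfit(np.log([1 / 8, 1 / 16, 1 / 32]), np.log(errs_p), 1)[0]
        assert rv == pytest.approx(vrate, abs=0.35)
        assert rp == pytest.approx(prate, abs=0.35)

    def test_pressure_gauge_zero_mean(self, stokes2d_sol_p1p1,
                                      stokes2d_sol_p2p1):
        for sol in (stokes2d_sol_p1p1, stokes2d_sol_p2p1):
            gv = asm.pressure_mean_vector(sol.Qp)
            assert abs(gv @ sol.p) < 1e-10 * gv.sum()

    def test_divergence_decreases_under_refinement(self, exact2d):
        props = FluidProperties(kinematic_viscosity=1.0)
        for pair in ("p2p1", "p1p1"):
            divs = []
            for n in (8, 16):
                mesh = build_unit_square_mesh(n)
                sol = solve_stokes(mesh, props, stokes2d_config(pair),
                                   make_square_bcs(exact2d))
                cq = asm.CellQuad(mesh, 4)
                d2 = 0.0
                for ch in cq.chunks():
                    gv = ch.eval_vector_grad(sol.Vv, sol.v)
                    div = gv[:, :, 0, 0] + gv[:, :, 1, 1]
                    d2 += float((ch.wdet * div**2).sum())
                divs.append(np.sqrt(d2))
            assert divs[1] < divs[0]

    def test_strong_vs_nitsche_converge_together(self, exact2d):
        """P2/P1 under strong and weak enforcement: mutual L2 distance of
        the velocities decays under refinement (at least quadratically)."""
        props = FluidProperties(kinematic_viscosity=1.0)
        dist = []
        for n in (8, 16):
            mesh = build_unit_square_mesh(n)
            bcs = make_square_bcs(exact2d)
            s1 = solve_stokes(mesh, props, stokes2d_config("p2p1"), bcs)
            cfg_n = DiscretizationConfig(element_pair="p2p1",
                                         enforcement="nitsche",
                                         nitsche_beta=10.0)
            s2 = solve_stokes(mesh, props, cfg_n, bcs)
            dv = s1.v - s2.v
            dist.append(l2_error_volume(
                s1.Vv, dv, lambda x: np.zeros((len(x), 2)), mesh, 6))
        assert dist[1] < dist[0] / 3.5

    def test_p1p1_requires_weak_enforcement(self):
        mesh = build_unit_square_mesh(4)
        props = FluidProperties(kinematic_viscosity=1.0)
        cfg = DiscretizationConfig(
            element_pair="p1p1", enforcement="strong",
            stabilization=StabilizationWeights(gamma_p=1e-2, gamma_v=1e-2),
        )
        with pytest.raises(ValueError, match="Nitsche"):
            solve_stokes(mesh, props, cfg, _zero_bcs((1, 2, 3, 4)))

    def test_p1p1_requires_nonzero_stabilization(self):
        mesh = build_unit_square_mesh(4)
        props = FluidProperties(kinematic_viscosity=1.0)
        cfg = DiscretizationConfig(
            element_pair="p1p1", enforcement="nitsche",
            stabilization=StabilizationWeights(gamma_p=0.0, gamma_v=0.0),
        )
        with pytest.raises(ValueError, match="stabilization"):
            solve_stokes(mesh, props, cfg, _zero_bcs((1, 2, 3, 4)))

    def test_bc_region_mismatch_rejected(self):
        mesh = build_unit_square_mesh(4)
        props = FluidProperties(kinematic_viscosity=1.0)
        with pytest.raises(ValueError, match="every tagged region"):
            solve_stokes(mesh, props, stokes2d_config("p2p1"),
                         _zero_bcs((1, 2, 3)))


class TestFluidProperties:
    def test_consistency_check(self):
        with pytest.raises(ValueError, match="mu != rho"):
            FluidProperties(dynamic_viscosity=1.0, kinematic_viscosity=1.0,
                            density=2.0)

    def test_derived_viscosities(self):
        p = FluidProperties(dynamic_viscosity=3.5e-3, density=1050.0,
                            density_scaled=False)
        assert p.kinematic_viscosity == pytest.approx(3.5e-3 / 1050)
        assert p.momentum_viscosity == 3.5e-3
        assert p.momentum_density == 1050.0


@pytest.fixture(scope="module")
def tiny_cylinder():
    return build_cylinder_mesh(1e-3, 2e-3, 4.5e-4)


class TestNavierStokesSteady:
    def test_matches_stokes_for_poiseuille(self, tiny_cylinder, exact_pois):
        """Convection vanishes for Poiseuille flow, so for a discretization
        shared between the two solvers (P2/P1) the pseudo-time steady state
        agrees with the stationary Stokes solution."""
        mesh = tiny_cylinder
        props = FluidProperties(kinematic_viscosity=4e-3, density=1.0)
        cfg = poiseuille_config("p2p1")
        bcs = make_poiseuille_bcs(exact_pois)
        s_st = solve_stokes(mesh, props, cfg, bcs)
        s_ns = solve_navier_stokes_steady(mesh, props, cfg, bcs)
        num = np.linalg.norm(s_ns.v - s_st.v)
        den = np.linalg.norm(s_st.v)
        assert num / den < 1e-3

    def test_p1p1_stabilizations_agree_to_discretization_error(
            self, tiny_cylinder, exact_pois):
        """P1/P1 uses CIP for Stokes but the interior penalty for
        Navier-Stokes; the two stabilized solutions differ only at the
        discretization-error level."""
        mesh = tiny_cylinder
        props = FluidProperties(kinematic_viscosity=4e-3, density=1.0)
        cfg = poiseuille_config("p1p1")
        bcs = make_poiseuille_bcs(exact_pois)
        s_st = solve_stokes(mesh, props, cfg, bcs)
        s_ns = solve_navier_stokes_steady(mesh, props, cfg, bcs)
        assert (np.linalg.norm(s_ns.v - s_st.v)
                / np.linalg.norm(s_st.v)) < 0.05

    def test_steady_state_criterion_met(self, tiny_cylinder, exact_pois):
        mesh = tiny_cylinder
        props = FluidProperties(kinematic_viscosity=4e-3, density=1.0)
        cfg = poiseuille_config("p1p1")
        sol = solve_navier_stokes_steady(mesh, props, cfg,
                                         make_poiseuille_bcs(exact_pois))
        assert sol.problem == "navier_stokes"
        assert sol.log["steady_norm"] < 1e-5
        assert sol.time_derivative is not None

    def test_reproduces_poiseuille_profile(self, tiny_cylinder, exact_pois):
        mesh = tiny_cylinder
        props = FluidProperties(kinematic_viscosity=4e-3, density=1.0)
        cfg = poiseuille_config("p2p1")
        sol = solve_navier_stokes_steady(mesh, props, cfg,
                                         make_poiseuille_bcs(exact_pois))
        err = l2_error_volume(sol.Vv, sol.v, exact_pois.velocity, mesh, 6,
                              relative=True)
        assert err < 0.05
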