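"""Incompressible flow solvers: stationary Stokes and steady-state
Navier-Stokes via adaptive BDF2 pseudo-time marching.

Discretizations
---------------
* Taylor-Hood P2/P1 with strong Dirichlet enforcement (the inf-sup stable
  workhorse), or
* equal-order P1/P1 stabilized by continuous-interior-penalty (CIP) jumps
  of the pressure normal gradient and the velocity divergence (Stokes) or
  by an interior-penalty gradient-jump stabilization (Navier-Stokes), with
  Dirichlet conditions enforced weakly by the non-symmetric Nitsche method
  with penalty ``beta * nu / h``.

The momentum equation can be density-scaled (divide by rho): pressure and
stresses are then "per density", which is the convention of the Poiseuille
benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp

from .fem.spaces import FunctionSpace
from .fem import assemble as asm
from .fem.linalg import SaddleSolver

__all__ = [
    "FluidProperties",
    "StabilizationWeights",
    "PseudoTimeConfig",
    "DiscretizationConfig",
    "BC",
    "BCSpec",
    "FlowSolution",
    "solve_stokes",
    "solve_navier_stokes_steady",
]


@dataclass(frozen=True)
class FluidProperties:
    """Fluid constants.  With ``density_scaled`` the momentum equation is
    divided by rho: the viscosity coefficient is kinematic and pressure/WSS
    come out scaled by density."""

    dynamic_viscosity: Optional[float] = None  # mu [Pa s]
    kinematic_viscosity: Optional[float] = None  # nu [m^2/s]
    density: float = 1.0  # rho [kg/m^3]
    density_scaled: bool = True

    def __post_init__(self):
        mu, nu, rho = self.dynamic_viscosity, self.kinematic_viscosity, self.density
        if mu is None and nu is None:
            raise ValueError("provide dynamic or kinematic viscosity")
        if rho <= 0:
            raise ValueError("density must be positive")
        if mu is None:
            object.__setattr__(self, "dynamic_viscosity", nu * rho)
        elif nu is None:
            object.__setattr__(self, "kinematic_viscosity", mu / rho)
        elif abs(mu - nu * rho) > 1e-12 * max(abs(mu), 1e-300):
            raise ValueError("inconsistent viscosities: mu != rho * nu")
        if self.dynamic_viscosity <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def momentum_viscosity(self) -> float:
        """Coefficient multiplying the velocity gradient in the momentum
        equation as assembled (nu if density-scaled, mu otherwise)."""
        return self.kinematic_viscosity if self.density_scaled else self.dynamic_viscosity

    @property
    def momentum_density(self) -> float:
        return 1.0 if self.density_scaled else self.density


@dataclass(frozen=True)
class StabilizationWeights:
    gamma_p: float = 1e-2  # CIP pressure-gradient jumps
    gamma_v: float = 1e-2  # CIP divergence jumps
    alpha_i: float = 1e-3  # interior penalty, streamline term
    alpha_v: float = 1e-3  # interior penalty, velocity gradient jumps
    alpha_p: float = 1.0   # interior penalty, pressure gradient jumps

    def __post_init__(self):
        for name in ("gamma_p", "gamma_v", "alpha_i", "alpha_v", "alpha_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class PseudoTimeConfig:
    dt_min: float = 1e-2
    dt_max: float = 1e5
    ramp_duration: float = 0.5
    end_time: float = 1e6
    steady_tol: float = 1e-5
    dt_initial: float = 0.1
    growth: float = 1.5
    newton_max_iter: int = 12
    newton_fast_iter: int = 4


@dataclass(frozen=True)
class DiscretizationConfig:
    element_pair: str = "p2p1"  # "p1p1" | "p2p1"
    enforcement: str = "strong"  # "strong" | "nitsche"
    nitsche_beta: float = 10.0
    stress_form: str = "full_gradient"  # "full_gradient" | "symmetric"
    stabilization: StabilizationWeights = field(default_factory=StabilizationWeights)
    pseudo_time: PseudoTimeConfig = field(default_factory=PseudoTimeConfig)

    def __post_init__(self):
        if self.element_pair not in ("p1p1", "p2p1"):
            raise ValueError(f"unknown element pair {self.element_pair!r}")
        if self.enforcement not in ("strong", "nitsche"):
            raise ValueError(f"unknown enforcement {self.enforcement!r}")
        if self.stress_form not in ("full_gradient", "symmetric"):
            raise ValueError(f"unknown stress form {self.stress_form!r}")
        if self.nitsche_beta < 0:
            raise ValueError("nitsche_beta must be nonnegative")

    @property
    def velocity_degree(self) -> int:
        return 1 if self.element_pair == "p1p1" else 2

    @property
    def symmetric_stress(self) -> bool:
        return self.stress_form == "symmetric"


@dataclass(frozen=True)
class BC:
    """Boundary condition on one tagged region.

    kind: "dirichlet" (value: callable points->velocity), "traction"
    (value: callable points->traction), "do_nothing", or
    "zero_tangential_velocity" (normal component left natural)."""

    kind: str
    value: Optional[Callable] = None

    def __post_init__(self):
        kinds = ("dirichlet", "traction", "do_nothing", "zero_tangential_velocity")
        if self.kind not in kinds:
            raise ValueError(f"unknown BC kind {self.kind!r}")
        if self.kind in ("dirichlet", "traction") and self.value is None:
            raise ValueError(f"BC kind {self.kind!r} requires a value function")


@dataclass(frozen=True)
class BCSpec:
    """Per-region boundary conditions plus the body force."""

    regions: dict  # tag -> BC
    body_force: Optional[Callable] = None

    def validate(self, mesh):
        tags = set(np.unique(mesh.boundary_facet_tags).tolist())
        given = set(self.regions)
        if tags != given:
            raise ValueError(
                f"BCSpec must assign every tagged region exactly once: "
                f"mesh tags {sorted(tags)}, BC tags {sorted(given)}"
            )

    @property
    def dirichlet_only(self) -> bool:
        return all(bc.kind == "dirichlet" for bc in self.regions.values())


@dataclass
class FlowSolution:
    """Discrete velocity/pressure pair with full provenance metadata."""

    v: np.ndarray  # (n_v_dofs, gdim)
    p: np.ndarray  # (n_p_dofs,)
    mesh: object
    Vv: FunctionSpace
    Qp: FunctionSpace
    config: DiscretizationConfig
    props: FluidProperties
    bcs: BCSpec
    problem: str = "stokes"  # "stokes" | "navier_stokes"
    time_derivative: Optional[np.ndarray] = None  # final BDF2 stencil (n_v, gdim)
    log: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _make_spaces(mesh, config):
    deg_v = config.velocity_degree
    Vv = FunctionSpace(mesh, deg_v)
    Qp = FunctionSpace(mesh, 1)
    return Vv, Qp


def _normal_axis(mesh, facet_ids):
    """If all facets share an axis-aligned normal, return that axis, else None."""
    _, normals, _ = mesh.boundary_geometry
    n = normals[facet_ids]
    for k in range(mesh.dim):
        ek = np.zeros(mesh.dim)
        ek[k] = 1.0
        if np.all(np.abs(np.abs(n @ ek) - 1.0) < 1e-9):
            return k
    return None


def _strong_rows(mesh, Vv, bcs, config, ramp=1.0):
    """Collect strongly constrained vector dofs and their values."""
    gdim = mesh.dim
    rows, vals = [], []
    for tag, bc in bcs.regions.items():
        fids = mesh.facets_with_tag(tag)
        if len(fids) == 0:
            continue
        if bc.kind == "dirichlet" and config.enforcement == "strong":
            sdofs = Vv.facet_dofs(fids)
            vb = ramp * np.asarray(bc.value(Vv.dof_coords[sdofs]), dtype=float)
            for a in range(gdim):
                rows.append(sdofs * gdim + a)
                vals.append(vb[:, a])
        elif bc.kind == "zero_tangential_velocity" and config.enforcement == "strong":
            axis = _normal_axis(mesh, fids)
            if axis is None:
                raise ValueError(
                    "strong zero_tangential_velocity requires an axis-aligned "
                    "plane; use Nitsche enforcement instead"
                )
            sdofs = Vv.facet_dofs(fids)
            for a in range(gdim):
                if a == axis:
                    continue
                rows.append(sdofs * gdim + a)
                vals.append(np.zeros(len(sdofs)))
    if rows:
        rows = np.concatenate(rows)
        vals = np.concatenate(vals)
        # deduplicate (corner nodes shared by regions); last write wins is
        # avoided by unique-first which keeps the first occurrence
        rows, idx = np.unique(rows, return_index=True)
        vals = vals[idx]
        return rows, vals
    return np.array([], dtype=int), np.array([])


def _nitsche_contributions(mesh, Vv, Qp, bcs, config, nu, ramp=1.0):
    """Sum of Nitsche matrices/RHS over weakly enforced regions."""
    gdim = mesh.dim
    nv, npd = Vv.n_dofs * gdim, Qp.n_dofs
    A_vv = sp.csr_matrix((nv, nv))
    A_vp = sp.csr_matrix((nv, npd))
    A_pv = sp.csr_matrix((npd, nv))
    rv = np.zeros(nv)
    rp = np.zeros(npd)
    if config.enforcement != "nitsche":
        return A_vv, A_vp, A_pv, rv, rp
    sym = config.symmetric_stress
    beta = config.nitsche_beta
    for tag, bc in bcs.regions.items():
        fids = mesh.facets_with_tag(tag)
        if len(fids) == 0:
            continue
        if bc.kind == "dirichlet":
            vbc = None
            if bc.value is not None:
                vfun = bc.value
                vbc = (lambda x, f=vfun: ramp * np.asarray(f(x)))
            a_vv, a_vp, a_pv, r_v, r_p = asm.nitsche_system(
                Vv, Qp, fids, nu, beta, sym, vbc=vbc
            )
        elif bc.kind == "zero_tangential_velocity":
            a_vv, a_vp, a_pv, r_v, r_p = asm.nitsche_system(
                Vv, Qp, fids, nu, beta, sym, vbc=None, tangential=True
            )
        else:
            continue
        A_vv += a_vv
        A_vp += a_vp
        A_pv += a_pv
        rv += r_v
        rp += r_p
    return A_vv, A_vp, A_pv, rv, rp


def _traction_rhs(mesh, Vv, bcs, ramp=1.0):
    gdim = mesh.dim
    out = np.zeros(Vv.n_dofs * gdim)
    for tag, bc in bcs.regions.items():
        if bc.kind != "traction":
            continue
        fids = mesh.facets_with_tag(tag)
        fq = asm.FacetQuad(mesh, fids, 2 * Vv.degree + 1)
        gvals = ramp * np.asarray(bc.value(fq.xq.reshape(-1, gdim))).reshape(
            fq.n_facets, -1, gdim
        )
        out += asm.facet_functional(Vv, fq, gvals)
    return out


def _needs_pressure_gauge(bcs):
    return all(
        bc.kind in ("dirichlet",) for bc in bcs.regions.values()
    )


def _stokes_operator(mesh, Vv, Qp, config, props, bcs, ramp=1.0):
    """Assemble the (unconstrained) Stokes block system and RHS."""
    gdim = mesh.dim
    nu = props.momentum_viscosity
    sym = config.symmetric_stress
    deg = 2 * Vv.degree
    A_vv = asm.assemble_viscous(Vv, nu, sym, deg)
    B = asm.assemble_divergence(Vv, Qp, deg)
    S_p = None
    if config.element_pair == "p1p1":
        if config.enforcement != "nitsche":
            raise ValueError(
                "the stabilized P1/P1 pair requires Nitsche (weak) Dirichlet "
                "enforcement"
            )
        st = config.stabilization
        if st.gamma_p == 0.0 and st.gamma_v == 0.0:
            raise ValueError("P1/P1 requires nonzero CIP stabilization weights")
        S_v, S_p = asm.cip_matrices(Vv, Qp, st.gamma_p, st.gamma_v, nu)
        A_vv = A_vv + S_v
    n_vv, n_vp, n_pv, rv_n, rp_n = _nitsche_contributions(
        mesh, Vv, Qp, bcs, config, nu, ramp
    )
    A_vv = A_vv + n_vv
    A_vp = (-B.T) + n_vp
    A_pv = B + n_pv
    rv = rv_n + _traction_rhs(mesh, Vv, bcs, ramp)
    if bcs.body_force is not None:
        rv = rv + asm.assemble_load(Vv, bcs.body_force, 2 * Vv.degree + 2)
    rp = rp_n
    A_pp = S_p if S_p is not None else sp.csr_matrix((Qp.n_dofs, Qp.n_dofs))
    return A_vv, A_vp, A_pv, A_pp, rv, rp


def _component_decoupled(config) -> bool:
    """True when the velocity block carries no cross-component coupling:
    full-gradient stress and no divergence-jump stabilization."""
    if config.symmetric_stress:
        return False
    if config.element_pair == "p1p1" and config.stabilization.gamma_v > 0:
        return False
    return True


def solve_stokes(mesh, props: FluidProperties, config: DiscretizationConfig,
                 bcs: BCSpec) -> FlowSolution:
    """Solve the stationary Stokes problem on a tagged mesh.

    Dirichlet-only problems are gauge-fixed to a mean-zero pressure.
    """
    bcs.validate(mesh)
    Vv, Qp = _make_spaces(mesh, config)
    gdim = mesh.dim
    A_vv, A_vp, A_pv, A_pp, rv, rp = _stokes_operator(
        mesh, Vv, Qp, config, props, bcs
    )
    strong_rows, strong_vals = _strong_rows(mesh, Vv, bcs, config)
    gauge = asm.pressure_mean_vector(Qp) if _needs_pressure_gauge(bcs) else None
    mass_p = asm.pressure_mean_vector(Qp)  # lumped pressure mass diagonal
    solver = SaddleSolver(
        A_vv, A_vp, A_pv, A_pp, strong_rows,
        gauge_vec=gauge,
        precond_diag=mass_p / props.momentum_viscosity,
        decoupled=_component_decoupled(config),
    )
    solver.set_gdim(gdim)
    vflat, p = solver.solve(rv, rp, strong_vals)
    return FlowSolution(
        v=vflat.reshape(-1, gdim),
        p=p,
        mesh=mesh,
        Vv=Vv,
        Qp=Qp,
        config=config,
        props=props,
        bcs=bcs,
        problem="stokes",
    )


# ----------------------------------------------------------------------
# steady Navier-Stokes via BDF2 pseudo-time marching
# ----------------------------------------------------------------------

def _bdf2_coeffs(dt, dt_prev):
    """Variable-step BDF2 weights (a0, a1, a2) for  dv/dt ~ a0 v + a1 v1 + a2 v2."""
    if dt_prev is None:
        return 1.0 / dt, -1.0 / dt, 0.0
    r = dt / dt_prev
    a0 = (1.0 + 2.0 * r) / (dt * (1.0 + r))
    a1 = -(1.0 + r) / dt
    a2 = r * r / (dt * (1.0 + r))
    return a0, a1, a2


def solve_navier_stokes_steady(mesh, props: FluidProperties,
                               config: DiscretizationConfig,
                               bcs: BCSpec) -> FlowSolution:
    """March the incompressible Navier-Stokes equations to steady state.

    Starts from rest, ramps the Dirichlet data linearly over
    ``pseudo_time.ramp_duration`` seconds, then grows the BDF2 step
    adaptively (multiply by ``growth`` after fast Newton convergence, halve
    on divergence) within ``[dt_min, dt_max]`` until the L2 norm of the
    discrete time derivative drops below ``steady_tol``.
    """
    bcs.validate(mesh)
    pt = config.pseudo_time
    Vv, Qp = _make_spaces(mesh, config)
    gdim = mesh.dim
    nu = props.momentum_viscosity
    rho = props.momentum_density
    sym = config.symmetric_stress
    deg_v = Vv.degree

    # time-independent blocks
    A_visc = asm.assemble_viscous(Vv, nu, sym, 2 * deg_v)
    B = asm.assemble_divergence(Vv, Qp, 2 * deg_v)
    M = asm.assemble_vector_mass_volume(Vv, 2 * deg_v, coeff=rho)
    S_p = sp.csr_matrix((Qp.n_dofs, Qp.n_dofs))
    use_ip = config.element_pair == "p1p1"
    if use_ip and config.enforcement != "nitsche":
        raise ValueError("stabilized P1/P1 requires Nitsche enforcement")

    nv = Vv.n_dofs * gdim
    npd = Qp.n_dofs
    v = np.zeros(nv)
    v1 = np.zeros(nv)
    v2 = np.zeros(nv)
    p = np.zeros(npd)

    t = 0.0
    dt = min(max(pt.dt_initial, pt.dt_min), pt.dt_max)
    dt_prev = None
    st = config.stabilization
    mass_p = asm.pressure_mean_vector(Qp)
    gauge = mass_p if _needs_pressure_gauge(bcs) else None
    dt_history = []
    deg_conv = 3 * deg_v - 1

    def ramp(tt):
        return min(tt / pt.ramp_duration, 1.0) if pt.ramp_duration > 0 else 1.0

    n_steps = 0
    while t < pt.end_time:
        accepted = False
        while not accepted:
            t_new = t + dt
            r = ramp(t_new)
            a0, a1, a2 = _bdf2_coeffs(dt, dt_prev)
            n_vv, n_vp, n_pv, rv_n, rp_n = _nitsche_contributions(
                mesh, Vv, Qp, bcs, config, nu, ramp=r
            )
            rv_ext = rv_n + _traction_rhs(mesh, Vv, bcs, ramp=r)
            if bcs.body_force is not None:
                rv_ext = rv_ext + asm.assemble_load(
                    Vv, bcs.body_force, 2 * deg_v + 2
                )
            strong_rows, strong_vals = _strong_rows(
                mesh, Vv, bcs, config, ramp=r
            )
            vk = v.copy()
            pk = p.copy()
            converged = False
            res0 = None
            # stabilization frozen at the previous state within each step
            # (time-lagged), keeping the Newton Jacobian exact
            if use_ip:
                S_v, S_pm = asm.interior_penalty_matrices(
                    Vv, Qp, v.reshape(-1, gdim), st.alpha_i, st.alpha_v,
                    st.alpha_p,
                )
            else:
                S_v = sp.csr_matrix((nv, nv))
                S_pm = sp.csr_matrix((npd, npd))
            for it in range(pt.newton_max_iter):
                conv_res, conv_jac = asm.assemble_convection(
                    Vv, vk.reshape(-1, gdim), rho, deg_conv
                )
                R_v = (
                    M @ (a0 * vk + a1 * v1 + a2 * v2)
                    + conv_res
                    + (A_visc + S_v + n_vv) @ vk
                    + (-B.T + n_vp) @ pk
                    - rv_ext
                )
                R_p = (B + n_pv) @ vk + S_pm @ pk - rp_n
                if len(strong_rows):
                    R_v[strong_rows] = vk[strong_rows] - strong_vals
                res_norm = np.sqrt(np.dot(R_v, R_v) + np.dot(R_p, R_p))
                if res0 is None:
                    res0 = res_norm
                # converged relative to the step's initial imbalance, with a
                # floor at the rounding level of the assembled terms (the
                # physical scales here make fixed absolute tests meaningless)
                floor = 1e-13 * (
                    np.linalg.norm(A_visc @ vk) + np.linalg.norm(M @ (a0 * vk))
                    + np.linalg.norm(B.T @ pk) + np.linalg.norm(rv_ext) + 1e-300
                )
                if res_norm <= max(1e-8 * res0, floor):
                    converged = True
                    break
                J_vv = (M * a0 + A_visc + S_v + n_vv + conv_jac).tocsr()
                try:
                    lin = SaddleSolver(
                        J_vv, (-B.T + n_vp).tocsr(), (B + n_pv).tocsr(), S_pm,
                        strong_rows,
                        gauge_vec=gauge,
                        precond_diag=mass_p / nu,
                        decoupled=False,
                    )
                    lin.set_gdim(gdim)
                    dv, dp = lin.solve(-R_v, -R_p)
                except RuntimeError:
                    break
                if not (np.all(np.isfinite(dv)) and np.all(np.isfinite(dp))):
                    break
                vk += dv
                pk += dp
            if converged:
                accepted = True
                newton_iters = it
            else:
                dt *= 0.5
                if dt < pt.dt_min:
                    raise RuntimeError(
                        "pseudo-time step underflow: Newton failed to "
                        f"converge at dt={dt:.3e} < dt_min={pt.dt_min:.3e}"
                    )
        # step accepted
        v2, v1 = v1, v.copy()
        v, p = vk, pk
        dt_prev_accepted = dt
        t = t + dt
        n_steps += 1
        dt_history.append((t, dt, newton_iters))
        # steady-state check: relative L2 rate of change per second
        dvdt = (v - v1) / dt
        nrm_v = np.sqrt(max(v @ (M @ v), 0.0))
        norm_dvdt = np.sqrt(max(dvdt @ (M @ dvdt), 0.0)) / max(nrm_v, 1e-300)
        if t >= pt.ramp_duration and norm_dvdt < pt.steady_tol:
            break
        dt_prev = dt_prev_accepted
        if newton_iters <= pt.newton_fast_iter:
            dt = min(dt * pt.growth, pt.dt_max)
        # do not step over the end of the inflow ramp
        if t < pt.ramp_duration:
            dt = min(dt, pt.ramp_duration - t + 1e-12)

    if gauge is not None:
        p = p - (gauge @ p) / gauge.sum()
    a0, a1, a2 = _bdf2_coeffs(dt_prev_accepted, dt_prev)
    time_derivative = (a0 * v + a1 * v1 + a2 * v2).reshape(-1, gdim)
    return FlowSolution(
        v=v.reshape(-1, gdim),
        p=p,
        mesh=mesh,
        Vv=Vv,
        Qp=Qp,
        config=config,
        props=props,
        bcs=bcs,
        problem="navier_stokes",
        time_derivative=time_derivative,
        log={"steps": n_steps, "t_final": t, "dt_history": dt_history,
             "steady_norm": float(norm_dvdt)},
    )
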