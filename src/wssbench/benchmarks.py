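"""Analytic benchmarks, error norms, convergence studies and hemodynamic
indicators.

Two closed-form reference flows:

* :func:`stokes2d_exact` -- polynomial Stokes flow on the unit square
  (full-gradient stress, nu = 1):  v = (20xy^3, 5x^4 - 5y^4),
  p = 60x^2y - 20y^3 - 5.  The wall shear stress is evaluated per side;
  it is constant on three sides and grows linearly along the top, with a
  jump at the top-right corner.
* :func:`poiseuille_exact` -- Poiseuille flow in a cylinder of radius R:
  axial velocity u_m (1 - r^2/R^2), density-scaled pressure linear in z,
  and wall shear stress of magnitude 2 mu u_m / R directed against the
  flow.

Both are verified symbolically (divergence-free and momentum residual) at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import sympy as sym

from .fem import assemble as asm
from .meshing import (BoundaryLayerSpec, TaggedMesh, build_cylinder_mesh,
                      build_unit_square_mesh, region_area)
from .solver import (BC, BCSpec, DiscretizationConfig, FluidProperties,
                     StabilizationWeights, solve_navier_stokes_steady,
                     solve_stokes)
from . import wss as wssmod

__all__ = [
    "ExactSolution",
    "stokes2d_exact",
    "poiseuille_exact",
    "l2_error_volume",
    "wss_l2_error",
    "fit_convergence_rate",
    "ConvergenceStudy",
    "run_convergence_study",
    "HemodynamicSummary",
    "hemodynamic_summary",
]


@dataclass
class ExactSolution:
    """Closed-form velocity/pressure/WSS fields with problem constants."""

    velocity: Callable  # (m, dim) -> (m, dim)
    pressure: Callable  # (m, dim) -> (m,)
    wss: dict  # region tag -> callable (m, dim) -> (m, dim)
    params: dict
    dim: int

    def wss_on(self, tag):
        return self.wss[tag]


def _lambdify_vec(xs, exprs):
    fns = [sym.lambdify(xs, e, "numpy") for e in exprs]

    def f(pts):
        pts = np.atleast_2d(pts)
        cols = [np.broadcast_to(fn(*pts.T), pts.shape[:1]).astype(float)
                for fn in fns]
        return np.column_stack(cols)

    return f


def _lambdify_scalar(xs, expr):
    fn = sym.lambdify(xs, expr, "numpy")

    def f(pts):
        pts = np.atleast_2d(pts)
        return np.broadcast_to(fn(*pts.T), pts.shape[:1]).astype(float)

    return f


def stokes2d_exact() -> ExactSolution:
    """Manufactured polynomial Stokes flow on [0,1]^2 with nu=1, f=0 and
    the full-gradient stress T = -pI + grad(v).  Verified symbolically."""
    x, y = sym.symbols("x y", real=True)
    v = sym.Matrix([20 * x * y**3, 5 * x**4 - 5 * y**4])
    p = 60 * x**2 * y - 20 * y**3 - 5
    # divergence-free and momentum residual (nu * Lap v - grad p = 0)
    div_v = sym.simplify(sym.diff(v[0], x) + sym.diff(v[1], y))
    if div_v != 0:
        raise AssertionError("exact velocity is not divergence-free")
    mom = [
        sym.simplify(sym.diff(v[i], x, 2) + sym.diff(v[i], y, 2)
                     - sym.diff(p, [x, y][i]))
        for i in range(2)
    ]
    if any(m != 0 for m in mom):
        raise AssertionError("exact fields do not satisfy the Stokes system")
    grad_v = v.jacobian([x, y])
    T = -p * sym.eye(2) + grad_v  # nu = 1, full gradient
    normals = {1: (-1, 0), 2: (1, 0), 3: (0, -1), 4: (0, 1)}
    wss = {}
    for tag, n in normals.items():
        nvec = sym.Matrix(n)
        tn = T * nvec
        tt = tn - (tn.dot(nvec)) * nvec
        wss[tag] = _lambdify_vec((x, y), [sym.simplify(tt[0]), sym.simplify(tt[1])])
    return ExactSolution(
        velocity=_lambdify_vec((x, y), list(v)),
        pressure=_lambdify_scalar((x, y), p),
        wss=wss,
        params={"nu": 1.0},
        dim=2,
    )


def poiseuille_exact(R: float = 1e-3, u_m: float = 1.0, mu: float = 4e-3,
                     rho: float = 1.0, length: float = 2e-3,
                     density_scaled: bool = True) -> ExactSolution:
    """Poiseuille flow through a cylinder aligned with z in [0, length].

    Wall WSS magnitude is 2 mu u_m / R (divided by rho when density-scaled),
    directed along -z.  Pressure is normalized to zero at the outlet.
    """
    if R <= 0 or u_m <= 0 or mu <= 0:
        raise ValueError("R, u_m and mu must be positive")
    x, y, z = sym.symbols("x y z", real=True)
    # exact rational constants so the PDE-residual check is exact
    Rs, ums, mus, rhos, Ls = (sym.nsimplify(c, rational=True)
                              for c in (R, u_m, mu, rho, length))
    nu_eff = mus / rhos if density_scaled else mus
    v = sym.Matrix([0, 0, ums * (1 - (x**2 + y**2) / Rs**2)])
    p = 4 * nu_eff * ums / Rs**2 * (Ls - z)
    div_v = sym.simplify(v[0].diff(x) + v[1].diff(y) + v[2].diff(z))
    if div_v != 0:
        raise AssertionError("Poiseuille velocity is not divergence-free")
    # momentum: nu Lap v - grad p = 0 (convection vanishes identically)
    lap = sym.Matrix([sum(v[i].diff(c, 2) for c in (x, y, z)) for i in range(3)])
    conv = v.jacobian([x, y, z]) * v
    mom = conv - nu_eff * lap + sym.Matrix([p.diff(c) for c in (x, y, z)])
    if any(sym.simplify(m) != 0 for m in mom):
        raise AssertionError("Poiseuille fields do not satisfy Navier-Stokes")
    tau_mag = 2 * nu_eff * ums / Rs
    tau = np.array([0.0, 0.0, -float(tau_mag)])

    def wss_wall(pts):
        pts = np.atleast_2d(pts)
        return np.broadcast_to(tau, (len(pts), 3)).copy()

    vbar = u_m / 2.0
    return ExactSolution(
        velocity=_lambdify_vec((x, y, z), list(v)),
        pressure=_lambdify_scalar((x, y, z), p),
        wss={3: wss_wall},
        params={
            "R": R, "u_m": u_m, "mu": mu, "rho": rho, "length": length,
            "v_bar": vbar, "wss_magnitude": float(tau_mag),
            "flow_rate": float(np.pi * R**2 * vbar),
            "density_scaled": density_scaled,
        },
        dim=3,
    )


# ----------------------------------------------------------------------
# error norms and rate fitting
# ----------------------------------------------------------------------

def l2_error_volume(space, coeffs, exact, mesh, qdeg: int = 8,
                    relative: bool = False) -> float:
    """L2(Omega) error of a scalar or vector FE function against a callable."""
    coeffs = np.asarray(coeffs)
    vector = coeffs.ndim == 2
    e2 = ex2 = 0.0
    cq = asm.CellQuad(mesh, qdeg)
    for ch in cq.chunks():
        if vector:
            uh = ch.eval_vector(space, coeffs)
            ue = np.asarray(exact(ch.xq.reshape(-1, mesh.dim))).reshape(uh.shape)
            e2 += float((ch.wdet * ((uh - ue) ** 2).sum(-1)).sum())
            ex2 += float((ch.wdet * (ue**2).sum(-1)).sum())
        else:
            uh = ch.eval_scalar(space, coeffs)
            ue = np.asarray(exact(ch.xq.reshape(-1, mesh.dim))).reshape(uh.shape)
            e2 += float((ch.wdet * (uh - ue) ** 2).sum())
            ex2 += float((ch.wdet * ue**2).sum())
    err = np.sqrt(e2)
    return err / np.sqrt(ex2) if relative else err


def wss_l2_error(field: wssmod.WSSField, exact: ExactSolution,
                 tags: Optional[Sequence[int]] = None, qdeg: int = 8,
                 relative: bool = False) -> float:
    """L2(Gamma_wall) error of a WSS field against the exact per-region WSS.

    Segmented fields are compared segment by segment, so a discontinuity of
    the exact WSS at a corner is never smeared across regions."""
    mesh = field.mesh
    tags = list(tags if tags is not None else field.region_tags)
    e2 = ex2 = 0.0
    for tag in tags:
        fids = mesh.facets_with_tag(tag)
        fq = asm.FacetQuad(mesh, fids, qdeg)
        vals = field.eval_on(
            fq, segment_tag=tag if field.segments is not None else None
        )
        ex = np.asarray(exact.wss_on(tag)(fq.xq.reshape(-1, mesh.dim)))
        ex = ex.reshape(vals.shape)
        e2 += float((fq.wq * ((vals - ex) ** 2).sum(-1)).sum())
        ex2 += float((fq.wq * (ex**2).sum(-1)).sum())
    err = np.sqrt(e2)
    return err / np.sqrt(ex2) if relative else err


def fit_convergence_rate(resolutions, errors) -> float:
    """Least-squares slope of log(error) against log(h).

    ``resolutions`` are mesh sizes h (or anything proportional to h)."""
    h = np.asarray(resolutions, dtype=float)
    e = np.asarray(errors, dtype=float)
    if len(h) < 2 or len(h) != len(e):
        raise ValueError("need at least two (resolution, error) pairs")
    if np.any(e <= 0) or np.any(h <= 0):
        raise ValueError("resolutions and errors must be positive")
    return float(np.polyfit(np.log(h), np.log(e), 1)[0])


# ----------------------------------------------------------------------
# convergence studies
# ----------------------------------------------------------------------

@dataclass
class ConvergenceStudy:
    problem: str
    element_pair: str
    mesh_family: str
    levels: list  # [{resolution, h_max, errors: {name: float}}]
    rates: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def fit_rates(self):
        """Fit log-log slopes against the nominal resolution (edge length,
        or 1/N for the square), the abscissa the benchmark reports."""
        names = self.levels[0]["errors"].keys()
        hs = [lv["h_nominal"] for lv in self.levels]
        self.rates = {
            name: fit_convergence_rate(hs, [lv["errors"][name] for lv in self.levels])
            for name in names
        }
        return self.rates

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for lv in self.levels:
            row = {"resolution": lv["resolution"], "h_max": lv["h_max"]}
            row.update(lv["errors"])
            rows.append(row)
        return pd.DataFrame(rows)

    def errors_of(self, name):
        return [lv["errors"][name] for lv in self.levels]


def stokes2d_config(element_pair: str,
                    nitsche_beta: float = 10.0) -> DiscretizationConfig:
    """The 2D benchmark discretization: P2/P1 strong, or P1/P1 with CIP
    weights 1e-2 under Nitsche enforcement; full-gradient stress."""
    if element_pair == "p2p1":
        return DiscretizationConfig(
            element_pair="p2p1", enforcement="strong",
            stress_form="full_gradient",
        )
    return DiscretizationConfig(
        element_pair="p1p1", enforcement="nitsche", nitsche_beta=nitsche_beta,
        stress_form="full_gradient",
        stabilization=StabilizationWeights(gamma_p=1e-2, gamma_v=1e-2),
    )


def poiseuille_config(element_pair: str,
                      nitsche_beta: float = 10.0) -> DiscretizationConfig:
    """The cylinder benchmark discretization: symmetric stress; P1/P1 uses
    CIP weights gamma_p=1, gamma_v=1e-3 under Nitsche enforcement."""
    if element_pair == "p2p1":
        return DiscretizationConfig(
            element_pair="p2p1", enforcement="strong",
            stress_form="symmetric",
        )
    return DiscretizationConfig(
        element_pair="p1p1", enforcement="nitsche", nitsche_beta=nitsche_beta,
        stress_form="symmetric",
        stabilization=StabilizationWeights(gamma_p=1.0, gamma_v=1e-3),
    )


def _poiseuille_bcs(exact: ExactSolution) -> BCSpec:
    vin = exact.velocity
    zero = lambda x: np.zeros_like(np.atleast_2d(x))
    return BCSpec(regions={
        1: BC("dirichlet", vin),
        2: BC("zero_tangential_velocity"),
        3: BC("dirichlet", zero),
    })


def _wss_fields(sol, method: str, tags, per_segment: bool):
    """Compute one WSS method; for polygonal 2D domains every method is
    evaluated segment-wise so corner discontinuities stay per-side."""
    m = method.lower()
    if m.startswith("bflux"):
        space = m.split("-")[1].upper()
        if per_segment:
            return wssmod.boundary_flux_wss_per_segment(sol, tags, space)
        return wssmod.boundary_flux_wss(sol, tags, space)
    space = m.upper()
    if per_segment and space in ("P1", "P2"):
        fields = {t: wssmod.project_wss(sol, (t,), space) for t in tags}
        first = fields[tags[0]]
        total = sum(f.values for f in fields.values())
        return wssmod.WSSField(
            "projection", space, "continuous", sol.mesh, tuple(tags),
            np.concatenate([f.facet_ids for f in fields.values()]),
            total, W=first.W,
            segments={t: f.values for t, f in fields.items()},
        )
    return wssmod.project_wss(sol, tags, space)


DEFAULT_WSS_METHODS = {
    "p1p1": ("bflux-p1", "p1", "dg1", "dg0"),
    "p2p1": ("bflux-p1", "bflux-p2", "p1", "dg1", "dg0"),
}


def run_convergence_study(problem: str, element_pair: str,
                          mesh_family: str = "uniform",
                          levels: Sequence = None,
                          wss_methods: Sequence[str] = None,
                          nitsche_beta: float = 10.0,
                          solver: str = "stokes",
                          relative: bool = True,
                          qdeg_err: int = 6) -> ConvergenceStudy:
    """Run one of the analytic benchmarks over a mesh sequence and collect
    relative L2 errors of velocity, pressure and the requested WSS methods,
    with fitted log-log rates.

    problem "stokes2d": ``levels`` are elements-per-side counts N
    (default 8..256 by doubling); "poiseuille": ``levels`` are edge
    lengths in meters.
    """
    if wss_methods is None:
        wss_methods = DEFAULT_WSS_METHODS[element_pair]
    study_levels = []
    if problem == "stokes2d":
        exact = stokes2d_exact()
        cfg = stokes2d_config(element_pair, nitsche_beta)
        props = FluidProperties(kinematic_viscosity=1.0, density=1.0)
        if levels is None:
            levels = [2 ** (3 + i) for i in range(6)]
        side_tags = (1, 2, 3, 4)
        for n in levels:
            mesh = build_unit_square_mesh(int(n))
            bcs = BCSpec(regions={t: BC("dirichlet", exact.velocity)
                                  for t in side_tags})
            sol = solve_stokes(mesh, props, cfg, bcs)
            errors = {
                "velocity": l2_error_volume(sol.Vv, sol.v, exact.velocity,
                                            mesh, qdeg_err + 2, relative),
                "pressure": l2_error_volume(sol.Qp, sol.p, exact.pressure,
                                            mesh, qdeg_err + 2, relative),
            }
            for meth in wss_methods:
                fld = _wss_fields(sol, meth, side_tags, per_segment=True)
                errors[f"wss_{meth}"] = wss_l2_error(
                    fld, exact, side_tags, qdeg_err + 2, relative
                )
            study_levels.append({
                "resolution": int(n),
                "h_nominal": 1.0 / float(n),
                "h_max": float(mesh.cell_diameter.max()),
                "n_cells": int(mesh.n_cells),
                "errors": errors,
            })
    elif problem == "poiseuille":
        exact = poiseuille_exact()
        cfg = poiseuille_config(element_pair, nitsche_beta)
        props = FluidProperties(
            kinematic_viscosity=exact.params["mu"] / exact.params["rho"],
            density=1.0, density_scaled=True,
        )
        if levels is None:
            levels = (4e-4, 3e-4, 2.2e-4)
        bl = BoundaryLayerSpec() if mesh_family == "boundary_layer" else None
        R = exact.params["R"]
        L = exact.params["length"]
        for e in levels:
            mesh = build_cylinder_mesh(R, L, float(e), bl)
            bcs = _poiseuille_bcs(exact)
            if solver == "stokes":
                sol = solve_stokes(mesh, props, cfg, bcs)
            else:
                sol = solve_navier_stokes_steady(mesh, props, cfg, bcs)
            errors = {
                "velocity": l2_error_volume(sol.Vv, sol.v, exact.velocity,
                                            mesh, qdeg_err, relative),
                "pressure": l2_error_volume(sol.Qp, sol.p, exact.pressure,
                                            mesh, qdeg_err, relative),
            }
            for meth in wss_methods:
                fld = _wss_fields(sol, meth, (3,), per_segment=False)
                errors[f"wss_{meth}"] = wss_l2_error(
                    fld, exact, (3,), qdeg_err, relative
                )
            study_levels.append({
                "resolution": float(e),
                "h_nominal": float(e),
                "h_max": float(mesh.cell_diameter.max()),
                "n_cells": int(mesh.n_cells),
                "errors": errors,
            })
    else:
        raise ValueError(f"unknown problem {problem!r}")
    study = ConvergenceStudy(
        problem=problem, element_pair=element_pair, mesh_family=mesh_family,
        levels=study_levels,
        metadata={"wss_methods": list(wss_methods),
                  "nitsche_beta": nitsche_beta, "solver": solver},
    )
    study.fit_rates()
    return study


# ----------------------------------------------------------------------
# hemodynamic indicators
# ----------------------------------------------------------------------

@dataclass
class HemodynamicSummary:
    """Dome WSS statistics and the low-shear-area indicator."""

    max_wss: float
    min_wss: float
    avg_wss: float
    lsa: float  # percent of dome area with |tau| < threshold
    parent_mean_wss: float
    threshold: float  # 0.1 * parent mean
    dome_area: float

    def __post_init__(self):
        if not (self.min_wss <= self.avg_wss <= self.max_wss + 1e-12):
            raise AssertionError("inconsistent dome WSS statistics")
        if not (0.0 <= self.lsa <= 100.0):
            raise AssertionError("LSA must be a percentage")

    def to_dict(self):
        return {"max": self.max_wss, "min": self.min_wss, "avg": self.avg_wss,
                "lsa": self.lsa, "parent_mean": self.parent_mean_wss,
                "threshold": self.threshold}


def _region_mean_mag(field: wssmod.WSSField, tags, qdeg=4):
    mesh = field.mesh
    tot = area = 0.0
    for tag in tags:
        fids = mesh.facets_with_tag(tag)
        fq = asm.FacetQuad(mesh, fids, qdeg)
        mag = np.linalg.norm(field.eval_on(fq), axis=2)
        tot += float((fq.wq * mag).sum())
        area += float(fq.wq.sum())
    return tot / area, area


def _native_magnitudes_region(field: wssmod.WSSField, tags):
    mesh = field.mesh
    fids = mesh.facets_with_tag(tags)
    if field.kind == "continuous":
        dofs = field.W.facet_dofs(fids)
        return np.linalg.norm(field.values[dofs], axis=1)
    pos = wssmod._positions_in(field.facet_ids, fids)
    if field.kind == "dg0":
        return np.linalg.norm(field.values[pos], axis=1)
    return np.linalg.norm(field.values[pos], axis=2).ravel()


def hemodynamic_summary(field: wssmod.WSSField, dome_tags, parent_tags,
                        qdeg: int = 4) -> HemodynamicSummary:
    """Max/min/average |tau| over the dome region (max/min on the method's
    native evaluation set) and the low shear area: the percentage of dome
    area where |tau| falls below 10% of the parent-artery mean, accumulated
    quadrature-point-wise facet by facet."""
    dome_tags = wssmod._as_tuple(dome_tags)
    parent_tags = wssmod._as_tuple(parent_tags)
    if set(dome_tags) & set(parent_tags):
        raise ValueError("dome and parent regions must be disjoint")
    mesh = field.mesh
    if len(mesh.facets_with_tag(dome_tags)) == 0:
        raise ValueError("empty dome region")
    if len(mesh.facets_with_tag(parent_tags)) == 0:
        raise ValueError("empty parent-artery region")
    parent_mean, _ = _region_mean_mag(field, parent_tags, qdeg)
    threshold = 0.1 * parent_mean
    avg, dome_area = _region_mean_mag(field, dome_tags, qdeg)
    native = _native_magnitudes_region(field, dome_tags)
    low = 0.0
    for tag in dome_tags:
        fids = mesh.facets_with_tag(tag)
        fq = asm.FacetQuad(mesh, fids, qdeg)
        mag = np.linalg.norm(field.eval_on(fq), axis=2)
        low += float((fq.wq * (mag < threshold)).sum())
    return HemodynamicSummary(
        max_wss=float(native.max()),
        min_wss=float(native.min()),
        avg_wss=float(avg),
        lsa=100.0 * low / dome_area,
        parent_mean_wss=float(parent_mean),
        threshold=float(threshold),
        dome_area=float(dome_area),
    )
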