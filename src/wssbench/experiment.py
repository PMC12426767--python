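"""Experiment orchestration: run a configured study, export its artifacts,
and record a reproduction manifest."""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import __version__
from .benchmarks import (ConvergenceStudy, hemodynamic_summary,
                         poiseuille_config, run_convergence_study)
from .config import RunConfig
from .io import read_tagged_mesh
from .solver import (BC, BCSpec, DiscretizationConfig, FluidProperties,
                     StabilizationWeights, solve_navier_stokes_steady,
                     solve_stokes)
from . import wss as wssmod
from .benchmarks import DEFAULT_WSS_METHODS, _wss_fields

__all__ = ["run_experiment", "export_study_csv", "read_study_csv",
           "export_summary_json"]


def export_study_csv(study: ConvergenceStudy, path: str):
    """CSV table: one row per level plus a final ``rate`` row."""
    df = study.to_dataframe()
    rate_row = {"resolution": "rate", "h_max": ""}
    rate_row.update({k: study.rates[k] for k in study.rates})
    df = pd.concat([df, pd.DataFrame([rate_row])], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.12e")
    return path


def read_study_csv(path: str):
    """Re-parse an exported study table into (levels_df, rates)."""
    df = pd.read_csv(path)
    rates = df[df["resolution"] == "rate"].iloc[0].drop(
        ["resolution", "h_max"]
    ).astype(float).to_dict()
    levels = df[df["resolution"] != "rate"].copy()
    for c in levels.columns:
        levels[c] = pd.to_numeric(levels[c])
    return levels.reset_index(drop=True), rates


def export_summary_json(summary, path: str):
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    return path


def _manifest(config: RunConfig, extra: dict) -> dict:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    m = {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "code_version": __version__,
        "config": config.model_dump(mode="json"),
    }
    m.update(extra)
    return m


def _mesh_checksum(mesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.cells).tobytes())
    h.update(np.ascontiguousarray(mesh.boundary_facet_tags).tobytes())
    return h.hexdigest()


def run_experiment(config: RunConfig) -> dict:
    """Execute the configured experiment; writes CSV/JSON artifacts and a
    manifest into ``config.output_dir`` and returns a result dict."""
    os.makedirs(config.output_dir, exist_ok=True)
    out = {}
    if config.experiment in ("stokes2d", "poiseuille"):
        study = run_convergence_study(
            config.experiment,
            config.element_pair,
            mesh_family=config.mesh_family,
            levels=config.levels,
            wss_methods=config.wss_methods,
            nitsche_beta=config.nitsche_beta,
            solver=config.solver,
        )
        name = (f"{config.experiment}_{config.element_pair}"
                f"_{config.mesh_family}")
        csv_path = os.path.join(config.output_dir, name + ".csv")
        export_study_csv(study, csv_path)
        out["study"] = study
        out["csv"] = csv_path
        extra = {"rates": study.rates}
    elif config.experiment == "external_mesh":
        mesh = read_tagged_mesh(config.mesh_path, config.region_names_path)
        fl = config.fluid
        props = FluidProperties(
            dynamic_viscosity=fl.dynamic_viscosity,
            kinematic_viscosity=fl.kinematic_viscosity,
            density=fl.density, density_scaled=fl.density_scaled,
        )
        disc = _external_discretization(config)
        bcs = _external_bcs(config, mesh)
        if config.solver == "stokes":
            sol = solve_stokes(mesh, props, disc, bcs)
        else:
            sol = solve_navier_stokes_steady(mesh, props, disc, bcs)
        methods = config.wss_methods or DEFAULT_WSS_METHODS[config.element_pair]
        wall_tags = tuple(config.wall_tags)
        summaries = {}
        for meth in methods:
            fld = _wss_fields(sol, meth, wall_tags + ((config.dome_tag,)
                              if config.dome_tag else ()), per_segment=False)
            wssmod.wss_magnitude_table(fld).to_csv(
                os.path.join(config.output_dir, f"wss_{meth}.csv"),
                index=False, float_format="%.10e",
            )
            if fld.kind == "continuous":
                from .io import write_vtu
                write_vtu(mesh,
                          os.path.join(config.output_dir, f"wss_{meth}.vtu"),
                          {f"wss_{meth}": fld.values})
            if config.dome_tag is not None and config.parent_tag is not None:
                s = hemodynamic_summary(fld, config.dome_tag, config.parent_tag)
                summaries[meth] = s
                export_summary_json(
                    s, os.path.join(config.output_dir, f"summary_{meth}.json")
                )
        out["solution"] = sol
        out["summaries"] = summaries
        extra = {"mesh_checksum": _mesh_checksum(mesh)}
    else:  # pragma: no cover - schema forbids
        raise ValueError(config.experiment)
    manifest = _manifest(config, extra)
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    out["manifest"] = manifest
    return out


def _external_discretization(config: RunConfig) -> DiscretizationConfig:
    st = config.stabilization
    weights = StabilizationWeights(
        gamma_p=st.gamma_p if st.gamma_p is not None else 1.0,
        gamma_v=st.gamma_v if st.gamma_v is not None else 1e-3,
        alpha_i=st.alpha_i, alpha_v=st.alpha_v, alpha_p=st.alpha_p,
    )
    return DiscretizationConfig(
        element_pair=config.element_pair,
        enforcement=config.resolved_enforcement,
        nitsche_beta=config.nitsche_beta,
        stress_form="symmetric",
        stabilization=weights,
    )


def _external_bcs(config: RunConfig, mesh) -> BCSpec:
    """Parabolic inflow with the configured mean velocity on the inlet disc,
    no-slip walls (and dome), do-nothing outlets."""
    if config.inlet_tag is None or not config.wall_tags:
        raise ValueError("external meshes need inlet_tag and wall_tags")
    fids = mesh.facets_with_tag(config.inlet_tag)
    areas, normals, cents = mesh.boundary_geometry
    a = areas[fids]
    c = cents[fids]
    center = (a[:, None] * c).sum(0) / a.sum()
    n = (a[:, None] * normals[fids]).sum(0)
    n /= np.linalg.norm(n)
    radius = np.sqrt(a.sum() / np.pi)
    vmax = 2.0 * config.mean_inflow_velocity

    def vin(x):
        d = np.atleast_2d(x) - center
        d = d - (d @ n)[:, None] * n[None, :]
        r2 = (d**2).sum(1) / radius**2
        prof = vmax * np.maximum(1.0 - r2, 0.0)
        return -prof[:, None] * n[None, :]

    zero = lambda x: np.zeros_like(np.atleast_2d(x))
    regions = {config.inlet_tag: BC("dirichlet", vin)}
    for t in config.outlet_tags:
        regions[int(t)] = BC("do_nothing")
    wall_like = list(config.wall_tags)
    for t in (config.dome_tag, config.parent_tag):
        if t is not None and t not in regions and t not in wall_like:
            wall_like.append(t)
    for t in wall_like:
        regions[int(t)] = BC("dirichlet", zero)
    return BCSpec(regions=regions)
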