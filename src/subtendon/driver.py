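"""End-to-end orchestration of the experiment grid and report tables.

``run_full_sweep`` builds the archetype geometry, meshes it, solves the
seven interface models (frictionless, five friction coefficients, bonded)
under each isolated 100 N sub-tendon load, postprocesses the outcome
measures and writes a tidy CSV plus a JSON run manifest with the config
hash and artefact checksums.  ``run_invitro_report`` regenerates the
published summary table with the significance stars.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .core import SubTendonID
from .fe import (InterfaceModel, LoadCase, SolverOptions, isolated_load_grid,
                 run_load_cases)
from .geometry import make_archetype
from .invitro import (load_table1, posthoc_vs_soleus, sex_subgroup_means,
                      summarize_group)
from .material import neo_hookean_from_modulus
from .meshing import converge_mesh, loft_mesh
from .postprocess import sweep_table

log = logging.getLogger("subtendon")

__all__ = ["run_full_sweep", "run_invitro_report"]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def materials_from_config(config: RunConfig):
    return {s: neo_hookean_from_modulus(config.moduli_mpa[s.value],
                                        config.poisson)
            for s in SubTendonID}


def interface_grid_from_config(config: RunConfig):
    grid = []
    if config.include_frictionless:
        grid.append(InterfaceModel("frictionless", k_n=config.k_n,
                                   k_t=config.k_t))
    grid += [InterfaceModel("frictional", mu=m, k_n=config.k_n,
                            k_t=config.k_t) for m in config.mu_values]
    if config.include_bonded:
        grid.append(InterfaceModel("bonded", k_n=config.k_n, k_t=config.k_t))
    return grid


def run_full_sweep(config: RunConfig, options: SolverOptions | None = None
                   ) -> pd.DataFrame:
    """Run one archetype's full interface x load sweep; write artefacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "geometry"
    artefacts: list[Path] = []
    try:
        geometry = make_archetype(config.model_id,
                                  overrides=config.geometry_overrides or None)
        materials = materials_from_config(config)
        stage = "mesh"
        h = config.edge_length
        if config.converge:
            stage = "mesh convergence"
            h, table = converge_mesh(
                geometry, materials,
                LoadCase(loaded={SubTendonID.SOL},
                         force_per_subtendon=config.force_per_subtendon_n,
                         ramp_steps=config.ramp_steps),
                criterion=config.convergence_criterion, h0=h,
                solver_options=options)
            table.to_csv(outdir / "mesh_convergence.csv", index=False)
            artefacts.append(outdir / "mesh_convergence.csv")
        mesh = loft_mesh(geometry, h)
        log.info("model %s meshed: %d elements (h = %.2f mm)",
                 config.model_id, mesh.n_elements, h)
        stage = "solve"
        solutions = run_load_cases(
            mesh, materials, interface_grid_from_config(config),
            isolated_load_grid(force=config.force_per_subtendon_n,
                               ramp_steps=config.ramp_steps),
            options=options)
        stage = "postprocess"
        table = sweep_table(solutions, config.model_id, mesh,
                            exclusion_layers=config.exclusion_layers)
        csv_path = outdir / f"sweep_model{config.model_id}.csv"
        table.to_csv(csv_path, index=False)
        artefacts.append(csv_path)
        if config.write_vtu:
            from .vtkio import write_solution_vtu
            for (iface, load), sol in solutions.items():
                p = outdir / f"model{config.model_id}_{iface}_{load}.vtu"
                write_solution_vtu(sol, p)
                artefacts.append(p)
    except Exception as exc:
        raise RuntimeError(f"sweep failed at stage '{stage}': {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "version": __version__,
        "n_elements": int(mesh.n_elements),
        "max_edge_length_mm": float(h),
        "elapsed_s": round(time.time() - t_start, 2),
        "artefacts": {str(p.name): _checksum(p) for p in artefacts},
    }
    with open(outdir / f"manifest_model{config.model_id}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return table


def run_invitro_report(table: pd.DataFrame | None = None,
                       output_dir: str | None = None) -> dict:
    """Mean/SD summary, omnibus tests and post hoc stars per metric.

    Uses the packaged per-specimen fixture when no table is given.  Returns
    a dict with the summary table, the post hoc star table and the
    male/female whole-tendon subgroup means; writes them as CSV when
    ``output_dir`` is given.
    """
    if table is None:
        table = load_table1()
    if table["specimen"].nunique() < 2:
        raise ValueError("need at least two specimens")
    summary = summarize_group(table)
    if (table["sub_tendon"] == SubTendonID.SOL).any():
        posthoc = posthoc_vs_soleus(table)
    else:
        log.warning("no soleus rows: post hoc comparisons skipped")
        posthoc = None
    report = {
        "summary": summary,
        "posthoc": posthoc,
        "sex_subgroups": sex_subgroup_means(table),
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.round(1).to_csv(out / "invitro_summary.csv")
        if posthoc is not None:
            posthoc.to_csv(out / "invitro_posthoc.csv")
        with open(out / "invitro_sex_subgroups.json", "w") as fh:
            json.dump(report["sex_subgroups"], fh, indent=2)
    return report
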