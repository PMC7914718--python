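"""Artifact writers/readers: CSV tables, JSON manifests, legacy-ASCII VTK.

All simulation outputs are plain text.  The VTK writer emits legacy
unstructured-grid files (hexahedra for the matrix, vertices for cells)
that ParaView reads as a time series when written with indexed names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ecm import EcmMesh, FemSolution
from .engine import ScenarioResult, SimulationState

CELL_COLUMNS = ["id", "x", "y", "z", "phenotype", "mi", "group", "cj_count"]


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def cell_table(state: SimulationState) -> pd.DataFrame:
    rows = [{
        "id": c.id, "x": c.position[0], "y": c.position[1], "z": c.position[2],
        "phenotype": c.phenotype, "mi": c.mi, "group": c.group,
        "cj_count": c.cj_count,
    } for c in state.cells]
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def write_cells(state: SimulationState, path) -> None:
    cell_table(state).to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cell table missing column(s): {sorted(missing)}")
    return df


def write_result(result: ScenarioResult, outdir) -> Path:
    """Write metrics/events/cells CSVs plus the JSON run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.events.to_csv(out / "events.csv", index=False)
    write_cells(result.state, out / "cells_final.csv")
    edges = [sorted(e) for e in result.state.cj_edges]
    with open(out / "cj_edges.txt", "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=_json_default)
    return out


def read_manifest(path) -> dict:
    with open(path) as fh:
        m = json.load(fh)
    for key in ("c_sub", "zeta", "c_rep"):
        if key not in m:
            raise SchemaError(f"manifest missing calibration constant {key!r}")
    return m


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# VTK (legacy ASCII)
# ---------------------------------------------------------------------------

def write_vtk_mesh(mesh: EcmMesh, path, solution: FemSolution = None) -> None:
    """Unstructured-grid file with element modulus/tag and, if a solution is
    given, nodal displacements."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibered ECM\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.coords:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        ne = mesh.n_elems
        fh.write(f"CELLS {ne} {ne * 9}\n")
        for conn in mesh.connectivity:
            fh.write("8 " + " ".join(str(int(v)) for v in conn) + "\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("\n".join(["12"] * ne) + "\n")
        fh.write(f"CELL_DATA {ne}\n")
        fh.write("SCALARS youngs_modulus float 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{v:.6g}" for v in mesh.E_elem) + "\n")
        fh.write("SCALARS fiber_tag int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(v)) for v in mesh.tag) + "\n")
        if solution is not None:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            fh.write("VECTORS displacement float\n")
            for u in solution.displacement:
                fh.write(f"{u[0]:.6g} {u[1]:.6g} {u[2]:.6g}\n")


def write_vtk_cells(state: SimulationState, path) -> None:
    """Point-cloud file of the cells with phenotype/MI/group scalars."""
    phen_code = {"MSC": 0, "CM_early": 1, "CM_late": 2}
    cells = state.cells
    n = len(cells)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncells\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} float\n")
        for c in cells:
            p = c.position
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"CELLS {n} {n * 2}\n")
        for k in range(n):
            fh.write(f"1 {k}\n")
        fh.write(f"CELL_TYPES {n}\n")
        fh.write("\n".join(["1"] * n) + ("\n" if n else ""))
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS phenotype int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(phen_code[c.phenotype]) for c in cells)
                 + ("\n" if n else ""))
        fh.write("SCALARS maturation float 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{c.mi:.6g}" for c in cells) + ("\n" if n else ""))
        fh.write("SCALARS group int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(c.group) for c in cells) + ("\n" if n else ""))


def vtk_series_name(prefix: str, step_index: int) -> str:
    """Indexed file name so viewers pick the files up as a time series."""
    return f"{prefix}_{step_index:05d}.vtk"
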