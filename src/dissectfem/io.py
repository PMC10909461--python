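"""Result export: legacy ASCII VTK unstructured grids and CSV summaries."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fem.mesh import Mesh

_VTK_CELL = {"quad4": 9, "hex8": 12}
_VTK_IFACE = {2: 3, 4: 9}   # line / quad midsurface cells


def write_vtk(path: str | Path, mesh: Mesh, u: np.ndarray,
              cell_fields: dict[str, np.ndarray] | None = None,
              interface=None,
              interface_fields: dict[str, np.ndarray] | None = None) -> Path:
    """Write the deformed mesh (and optionally the interface mid-surface).

    Bulk cells come first, then interface mid-surface cells; per-cell
    fields of either kind are padded with NaN on the other kind.
    """
    path = Path(path)
    dim = mesh.dim
    nn = mesh.n_nodes
    pts = np.zeros((nn, 3))
    pts[:, :dim] = mesh.nodes + u.reshape(-1, dim)
    cells = [tuple(c) for c in mesh.elems]
    types = [_VTK_CELL[mesh.elem_type]] * len(cells)
    if interface is not None:
        m = interface.m
        for pair in interface.pairs:
            cells.append(tuple(pair[:m]))     # bottom facet as midsurface
        types += [_VTK_IFACE[m]] * interface.n

    lines = ["# vtk DataFile Version 3.0", "dissectfem output", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {nn} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in pts]
    total = sum(len(c) + 1 for c in cells)
    lines.append(f"CELLS {len(cells)} {total}")
    lines += [" ".join(map(str, (len(c),) + c)) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += [str(t) for t in types]

    nb = mesh.elems.shape[0]
    ntot = len(cells)
    all_fields = {}
    for name, arr in (cell_fields or {}).items():
        buf = np.full(ntot, np.nan)
        buf[:nb] = arr
        all_fields[name] = buf
    for name, arr in (interface_fields or {}).items():
        buf = np.full(ntot, np.nan)
        buf[nb:] = arr
        all_fields[name] = buf
    if all_fields:
        lines.append(f"CELL_DATA {ntot}")
        for name, arr in all_fields.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in arr]

    # point data: displacement vector
    lines.append(f"POINT_DATA {nn}")
    lines.append("VECTORS displacement double")
    uu = np.zeros((nn, 3))
    uu[:, :dim] = u.reshape(-1, dim)
    lines += [" ".join(f"{v:.9g}" for v in p) for p in uu]
    path.write_text("\n".join(lines) + "\n")
    return path


TRAJECTORY_COLUMNS = ["stage", "gamma", "iterations", "residual",
                      "max_initiation", "max_failure", "external_work",
                      "strain_energy", "cohesive_dissipation",
                      "stabilization_energy"]


def trajectory_table(traj) -> pd.DataFrame:
    """Per-step convergence and energy summary of a trajectory."""
    rows = [{c: getattr(r, c) for c in TRAJECTORY_COLUMNS}
            for r in traj.records]
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def export_results(out_dir: str | Path, traj=None, sweep=None,
                   model=None, u=None, surface=None) -> list[Path]:
    """Write the standard outputs of a run into ``out_dir``.

    Trajectory -> trajectory.csv; sweep table -> sweep.csv; final state
    (mesh + damage + mode mix) -> state.vtk.  Identical inputs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if traj is not None:
        p = out / "trajectory.csv"
        trajectory_table(traj).to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    if sweep is not None:
        p = out / "sweep.csv"
        sweep.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    if model is not None and u is not None:
        fields = {}
        if surface is not None:
            ngp = surface.n // model.interface.n
            fields = {
                "damage": surface.d.reshape(-1, ngp).mean(axis=1),
                "mode_mix": np.nan_to_num(
                    surface.mode_mix().reshape(-1, ngp), nan=-1.0).mean(axis=1),
                "G_I": surface.GI.reshape(-1, ngp).mean(axis=1),
                "G_II": surface.GII.reshape(-1, ngp).mean(axis=1),
                "G_III": surface.GIII.reshape(-1, ngp).mean(axis=1),
            }
        p = write_vtk(out / "state.vtk", model.mesh, u,
                      interface=model.interface, interface_fields=fields)
        written.append(p)
    return written
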