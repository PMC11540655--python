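"""Minimal ASCII VTK XML writers for point-cloud results.

States are exported as unstructured grids of vertex cells (.vtu) with nodal
fields as point data, plus a .pvd collection for time series. The files are
plain text and readable by ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_vtu", "write_pvd", "export_domain", "export_procedure"]


def _data_array(name, arr):
    arr = np.asarray(arr)
    ncomp = 1 if arr.ndim == 1 else arr.shape[1]
    flat = arr.reshape(-1)
    body = " ".join(f"{v:.9g}" for v in flat)
    return (f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{body}</DataArray>')


def write_vtu(path, points: np.ndarray, point_data: dict | None = None) -> None:
    """Write a point cloud as a VTK unstructured grid of vertex cells."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    point_data = point_data or {}
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{n}">',
        "<Points>", _data_array("Points", points), "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">'
        + " ".join(str(i) for i in range(n)) + "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">'
        + " ".join(str(i + 1) for i in range(n)) + "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">'
        + " ".join("1" for _ in range(n)) + "</DataArray>",
        "</Cells>",
        "<PointData>",
        *[_data_array(k, v) for k, v in point_data.items()],
        "</PointData>",
        "</Piece>", "</UnstructuredGrid>", "</VTKFile>",
    ]
    Path(path).write_text("\n".join(lines))


def write_pvd(path, entries) -> None:
    """Write a ParaView collection; ``entries`` is a list of (time, filename)."""
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="Collection" version="0.1" byte_order="LittleEndian">',
             "<Collection>"]
    for t, fname in entries:
        lines.append(f'<DataSet timestep="{t}" group="" part="0" file="{fname}"/>')
    lines += ["</Collection>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def export_domain(domain, path) -> None:
    """Write the reference configuration with region labels as point data."""
    write_vtu(path, domain.node_coords,
              {"region": domain.node_region.astype(float)})


def export_procedure(result, outdir, basename: str = "state") -> None:
    """Write a .vtu per snapshot, a .pvd series and a JSON event log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # nodal stiffening scale for inspection: max scale over incident ips is
    # approximated by nearest-ip lookup through the shape table being absent
    # here, so export the per-node region and displacement only.
    entries = []
    log = []
    for k, snap in enumerate(result.snapshots):
        fname = f"{basename}_{k:03d}.vtu"
        write_vtu(outdir / fname, result.domain.node_coords + snap.u,
                  {"displacement": snap.u,
                   "region": result.domain.node_region.astype(float)})
        entries.append((k, fname))
        rec = {"event": snap.label,
               "max_displacement_mm": float(np.linalg.norm(snap.u, axis=1).max())}
        if snap.report is not None:
            rec.update(iterations=snap.report.iterations,
                       converged=bool(snap.report.converged),
                       displacement_increment_mm=snap.report.displacement_increment)
        log.append(rec)
    write_pvd(outdir / f"{basename}.pvd", entries)
    (outdir / "events.json").write_text(json.dumps(log, indent=2))
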