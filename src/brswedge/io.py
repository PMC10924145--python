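"""File I/O: VTU mesh export/import, CSV/JSON trace and feature exports,
HDF5 voltage histories, YAML configs.

The VTU writer emits plain ASCII VTK XML unstructured grids (lines,
triangles or tetrahedra) with optional per-node and per-element data
arrays; the reader supports the same subset for round trips and for
importing externally supplied meshes.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Mesh

_VTK_CELL_TYPES = {1: 3, 2: 5, 3: 10}          # dim -> VTK type id
_VTK_DIM = {3: 1, 5: 2, 10: 3}


def write_vtu(mesh: Mesh, path, point_data=None, cell_data=None):
    """Write a mesh (plus optional data arrays) as ASCII VTU."""
    path = Path(path)
    pts = mesh.points
    if pts.shape[1] < 3:                        # VTK points are 3D
        pts = np.hstack([pts, np.zeros((len(pts), 3 - pts.shape[1]))])
    ncell, nn = len(mesh.cells), mesh.n_nodes
    vtk_type = _VTK_CELL_TYPES[mesh.dim]

    def arr(a, per_line=6):
        flat = np.asarray(a).ravel()
        return "\n".join(" ".join(f"{v:.10g}" for v in flat[i:i + per_line])
                         for i in range(0, len(flat), per_line))

    def data_arrays(data, n_expected):
        out = []
        for name, a in (data or {}).items():
            a = np.asarray(a)
            ncomp = 1 if a.ndim == 1 else a.shape[1]
            if len(a) != n_expected:
                raise ValueError(f"data array {name!r} has wrong length")
            dtype = "Int64" if np.issubdtype(a.dtype, np.integer) \
                else "Float64"
            out.append(
                f'<DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
                f"{arr(a)}\n</DataArray>")
        return "\n".join(out)

    offs = np.arange(1, ncell + 1) * (mesh.dim + 1)
    xml_text = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{nn}" NumberOfCells="{ncell}">
<PointData>
{data_arrays(point_data, nn)}
</PointData>
<CellData>
{data_arrays(cell_data, ncell)}
</CellData>
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">
{arr(pts)}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{arr(mesh.cells)}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{arr(offs)}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{arr(np.full(ncell, vtk_type))}
</DataArray>
</Cells>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml_text)


def read_vtu(path):
    """Read an ASCII VTU written by :func:`write_vtu` (or compatible).

    Returns (Mesh, point_data dict, cell_data dict).
    """
    root = ET.parse(Path(path)).getroot()
    piece = root.find(".//Piece")

    def parse_array(el):
        text = (el.text or "").split()
        if el.get("type") in ("Int64", "Int32", "UInt8"):
            a = np.array([int(v) for v in text], dtype=np.int64)
        else:
            a = np.array([float(v) for v in text])
        ncomp = int(el.get("NumberOfComponents", "1"))
        return a.reshape(-1, ncomp) if ncomp > 1 else a

    pts = parse_array(piece.find("Points/DataArray"))
    cells_el = {el.get("Name"): el for el in piece.findall("Cells/DataArray")}
    conn = parse_array(cells_el["connectivity"])
    types = parse_array(cells_el["types"])
    vtk_type = int(types[0])
    if not np.all(types == vtk_type):
        raise ValueError("mixed element types are not supported")
    dim = _VTK_DIM[vtk_type]
    cells = conn.reshape(-1, dim + 1)
    # drop zero-padded coordinate columns
    keep = [k for k in range(pts.shape[1])
            if k < dim or np.any(pts[:, k] != 0.0)]
    pts = pts[:, :max(dim, len(keep))][:, :dim] if dim < 3 else pts[:, :3]
    pdata = {el.get("Name"): parse_array(el)
             for el in piece.findall("PointData/DataArray")}
    cdata = {el.get("Name"): parse_array(el)
             for el in piece.findall("CellData/DataArray")}
    mesh = Mesh(points=pts, cells=cells,
                depth=pdata.get("depth"), apexbase=pdata.get("apexbase"))
    return mesh, pdata, cdata


def trace_to_csv(trace, path):
    """AP trace -> CSV (time_ms, V_mV)."""
    pd.DataFrame({"time_ms": trace.time, "V_mV": trace.v}).to_csv(
        Path(path), index=False)


def ecg_to_csv(ecg, path):
    """ECG trace -> CSV (time_ms + one column per lead)."""
    df = pd.DataFrame(ecg.data, columns=ecg.labels)
    df.insert(0, "time_ms", ecg.time)
    df.to_csv(Path(path), index=False)


def features_to_json(features, path):
    out = {"qrs_onset_ms": features.qrs_onset,
           "qrs_end_ms": features.qrs_end,
           "leads": {lab: asdict(lf)
                     for lab, lf in features.per_lead.items()},
           "meta": features.meta}
    Path(path).write_text(json.dumps(out, indent=2, default=float))


def save_history(history, path):
    """VmHistory -> HDF5 (vm, times, JSON-encoded metadata)."""
    import h5py
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("times", data=history.times)
        f.create_dataset("vm", data=history.vm)
        meta = {k: v for k, v in history.meta.items()
                if k != "final_states"}
        f.attrs["meta"] = json.dumps(meta, default=str)


def load_history(path):
    import h5py
    from .fem import VmHistory
    with h5py.File(Path(path), "r") as f:
        times = f["times"][...]
        vm = f["vm"][...]
        meta = json.loads(f.attrs["meta"])
    return VmHistory(times, vm, meta)


def history_to_vtu_frames(mesh, history, out_dir, every=10):
    """Write a VmHistory as a VTU frame series (one file per sample)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(0, len(history.times), every):
        p = out_dir / f"vm_{int(round(history.times[k])):05d}ms.vtu"
        write_vtu(mesh, p, point_data={"Vm_mV": history.vm[k]})
        paths.append(p)
    return paths


def electrodes_to_json(torso, path):
    reg = {name: {"node": int(nid),
                  "position": [float(x)
                               for x in torso.mesh.points[nid]]}
           for name, nid in torso.electrodes.items()}
    Path(path).write_text(json.dumps(reg, indent=2))


def config_to_yaml(config, path):
    """Dataclass config -> YAML."""
    if not is_dataclass(config):
        raise TypeError("expected a dataclass config")
    Path(path).write_text(yaml.safe_dump(asdict(config)))


def yaml_to_dict(path):
    return yaml.safe_load(Path(path).read_text())
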