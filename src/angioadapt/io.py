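"""Readers and writers: network exchange tables, VTK exports, config files.

The exchange format is two delimited UTF-8 text tables with an explicit
units header line — nodes (id, x, y, kind, bc_type, bc_value, bc_hematocrit,
bc_po2) and segments (id, node_from, node_to, diameter, type, flowing,
fixed_diameter). Writers are deterministic; readers validate referential
integrity and report offending rows.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .network import Network, StructuralError
from .params import SimulationConfig
from .tissue import TissueDomain

NODE_UNITS = "# units: x=um, y=um, bc_value=mmHg|nl/min, bc_hematocrit=1, bc_po2=mmHg"
SEGMENT_UNITS = "# units: diameter=um"


class FormatError(Exception):
    pass


def write_network(net: Network, prefix: str) -> Tuple[str, str]:
    """Write `<prefix>_nodes.csv` and `<prefix>_segments.csv`."""
    nodes_path = f"{prefix}_nodes.csv"
    segs_path = f"{prefix}_segments.csv"
    nrows = []
    for nid in sorted(net.nodes):
        n = net.nodes[nid]
        nrows.append(
            {
                "id": nid,
                "x": n.x,
                "y": n.y,
                "kind": n.kind,
                "bc_type": n.bc_type or "",
                "bc_value": "" if n.bc_value is None else n.bc_value,
                "bc_hematocrit": "" if n.bc_hematocrit is None else n.bc_hematocrit,
                "bc_po2": "" if n.bc_po2 is None else n.bc_po2,
            }
        )
    srows = []
    for sid in sorted(net.segments):
        s = net.segments[sid]
        srows.append(
            {
                "id": sid,
                "node_from": s.n_from,
                "node_to": s.n_to,
                "diameter": s.diameter,
                "type": s.type,
                "flowing": int(s.flowing),
                "fixed_diameter": int(s.fixed_diameter),
            }
        )
    with open(nodes_path, "w") as f:
        f.write(NODE_UNITS + "\n")
        pd.DataFrame(nrows).to_csv(f, index=False, float_format="%.17g")
    with open(segs_path, "w") as f:
        f.write(SEGMENT_UNITS + "\n")
        pd.DataFrame(srows).to_csv(f, index=False, float_format="%.17g")
    return nodes_path, segs_path


def read_network(prefix: str) -> Network:
    """Read a network written by `write_network`; strict validation."""
    nodes_path = f"{prefix}_nodes.csv"
    segs_path = f"{prefix}_segments.csv"
    for path in (nodes_path, segs_path):
        with open(path) as f:
            first = f.readline()
        if not first.startswith("# units:"):
            raise FormatError(f"{path}: missing units header line")
    nodes = pd.read_csv(nodes_path, comment="#", float_precision="round_trip")
    segs = pd.read_csv(segs_path, comment="#", float_precision="round_trip")

    net = Network()
    id_map: Dict[int, int] = {}
    for row_no, row in nodes.iterrows():
        def opt(v):
            return None if pd.isna(v) or v == "" else float(v)

        nid = net.add_node(
            float(row["x"]),
            float(row["y"]),
            kind=str(row["kind"]),
            bc_type=None if pd.isna(row["bc_type"]) or row["bc_type"] == "" else str(row["bc_type"]),
            bc_value=opt(row["bc_value"]),
            bc_hematocrit=opt(row["bc_hematocrit"]),
            bc_po2=opt(row["bc_po2"]),
        )
        id_map[int(row["id"])] = nid
    for row_no, row in segs.iterrows():
        a, b = int(row["node_from"]), int(row["node_to"])
        if a not in id_map or b not in id_map:
            raise FormatError(f"{segs_path}: row {row_no}: dangling endpoint {a if a not in id_map else b}")
        net.add_segment(
            id_map[a],
            id_map[b],
            float(row["diameter"]),
            type=str(row["type"]),
            flowing=bool(int(row["flowing"])),
            fixed_diameter=bool(int(row["fixed_diameter"])),
        )
    try:
        net.validate()
    except StructuralError as exc:
        raise FormatError(f"invalid network in {prefix}: {exc}") from exc
    return net


# --------------------------------------------------------------------- VTK
def write_vtk_polylines(
    net: Network,
    path: str,
    segment_scalars: Optional[Dict[str, Dict[int, float]]] = None,
) -> str:
    """Legacy-VTK polydata: one line cell per segment, scalars per cell."""
    nids = sorted(net.nodes)
    index = {n: k for k, n in enumerate(nids)}
    sids = sorted(net.segments)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmicrovascular network\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(nids)} float\n")
        for n in nids:
            node = net.nodes[n]
            f.write(f"{node.x:.3f} {node.y:.3f} 0.0\n")
        f.write(f"LINES {len(sids)} {3 * len(sids)}\n")
        for s in sids:
            seg = net.segments[s]
            f.write(f"2 {index[seg.n_from]} {index[seg.n_to]}\n")
        scalars = {"diameter": {s: net.segments[s].diameter for s in sids}}
        if segment_scalars:
            scalars.update(segment_scalars)
        if sids:
            f.write(f"CELL_DATA {len(sids)}\n")
            for name, values in scalars.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for s in sids:
                    f.write(f"{values.get(s, 0.0):.4f}\n")
    return path


def write_vtk_grid(domain: TissueDomain, fields: Dict[str, np.ndarray], path: str) -> str:
    """Legacy-VTK structured points for tissue-grid fields (NaN off-domain)."""
    nx, ny = domain.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ntissue grid\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} 1\n")
        f.write(f"ORIGIN {domain.origin[0]:.3f} {domain.origin[1]:.3f} 0.0\n")
        f.write(f"SPACING {domain.spacing} {domain.spacing} 1.0\n")
        f.write(f"POINT_DATA {nx * ny}\n")
        for name, values in fields.items():
            if len(values) != domain.n_points:
                raise FormatError(f"field {name}: length does not match the tissue grid")
            grid = np.full((nx, ny), np.nan)
            for k, (i, j) in enumerate(domain.index):
                grid[i, j] = values[k]
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for j in range(ny):
                for i in range(nx):
                    v = grid[i, j]
                    f.write("nan\n" if np.isnan(v) else f"{v:.4f}\n")
    return path


# ------------------------------------------------------------------- config
def save_config(config: SimulationConfig, path: str) -> str:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
    return path


def load_config(path: str) -> SimulationConfig:
    with open(path) as f:
        data = yaml.safe_load(f)
    return SimulationConfig.from_dict(data)
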