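"""VTK unstructured-grid (.vtu) output, CSV metrics tables, and run logs.

Files are XML VTU with ASCII data arrays printed at 17 significant digits,
so a reader round-trip recovers coordinates bitwise.  Hexahedra use VTK cell
type 12; cell data carry ``strip_id`` and ``calcified`` flags, point data
the displacement field ``u``.  A matching minimal reader is provided for
round-trip checks and for the ``metrics`` CLI subcommand.
"""

from __future__ import annotations

import csv
import json
import time
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

__all__ = ["write_vtu", "read_vtu", "SimulationWriter", "write_vtu_series"]

_VTK_HEX = 12


def _fmt(arr: np.ndarray) -> str:
    return " ".join(f"{v:.17g}" for v in np.asarray(arr).ravel())


def write_vtu(
    path,
    points: np.ndarray,
    cells: np.ndarray,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write hexahedral cells to an XML VTU file (ASCII arrays)."""
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    n_pts, n_cells = len(points), len(cells)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "          " + _fmt(points),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + " ".join(map(str, cells.ravel())),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + " ".join(str(8 * (i + 1)) for i in range(n_cells)),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        "          " + " ".join([str(_VTK_HEX)] * n_cells),
        "        </DataArray>",
        "      </Cells>",
    ]
    if point_data:
        lines.append("      <PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            lines += [
                f'        <DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">',
                "          " + _fmt(arr),
                "        </DataArray>",
            ]
        lines.append("      </PointData>")
    if cell_data:
        lines.append("      <CellData>")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            lines += [
                f'        <DataArray type="Float64" Name="{name}" '
                'NumberOfComponents="1" format="ascii">',
                "          " + _fmt(arr.astype(float)),
                "        </DataArray>",
            ]
        lines.append("      </CellData>")
    lines += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(lines))


def read_vtu(path):
    """Minimal VTU reader: returns (points, cells, point_data, cell_data)."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    n_pts = int(piece.get("NumberOfPoints"))
    n_cells = int(piece.get("NumberOfCells"))

    def parse(el, dtype=float):
        return np.fromstring(el.text, sep=" ", dtype=dtype)

    pts = parse(piece.find("Points/DataArray")).reshape(n_pts, 3)
    conn = None
    for da in piece.findall("Cells/DataArray"):
        if da.get("Name") == "connectivity":
            conn = parse(da).astype(np.int64).reshape(n_cells, 8)
    point_data, cell_data = {}, {}
    for section, store, n in (
        ("PointData", point_data, n_pts),
        ("CellData", cell_data, n_cells),
    ):
        sec = piece.find(section)
        if sec is None:
            continue
        for da in sec.findall("DataArray"):
            arr = parse(da)
            ncomp = int(da.get("NumberOfComponents", "1"))
            store[da.get("Name")] = arr.reshape(n, ncomp) if ncomp > 1 else arr
    return pts, conn, point_data, cell_data


METRICS_SCHEMA_VERSION = 1
METRICS_COLUMNS = [
    "increment", "n", "n_all", "amplitude_max", "up_down_ratio",
    "median_K_at_crests", "fraction_K_negative", "mean_us1_at_crests",
    "crest_sign_agreement", "self_intersection",
]


def metrics_rows(state) -> list[dict]:
    rows = []
    for k, m in enumerate(state.metrics_history):
        g = m.gaussian_curvature_stats
        rows.append(
            {
                "increment": k,
                "n": m.n,
                "n_all": m.n_all,
                "amplitude_max": f"{m.amplitude_max:.17g}",
                "up_down_ratio": f"{m.up_down_ratio:.17g}",
                "median_K_at_crests": f"{g.get('median_at_crests', float('nan')):.17g}",
                "fraction_K_negative": f"{g.get('fraction_negative', float('nan')):.17g}",
                "mean_us1_at_crests": f"{g.get('mean_us1_at_crests', float('nan')):.17g}",
                "crest_sign_agreement": f"{g.get('crest_sign_agreement', float('nan')):.17g}",
                "self_intersection": int(m.self_intersection),
            }
        )
    return rows


class SimulationWriter:
    """Writes the per-increment VTU series, metrics.csv, and run.log."""

    def __init__(self, out_dir):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)

    def write_increment(self, state) -> None:
        k = state.increment_index - 1
        mesh = state.mesh
        cell_data = {
            "strip_id": mesh.strip_id.astype(float),
            "deposition_time": np.array(
                [mesh.deposition_time[s] for s in mesh.strip_id], dtype=float
            ),
            "calcified": np.array(
                [float(state.strip_registry[s].calcified) for s in mesh.strip_id]
            ),
        }
        write_vtu(
            self.out_dir / f"inc_{k:04d}_ref.vtu",
            mesh.node_coords, mesh.hex_connectivity,
            point_data={"u": state.u}, cell_data=cell_data,
        )
        write_vtu(
            self.out_dir / f"inc_{k:04d}_def.vtu",
            state.deformed_coords(), mesh.hex_connectivity,
            point_data={"u": state.u}, cell_data=cell_data,
        )

    def write_metrics_csv(self, state) -> None:
        rows = metrics_rows(state)
        with open(self.out_dir / "metrics.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=METRICS_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)

    def write_failure(self, state) -> None:
        with open(self.out_dir / "failure.json", "w") as f:
            json.dump(state.failure, f, indent=2)

    def write_log(self, config_text: str) -> None:
        import hashlib

        digest = hashlib.sha256(config_text.encode()).hexdigest()[:16]
        with open(self.out_dir / "run.log", "a") as f:
            f.write(f"# run at {time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
            f.write(f"# config sha256/16 {digest}\n")
            f.write(config_text.rstrip() + "\n")


def write_vtu_series(states, out_dir) -> list:
    """Write ref/def VTU pairs for a history of states; returns file paths."""
    states = list(states)
    if not states:
        raise ValueError("empty state history")
    w = SimulationWriter(out_dir)
    paths = []
    for st in states:
        w.write_increment(st)
        k = st.increment_index - 1
        paths += [w.out_dir / f"inc_{k:04d}_ref.vtu", w.out_dir / f"inc_{k:04d}_def.vtu"]
    return paths
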