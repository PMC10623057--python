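"""Output writers: legacy-ASCII VTK, CSV tables, JSON summaries, manifests.

All writers are deterministic (fixed float formatting, no timestamps), so
running the same study twice produces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .elasticity import PlaneStressSolution
from .fracture import ERRResult
from .meshing import CrackMesh

__all__ = ["export_vtk", "read_vtk_points", "err_to_csv", "write_manifest",
           "write_json"]

_FMT = "%.12e"


def export_vtk(mesh: CrackMesh, sol: PlaneStressSolution | None, path) -> Path:
    """Write the mesh (and optionally displacement + von Mises stress) as a
    legacy-ASCII VTK unstructured grid."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "ocufrac plane-stress crack model",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{_FMT % x} {_FMT % y} 0.000000000000e+00")
    n_cells = mesh.n_elements
    size = 4 * len(mesh.tris) + 5 * len(mesh.quads)
    lines.append(f"CELLS {n_cells} {size}")
    for tri in mesh.tris:
        lines.append("3 " + " ".join(str(int(i)) for i in tri))
    for quad in mesh.quads:
        lines.append("4 " + " ".join(str(int(i)) for i in quad))
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend(["5"] * len(mesh.tris))  # VTK_TRIANGLE
    lines.extend(["9"] * len(mesh.quads))  # VTK_QUAD
    # ring / seam tags
    ring_tag = np.zeros(n_cells, dtype=int)
    for side_idx, side in enumerate(("left", "right")):
        for k, ring in enumerate(mesh.tip_rings.get(side, [])):
            ring_tag[ring] = 100 * (side_idx + 1) + (k + 1)
    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS ring_tag int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(t)) for t in ring_tag)
    if sol is not None:
        vm = sol.von_mises()
        lines.append("SCALARS von_mises double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(_FMT % v for v in vm)
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement double")
        for ux, uy in sol.u:
            lines.append(f"{_FMT % ux} {_FMT % uy} 0.000000000000e+00")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_points(path) -> np.ndarray:
    """Minimal legacy-VTK reader for round-trip checks: node coordinates."""
    toks = Path(path).read_text().split("\n")
    for i, line in enumerate(toks):
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            pts = []
            j = i + 1
            while len(pts) < n:
                vals = toks[j].split()
                pts.append([float(vals[0]), float(vals[1])])
                j += 1
            return np.array(pts)
    raise ValueError(f"no POINTS section in {path}")


def err_to_csv(result: ERRResult, path) -> Path:
    """One row per contour ring, plus the averaged G and its scatter."""
    path = Path(path)
    lines = ["ring,G_J_per_m2"]
    for k, g in enumerate(result.per_ring_G, start=1):
        lines.append(f"{k},{_FMT % g}")
    lines.append(f"mean_4_10,{_FMT % result.G}")
    lines.append(f"scatter,{_FMT % result.scatter}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def write_manifest(config_path, outdir, diagnostics: dict) -> Path:
    """Reproducibility manifest: package version, config hash, diagnostics."""
    config_path = Path(config_path)
    digest = hashlib.sha256(config_path.read_bytes()).hexdigest()
    return write_json(
        {
            "package": "ocufrac",
            "version": __version__,
            "config": config_path.name,
            "config_sha256": digest,
            "diagnostics": diagnostics,
        },
        Path(outdir) / "manifest.json",
    )
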