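"""Mesh export of the osteotomized column for printing workflows.

Builds watertight triangle meshes (binary STL, mm units) of the distal
fragment and of the proximal fragment after the wedge-opening rotation.
Both fragments are convex polyhedra — the column cut by the sloped top
plane and the osteotomy plane — so their vertices are computed exactly
and meshed as convex hulls.  With zero correction the two fragments
tile the intact sloped column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from .geometry import ColumnModel, OsteotomyPlan, transform_point

__all__ = ["column_mesh", "fragment_meshes", "export_fragments"]


def _hull(vertices: np.ndarray) -> trimesh.Trimesh:
    mesh = trimesh.convex.convex_hull(np.asarray(vertices, float))
    if not mesh.is_watertight:
        raise ValueError("constructed fragment mesh is not watertight")
    return mesh


def _cut_corners(column: ColumnModel, plan: OsteotomyPlan) -> np.ndarray:
    """The 4 corners of the osteotomy plane on the column's side faces."""
    w, d = column.width_ml, column.depth_ap
    for y in (0.0, d):
        if not 0.0 < plan.plane_z(y) < column.top_z(y):
            raise ValueError(
                "osteotomy plane leaves the column between bottom and top surfaces"
            )
    return np.array([[x, y, plan.plane_z(y)] for x in (0.0, w) for y in (0.0, d)])


def column_mesh(column: ColumnModel) -> trimesh.Trimesh:
    """Watertight mesh of the intact sloped column."""
    bottom = [[x, y, 0.0] for x in (0.0, column.width_ml) for y in (0.0, column.depth_ap)]
    return _hull(np.vstack([bottom, column.top_corners()]))


def fragment_meshes(
    column: ColumnModel, plan: OsteotomyPlan
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """(distal, proximal) fragment meshes; the proximal one is rotated.

    The osteotomy plane passes through the hinge line on the lateral
    face; the proximal fragment rotates about that line by the
    correction angle with the sign that opens the gap medially.
    """
    w, d = column.width_ml, column.depth_ap
    cut = _cut_corners(column, plan)
    bottom = np.array([[x, y, 0.0] for x in (0.0, w) for y in (0.0, d)])
    distal = _hull(np.vstack([bottom, cut]))
    proximal_verts = np.vstack([cut, column.top_corners()])
    if plan.correction != 0.0:
        h = plan.hinge_point()
        proximal_verts = np.array([transform_point(p, plan, h) for p in proximal_verts])
    return distal, _hull(proximal_verts)


def export_fragments(column: ColumnModel, plan: OsteotomyPlan, out_dir) -> tuple[Path, Path]:
    """Write ``distal.stl`` and ``proximal.stl`` (binary, mm) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    distal, proximal = fragment_meshes(column, plan)
    paths = (out_dir / "distal.stl", out_dir / "proximal.stl")
    for mesh, path in zip((distal, proximal), paths):
        mesh.export(path, file_type="stl")
    return paths
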