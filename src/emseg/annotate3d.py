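"""Headless 3-D annotation: per-object surface meshes, object tables, CSV export.

Meshes are extracted by marching cubes at iso-level 0.5 on the binary mask of
one object, after padding the volume with one background voxel so that
objects touching the border still yield a closed (watertight) surface.
Vertex coordinates are physical, in nanometres, ordered (x, y, z); marker
points live in the same space so they can be placed on the object surface.

Tables export as plain CSV — ``objects.csv`` (id,name,r,g,b,voxel_count) and
``markers.csv`` (object_id,x_nm,y_nm,z_nm,note) — and meshes as OBJ and STL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from skimage import measure

from .core import LabelVolume
from .ffn import _palette


class ObjectNotFoundError(KeyError):
    pass


@dataclass
class MeshObject:
    object_id: int
    vertices: np.ndarray  # (n, 3) float, (x, y, z) nm
    faces: np.ndarray  # (m, 3) int

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @property
    def volume_nm3(self) -> float:
        """Enclosed volume from the signed-tetrahedron sum over faces."""
        return float(abs(self.to_trimesh().volume))

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


def marching_cubes_mesh(
    labels: LabelVolume,
    object_id: int,
    spacing: tuple[float, float, float] | None = None,
) -> MeshObject:
    """Iso-surface of one object at level 0.5, vertex coordinates in nm."""
    spacing = labels.spacing if spacing is None else spacing
    mask = labels.labels == object_id
    if object_id == 0 or not mask.any():
        raise ObjectNotFoundError(f"object id {object_id} not present")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    verts -= np.asarray(spacing)  # undo the 1-voxel pad offset
    verts = verts[:, ::-1]  # (z, y, x) nm → (x, y, z) nm
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces())
    return MeshObject(int(object_id), np.asarray(mesh.vertices), np.asarray(mesh.faces))


@dataclass
class AnnotationRow:
    name: str
    color: tuple[int, int, int]
    voxel_count: int
    markers: list = field(default_factory=list)  # (x_nm, y_nm, z_nm, note)


@dataclass
class AnnotationTable:
    rows: dict[int, AnnotationRow] = field(default_factory=dict)

    def add_marker(self, object_id: int, xyz_nm, note: str = "") -> None:
        if object_id not in self.rows:
            raise ObjectNotFoundError(f"object id {object_id} not in table")
        x, y, z = (float(v) for v in xyz_nm)
        self.rows[object_id].markers.append((x, y, z, note))


def build_annotation_table(labels: LabelVolume) -> AnnotationTable:
    """One row per nonzero id with a default name and a deterministic color."""
    ids = labels.ids()
    counts = np.bincount(labels.labels.ravel())
    palette = _palette(len(ids))
    table = AnnotationTable()
    for k, oid in enumerate(ids, start=1):
        table.rows[int(oid)] = AnnotationRow(
            name=f"obj_{oid}",
            color=tuple(int(c) for c in palette[k]),
            voxel_count=int(counts[oid]),
        )
    return table


def export_annotations(
    table: AnnotationTable, meshes: list[MeshObject], out_dir
) -> list[str]:
    """Write objects.csv, markers.csv and one OBJ + STL file per mesh.

    Returns the manifest of written file names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []

    obj_rows = [
        {
            "id": oid,
            "name": row.name,
            "r": row.color[0],
            "g": row.color[1],
            "b": row.color[2],
            "voxel_count": row.voxel_count,
        }
        for oid, row in sorted(table.rows.items())
    ]
    pd.DataFrame(obj_rows, columns=["id", "name", "r", "g", "b", "voxel_count"]).to_csv(
        out / "objects.csv", index=False
    )
    manifest.append("objects.csv")

    marker_rows = [
        {"object_id": oid, "x_nm": x, "y_nm": y, "z_nm": z, "note": note}
        for oid, row in sorted(table.rows.items())
        for (x, y, z, note) in row.markers
    ]
    pd.DataFrame(
        marker_rows, columns=["object_id", "x_nm", "y_nm", "z_nm", "note"]
    ).to_csv(out / "markers.csv", index=False)
    manifest.append("markers.csv")

    for mesh in meshes:
        tm = mesh.to_trimesh()
        for ext in ("obj", "stl"):
            name = f"mesh_{mesh.object_id:04d}.{ext}"
            tm.export(out / name)
            manifest.append(name)
    return manifest


def load_annotations(in_dir) -> AnnotationTable:
    """Re-read objects.csv/markers.csv written by :func:`export_annotations`."""
    in_dir = Path(in_dir)
    table = AnnotationTable()
    objs = pd.read_csv(in_dir / "objects.csv")
    for rec in objs.itertuples():
        table.rows[int(rec.id)] = AnnotationRow(
            name=str(rec.name),
            color=(int(rec.r), int(rec.g), int(rec.b)),
            voxel_count=int(rec.voxel_count),
        )
    markers = pd.read_csv(in_dir / "markers.csv")
    for rec in markers.itertuples():
        note = "" if pd.isna(rec.note) else str(rec.note)
        table.add_marker(int(rec.object_id), (rec.x_nm, rec.y_nm, rec.z_nm), note)
    return table
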