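"""Tabular and mesh I/O.

CSV schemas
-----------
annotations : nucleus_id, view, x_um, y_um, z_um
fits        : nucleus_id, cx, cy, cz, e1x..e3z, L1, L2, L3, aspect_ratio, flags
plates      : cell_id, frame, cx, cy, cz, e1x..e3z, L1, L2, L3[, anaphase_frame]
events      : cell_id, condensation_frame, metaphase_frame, anaphase_frame,
              condensation_censored[, last_observed_frame][, frame_interval_min]
records     : one OrientationRecord per row
Meshes are ASCII PLY (via trimesh).  All coordinates in µm.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .division import PlateTrack
from .ellipsoid import AnnotationSet, Ellipsoid, is_elongated, orientation_reliable
from .errors import SpheroidGeomError
from .geometry import TriangleMesh
from .orientation import OrientationRecord
from .timing import DEFAULT_FRAME_INTERVAL_MIN, MitosisEvent

__all__ = [
    "read_annotations",
    "write_annotations",
    "write_fits",
    "read_fits",
    "read_plate_tracks",
    "write_plate_tracks",
    "read_events",
    "write_events",
    "write_records",
    "read_records",
    "write_mesh_ply",
    "read_mesh_ply",
    "write_json",
]

_AXIS_COLS = [f"e{i}{c}" for i in (1, 2, 3) for c in "xyz"]


def read_annotations(path) -> list[AnnotationSet]:
    df = pd.read_csv(path)
    required = {"nucleus_id", "view", "x_um", "y_um", "z_um"}
    if not required.issubset(df.columns):
        raise SpheroidGeomError(f"annotation CSV needs columns {sorted(required)}")
    out = []
    for nid, grp in df.groupby("nucleus_id", sort=False):
        out.append(
            AnnotationSet(
                nucleus_id=str(nid),
                points=grp[["x_um", "y_um", "z_um"]].to_numpy(float),
                views=[str(v) for v in grp["view"]],
            )
        )
    return out


def write_annotations(path, annotations: Iterable[AnnotationSet]) -> None:
    rows = []
    for ann in annotations:
        for p, v in zip(ann.points, ann.views):
            rows.append(
                {
                    "nucleus_id": ann.nucleus_id,
                    "view": v,
                    "x_um": p[0],
                    "y_um": p[1],
                    "z_um": p[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _ellipsoid_row(e: Ellipsoid) -> dict:
    row = {"cx": e.center[0], "cy": e.center[1], "cz": e.center[2]}
    row.update(dict(zip(_AXIS_COLS, e.axes.ravel())))
    row.update({"L1": e.lengths[0], "L2": e.lengths[1], "L3": e.lengths[2]})
    return row


def _row_ellipsoid(row) -> Ellipsoid:
    return Ellipsoid(
        center=np.array([row["cx"], row["cy"], row["cz"]], dtype=float),
        axes=np.array([row[c] for c in _AXIS_COLS], dtype=float).reshape(3, 3),
        lengths=np.array([row["L1"], row["L2"], row["L3"]], dtype=float),
    )


def write_fits(path, fits: Sequence[tuple[str, Ellipsoid]]) -> None:
    """Write fitted ellipsoids with derived aspect ratio and flags."""
    rows = []
    for nid, e in fits:
        row = {"nucleus_id": nid}
        row.update(_ellipsoid_row(e))
        row["aspect_ratio"] = e.aspect_ratio
        flags = []
        if not orientation_reliable(e):
            flags.append("orientation-unreliable")
        if is_elongated(e):
            flags.append("elongated")
        row["flags"] = ";".join(flags)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fits(path) -> list[tuple[str, Ellipsoid]]:
    df = pd.read_csv(path)
    return [(str(r["nucleus_id"]), _row_ellipsoid(r)) for _, r in df.iterrows()]


def write_plate_tracks(path, tracks: Iterable[PlateTrack]) -> None:
    rows = []
    for t in tracks:
        for frame, plate in zip(t.frames, t.plates):
            row = {"cell_id": t.cell_id, "frame": frame}
            row.update(_ellipsoid_row(plate))
            row["anaphase_frame"] = (
                t.anaphase_frame if t.anaphase_frame is not None else ""
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_tracks(path) -> list[PlateTrack]:
    df = pd.read_csv(path)
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        ana = None
        if "anaphase_frame" in grp.columns:
            vals = grp["anaphase_frame"].dropna()
            if len(vals):
                ana = int(vals.iloc[0])
        tracks.append(
            PlateTrack(
                cell_id=str(cid),
                frames=[int(f) for f in grp["frame"]],
                plates=[_row_ellipsoid(r) for _, r in grp.iterrows()],
                anaphase_frame=ana,
            )
        )
    return tracks


def write_events(path, events: Iterable[MitosisEvent]) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "cell_id": e.cell_id,
                "condensation_frame": e.condensation_frame,
                "metaphase_frame": e.metaphase_frame,
                "anaphase_frame": e.anaphase_frame,
                "condensation_censored": e.condensation_censored,
                "last_observed_frame": e.last_observed_frame,
                "frame_interval_min": e.frame_interval_min,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _opt_int(v) -> int | None:
    return None if pd.isna(v) else int(v)


def read_events(path) -> list[MitosisEvent]:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        events.append(
            MitosisEvent(
                cell_id=str(r["cell_id"]),
                condensation_frame=_opt_int(r.get("condensation_frame")),
                metaphase_frame=_opt_int(r.get("metaphase_frame")),
                anaphase_frame=_opt_int(r.get("anaphase_frame")),
                condensation_censored=bool(r.get("condensation_censored", False)),
                last_observed_frame=_opt_int(r.get("last_observed_frame")),
                frame_interval_min=float(
                    r.get("frame_interval_min", DEFAULT_FRAME_INTERVAL_MIN)
                ),
            )
        )
    return events


def write_records(path, records: Iterable[OrientationRecord]) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def read_records(path) -> list[OrientationRecord]:
    df = pd.read_csv(path)
    return [
        OrientationRecord(
            nucleus_id=str(r["nucleus_id"]),
            aspect_ratio=float(r["aspect_ratio"]),
            depth_um=float(r["depth_um"]),
            angle_deg=float(r["angle_deg"]),
            elongated=bool(r["elongated"]),
            orientation_reliable=bool(r["orientation_reliable"]),
        )
        for _, r in df.iterrows()
    ]


def write_mesh_ply(path, mesh: TriangleMesh) -> None:
    """Export a mesh as ASCII PLY."""
    import trimesh

    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, process=False
    )
    tm.export(path, file_type="ply", encoding="ascii")


def read_mesh_ply(path) -> TriangleMesh:
    """Load an ASCII/binary PLY as a :class:`TriangleMesh`.

    Face normals are recomputed and oriented outward from the centroid
    (meshes written by this package are convex hulls).
    """
    import trimesh

    tm = trimesh.load(path, file_type="ply", process=False)
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.intp)
    tri = vertices[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    centroid = vertices.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, tri[:, 0] - centroid[None, :]) < 0
    normals[flip] *= -1.0
    return TriangleMesh(vertices=vertices, faces=faces, face_normals=normals)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
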