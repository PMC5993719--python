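"""Cell-division-axis orientation from metaphase-plate ellipsoids.

The metaphase plate — the disc of aligned condensed chromosomes — is
segmented as an ellipsoid flattened along one axis; the plate's shortest
axis (the disc normal) is the division axis.  The last plate observed
strictly before anaphase onset is the reference, and its shortest axis is
compared with the outward normal of the spheroid hull at the closest
surface point: 90 deg means the division axis is parallel to the surface
(plate perpendicular to it), 0 deg means the cell divides radially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ellipsoid import Ellipsoid
from .errors import EmptyInputError, SpheroidGeomError
from .geometry import TriangleMesh, angle_to_normal, closest_surface_point

__all__ = [
    "PlateTrack",
    "ReferencePlate",
    "DivisionRecord",
    "select_reference_plate",
    "division_angle",
    "analyze_track",
]

#: Minimum L2/L3 for a plate to count as flattened: below this the shortest
#: axis (hence the division axis) is ill-defined.
MIN_PLATE_FLATNESS = 1.1

FLAG_ANAPHASE_UNCENSORED = "anaphase-uncensored"


@dataclass
class PlateTrack:
    """Time-ordered metaphase-plate fits of one dividing cell."""

    cell_id: str
    frames: list[int]
    plates: list[Ellipsoid]
    anaphase_frame: int | None = None

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.plates):
            raise SpheroidGeomError("one plate per frame required")
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise SpheroidGeomError("plate frames must be strictly increasing")


@dataclass(frozen=True)
class ReferencePlate:
    """The plate used for the division-axis measurement, with provenance."""

    plate: Ellipsoid
    frame: int
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class DivisionRecord:
    """Division-axis orientation of one mitotic cell."""

    cell_id: str
    angle_deg: float
    depth_um: float
    reference_frame: int
    flags: frozenset[str]


def select_reference_plate(track: PlateTrack) -> ReferencePlate:
    """Last metaphase plate detected strictly before anaphase onset.

    If no anaphase frame was recorded (the movie ended first) the last
    observed plate is used and the result carries the
    ``anaphase-uncensored`` flag.
    """
    if not track.plates:
        raise EmptyInputError(f"track {track.cell_id!r} has no plates")
    if track.anaphase_frame is None:
        return ReferencePlate(
            plate=track.plates[-1],
            frame=track.frames[-1],
            flags=frozenset({FLAG_ANAPHASE_UNCENSORED}),
        )
    candidates = [i for i, f in enumerate(track.frames) if f < track.anaphase_frame]
    if not candidates:
        raise SpheroidGeomError(
            f"track {track.cell_id!r}: no plate strictly before anaphase "
            f"frame {track.anaphase_frame}"
        )
    i = candidates[-1]
    return ReferencePlate(plate=track.plates[i], frame=track.frames[i])


def division_angle(
    plate: Ellipsoid,
    mesh: TriangleMesh,
    min_flatness: float = MIN_PLATE_FLATNESS,
) -> float:
    """Angle (deg, [0, 90]) of the division axis to the local surface normal.

    The division axis is the plate ellipsoid's shortest axis e3.  Raises
    when the plate is not flattened (L2/L3 <= ``min_flatness``), since then
    the shortest axis is ill-defined.
    """
    flatness = float(plate.lengths[1] / plate.lengths[2])
    if flatness <= min_flatness:
        raise SpheroidGeomError(
            f"plate not flattened (L2/L3 = {flatness:.3f} <= {min_flatness}): "
            "shortest axis ill-defined"
        )
    _, face, _ = closest_surface_point(mesh, plate.center)
    return angle_to_normal(plate.e3, mesh.face_normals[face])


def analyze_track(
    track: PlateTrack,
    mesh: TriangleMesh,
    min_flatness: float = MIN_PLATE_FLATNESS,
) -> DivisionRecord:
    """Reference-plate selection plus division angle and depth for one cell."""
    ref = select_reference_plate(track)
    angle = division_angle(ref.plate, mesh, min_flatness=min_flatness)
    _, _, depth = closest_surface_point(mesh, ref.plate.center)
    return DivisionRecord(
        cell_id=track.cell_id,
        angle_deg=angle,
        depth_um=depth,
        reference_frame=ref.frame,
        flags=ref.flags,
    )
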