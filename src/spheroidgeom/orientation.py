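"""Per-nucleus orientation relative to the spheroid surface, and cohort summaries.

For each fitted nucleus ellipsoid: find the closest point on the spheroid
convex hull to the ellipsoid centre, take the outward normal of that face,
and measure the angle between the nucleus long axis e1 and the normal.
90 deg means the long axis is parallel to the surface.  Cohort summaries
follow the analysis filters used for spheroid data: nuclei in a depth shell
(default 0-100 µm from the surface), and angle statistics restricted to
elongated (L1/L3 > 1.5), orientation-reliable nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

from .ellipsoid import (
    ELONGATION_THRESHOLD,
    Ellipsoid,
    is_elongated,
    orientation_reliable,
)
from .errors import EmptyInputError, SpheroidGeomError
from .geometry import TriangleMesh, angle_to_normal, closest_surface_point

__all__ = [
    "OrientationRecord",
    "nucleus_orientation",
    "shell_filter",
    "summarize",
    "CohortSummary",
]

#: A fitted centre farther than this outside the hull indicates the
#: annotations and the stack do not belong together.
MAX_CENTER_OUTSIDE_UM = 5.0


@dataclass(frozen=True)
class OrientationRecord:
    """One nucleus: elongation, depth below the surface, angle to the normal."""

    nucleus_id: str
    aspect_ratio: float
    depth_um: float
    angle_deg: float
    elongated: bool
    orientation_reliable: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg <= 90.0):
            raise SpheroidGeomError("angle must be in [0, 90] degrees")
        if self.aspect_ratio < 1.0 or self.depth_um < 0.0:
            raise SpheroidGeomError("aspect_ratio >= 1 and depth >= 0 required")


def nucleus_orientation(
    e: Ellipsoid,
    mesh: TriangleMesh,
    nucleus_id: str = "",
    elongation_threshold: float = ELONGATION_THRESHOLD,
    max_outside_um: float = MAX_CENTER_OUTSIDE_UM,
) -> OrientationRecord:
    """Orientation record of one fitted nucleus against the hull.

    Depth is measured from the ellipsoid *centre* to the hull; the angle is
    between e1 and the outward face normal of the nearest hull triangle.
    Raises if the centre lies farther than ``max_outside_um`` outside the
    hull (annotation/hull mismatch).
    """
    outside = mesh.max_outside_distance(e.center)
    if outside > max_outside_um:
        raise SpheroidGeomError(
            f"ellipsoid centre lies {outside:.1f} µm outside the hull "
            f"(limit {max_outside_um} µm): annotations and stack disagree"
        )
    _, face, depth = closest_surface_point(mesh, e.center)
    angle = angle_to_normal(e.e1, mesh.face_normals[face])
    return OrientationRecord(
        nucleus_id=nucleus_id,
        aspect_ratio=e.aspect_ratio,
        depth_um=depth,
        angle_deg=angle,
        elongated=is_elongated(e, elongation_threshold),
        orientation_reliable=orientation_reliable(e),
    )


def shell_filter(
    records: Iterable[OrientationRecord],
    min_depth: float = 0.0,
    max_depth: float = 100.0,
) -> list[OrientationRecord]:
    """Keep nuclei with ``min_depth <= depth <= max_depth`` (µm, inclusive)."""
    if min_depth > max_depth:
        raise SpheroidGeomError("min_depth must not exceed max_depth")
    return [r for r in records if min_depth <= r.depth_um <= max_depth]


@dataclass(frozen=True)
class CohortSummary:
    """Cohort statistics over a set of orientation records.

    Aspect-ratio statistics cover all records; the elongated fraction is
    the share with L1/L3 above the elongation threshold; angle statistics
    cover only elongated, orientation-reliable nuclei (``angle_n`` of
    them).  ``angle_available`` is False when that subset is empty.
    """

    n: int
    ratio_median: float
    ratio_q1: float
    ratio_q3: float
    elongated_fraction: float
    angle_n: int
    angle_available: bool
    angle_median: float | None
    angle_q1: float | None
    angle_q3: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(records: Sequence[OrientationRecord]) -> CohortSummary:
    """Summarise a cohort: ratio quartiles, elongated fraction, angle quartiles.

    Angle quartiles are computed over the elongated *and* orientation-
    reliable subset only; adding a non-elongated nucleus never moves the
    angle median.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("cannot summarise an empty cohort")
    ratios = np.array([r.aspect_ratio for r in records])
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    elong = np.array([r.elongated for r in records])
    angle_subset = [
        r.angle_deg for r in records if r.elongated and r.orientation_reliable
    ]
    if angle_subset:
        a1, amed, a3 = np.percentile(angle_subset, [25, 50, 75])
        angle_stats = (True, float(amed), float(a1), float(a3))
    else:
        angle_stats = (False, None, None, None)
    return CohortSummary(
        n=len(records),
        ratio_median=float(med),
        ratio_q1=float(q1),
        ratio_q3=float(q3),
        elongated_fraction=float(elong.mean()),
        angle_n=len(angle_subset),
        angle_available=angle_stats[0],
        angle_median=angle_stats[1],
        angle_q1=angle_stats[2],
        angle_q3=angle_stats[3],
    )
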