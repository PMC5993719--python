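"""Ellipsoid fitting to 3D boundary-point annotations.

A nucleus is modelled as an ellipsoid with centre ``c``, orthonormal axes
``e1, e2, e3`` and semi-axis lengths ``L1 >= L2 >= L3`` (µm).  Boundary
points are clicked on the three orthogonal views (xy, yz, xz) of the raw
stack around a central plane of the nucleus; all points enter one joint 3D
fit (the view tag is metadata only).

The fit is direct algebraic least squares on the general quadric

    Q(p) = A x^2 + B y^2 + C z^2 + D xy + E xz + F yz + G x + H y + I z + J

minimising ``sum_i Q(p_i)^2`` subject to ``||coeffs|| = 1`` (smallest right
singular vector of the design matrix).  Input points are centred and scaled
before the solve for conditioning; the result is mapped back afterwards.
The optimal quadric is then decomposed into centre/axes/lengths and
rejected if it is not an ellipsoid.  On noiseless points from a true
ellipsoid in general position the recovery is exact to numerical tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    NotAnEllipsoidError,
    TooFewPointsError,
)

__all__ = [
    "Ellipsoid",
    "AnnotationSet",
    "fit_ellipsoid",
    "quadric_to_ellipsoid",
    "aspect_ratio",
    "is_elongated",
    "orientation_reliable",
    "ELONGATION_THRESHOLD",
    "ORIENTATION_RELIABLE_RATIO",
]

#: L1/L3 above which a nucleus counts as elongated (strict inequality).
ELONGATION_THRESHOLD = 1.5

#: Minimum L1/L2 for the long axis to be considered well defined.  Below
#: this the nucleus is near-oblate/spherical and its long-axis direction is
#: numerically meaningless, so orientation results are flagged unreliable.
ORIENTATION_RELIABLE_RATIO = 1.02

#: Minimum number of annotation points: a normalised quadric has 9 degrees
#: of freedom.
MIN_POINTS = 9


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid with centre (µm), orthonormal axes and sorted lengths.

    ``axes`` is a (3, 3) array whose *rows* are the unit vectors e1, e2, e3
    paired with ``lengths`` L1 >= L2 >= L3.
    """

    center: np.ndarray
    axes: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        if self.center.shape != (3,) or self.axes.shape != (3, 3):
            raise DegenerateInputError("ellipsoid needs a 3-centre and 3x3 axes")
        if self.lengths.shape != (3,) or np.any(self.lengths <= 0):
            raise NotAnEllipsoidError("semi-axis lengths must be positive")
        if np.any(np.diff(self.lengths) > 1e-12):
            raise DegenerateInputError("lengths must be sorted L1 >= L2 >= L3")
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise DegenerateInputError("axes must be orthonormal")

    @property
    def e1(self) -> np.ndarray:
        """Unit vector of the longest axis."""
        return self.axes[0]

    @property
    def e3(self) -> np.ndarray:
        """Unit vector of the shortest axis."""
        return self.axes[2]

    @property
    def aspect_ratio(self) -> float:
        return float(self.lengths[0] / self.lengths[2])

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """Evaluate ``||D^-1 R (p - c)||^2 - 1`` (zero on the surface)."""
        q = (np.atleast_2d(points) - self.center) @ self.axes.T
        return np.einsum("ij,ij->i", q / self.lengths, q / self.lengths) - 1.0

    def surface_point(self, u: np.ndarray) -> np.ndarray:
        """Map a unit direction in the ellipsoid frame to a surface point."""
        u = np.asarray(u, dtype=float)
        return self.center + (u * self.lengths) @ self.axes


@dataclass
class AnnotationSet:
    """Boundary points of one nucleus, tagged with their source view."""

    nucleus_id: str
    points: np.ndarray  # (n, 3) µm
    views: list[str] = field(default_factory=list)  # 'xy' | 'yz' | 'xz'

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not self.views:
            self.views = ["xy"] * len(self.points)
        if len(self.views) != len(self.points):
            raise DegenerateInputError("one view tag per point required")


def _design_matrix(p: np.ndarray) -> np.ndarray:
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    return np.column_stack(
        [x * x, y * y, z * z, x * y, x * z, y * z, x, y, z, np.ones_like(x)]
    )


def quadric_to_ellipsoid(coeffs: np.ndarray) -> Ellipsoid:
    """Decompose quadric coefficients into an :class:`Ellipsoid`.

    ``coeffs`` are ``(A, B, C, D, E, F, G, H, I, J)`` for
    ``A x^2 + B y^2 + C z^2 + D xy + E xz + F yz + G x + H y + I z + J = 0``.

    Raises :class:`NotAnEllipsoidError` when the quadratic form (after sign
    normalisation) is not positive definite, i.e. the quadric is a
    hyperboloid, paraboloid, cone or degenerate surface.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (10,):
        raise DegenerateInputError("expected 10 quadric coefficients")
    A, B, C, D, E, F, G, H, I, J = coeffs
    M = np.array(
        [
            [A, D / 2.0, E / 2.0],
            [D / 2.0, B, F / 2.0],
            [E / 2.0, F / 2.0, C],
        ]
    )
    b = np.array([G, H, I])
    if abs(np.linalg.det(M)) < 1e-14 * max(1.0, np.abs(M).max()) ** 3:
        raise NotAnEllipsoidError("singular quadratic form (paraboloid/cylinder)")
    center = np.linalg.solve(M, -b / 2.0)
    # constant after translating to the centre: Q(center) = c^T M c + b.c + J
    k = -(center @ M @ center + b @ center + J)
    if k < 0:
        M, k = -M, -k
    eigvals, eigvecs = np.linalg.eigh(M)
    if np.any(eigvals <= 0) or k <= 0:
        raise NotAnEllipsoidError("quadratic form is not positive definite")
    lengths = np.sqrt(k / eigvals)  # eigh ascending eigvals -> descending lengths
    axes = eigvecs.T  # rows are eigenvectors, already aligned with lengths
    order = np.argsort(lengths)[::-1]
    lengths = lengths[order]
    axes = axes[order]
    # canonical signs: largest component of each axis positive, right-handed
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] *= -1.0
    if np.linalg.det(axes) < 0:
        axes[2] *= -1.0
    return Ellipsoid(center=center, axes=axes, lengths=lengths)


def fit_ellipsoid(annotation: AnnotationSet | np.ndarray) -> Ellipsoid:
    """Least-squares ellipsoid through a set of 3D boundary points.

    Accepts an :class:`AnnotationSet` or a raw (n, 3) array.  Raises
    :class:`TooFewPointsError` below 9 points,
    :class:`DegenerateInputError` for coplanar configurations and
    :class:`NotAnEllipsoidError` when the optimal quadric is not an
    ellipsoid.
    """
    pts = annotation.points if isinstance(annotation, AnnotationSet) else annotation
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    if len(pts) < MIN_POINTS:
        raise TooFewPointsError(
            f"need at least {MIN_POINTS} points, got {len(pts)}"
        )
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # coplanarity: the centred cloud must span 3 dimensions
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[2] <= 1e-9 * max(sv[0], 1e-30):
        raise DegenerateInputError("annotation points are (near-)coplanar")
    scale = float(np.sqrt((centred**2).sum(axis=1).mean()))
    normed = centred / scale

    dm = _design_matrix(normed)
    _, _, vt = np.linalg.svd(dm, full_matrices=False)
    coeffs = vt[-1]
    ell_n = quadric_to_ellipsoid(coeffs)
    return Ellipsoid(
        center=centroid + scale * ell_n.center,
        axes=ell_n.axes,
        lengths=scale * ell_n.lengths,
    )


def aspect_ratio(e: Ellipsoid) -> float:
    """Nucleus elongation: longest over shortest semi-axis, L1/L3 (>= 1)."""
    return e.aspect_ratio


def is_elongated(e: Ellipsoid, threshold: float = ELONGATION_THRESHOLD) -> bool:
    """True iff L1/L3 strictly exceeds ``threshold`` (default 1.5)."""
    return e.aspect_ratio > threshold


def orientation_reliable(
    e: Ellipsoid, min_ratio: float = ORIENTATION_RELIABLE_RATIO
) -> bool:
    """True iff L1/L2 >= ``min_ratio`` so the long-axis direction is well defined."""
    return float(e.lengths[0] / e.lengths[1]) >= min_ratio
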