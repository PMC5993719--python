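"""Spheroid envelope extraction from a fluorescence z-stack.

Pipeline: Gaussian denoise -> threshold -> convex hull of foreground voxel
centres -> triangulated surface mesh.  The hull is the proxy for the
spheroid surface; depth of any point is its distance to the hull.

Conventions
-----------
Stacks are stored ``(z, y, x)`` with per-axis spacing ``(dz, dy, dx)`` in
µm.  The voxel at index ``(iz, iy, ix)`` has physical centre
``(x, y, z) = (ix*dx, iy*dy, iz*dz)``; all meshes and queries live in that
physical (x, y, z) frame.  Foreground means *strictly greater than* the
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, SpheroidGeomError
from .geometry import TriangleMesh, closest_surface_point, convex_hull_mesh

__all__ = [
    "VoxelGrid",
    "BinaryGrid",
    "denoise",
    "binarize",
    "extract_convex_hull",
    "depth_from_surface",
    "read_tiff",
    "write_tiff",
]

#: Default Gaussian denoise width in µm.
DEFAULT_SIGMA_UM = 2.0

#: Below this foreground fraction the threshold step likely failed
#: (uneven staining / empty field); a warning is emitted.
MIN_FOREGROUND_FRACTION = 1e-4


@dataclass
class VoxelGrid:
    """3D intensity stack with anisotropic physical spacing.

    ``intensities`` is (z, y, x); ``spacing`` is (dz, dy, dx) in µm/voxel.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise DegenerateInputError("intensities must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DegenerateInputError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class BinaryGrid:
    """Boolean mask aligned with a :class:`VoxelGrid`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DegenerateInputError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)


def denoise(grid: VoxelGrid, sigma_um: float = DEFAULT_SIGMA_UM) -> VoxelGrid:
    """Gaussian smoothing with an isotropic physical width.

    ``sigma_um`` is converted to per-axis voxel sigmas via the grid spacing
    so the smoothing kernel is isotropic in µm despite anisotropic voxels.
    ``sigma_um = 0`` is the identity.
    """
    if sigma_um < 0:
        raise SpheroidGeomError("sigma_um must be >= 0")
    if sigma_um == 0:
        return VoxelGrid(grid.intensities.copy(), grid.spacing)
    sigmas = [sigma_um / s for s in grid.spacing]
    out = ndimage.gaussian_filter(
        grid.intensities.astype(np.float32, copy=False), sigma=sigmas
    )
    return VoxelGrid(out, grid.spacing)


def binarize(
    grid: VoxelGrid, method: str = "otsu", level: float | None = None
) -> BinaryGrid:
    """Threshold a stack into foreground (> threshold) and background.

    ``method='otsu'`` computes Otsu's threshold on the full 3D histogram
    (256 bins); ``method='fixed'`` uses the supplied ``level``.
    """
    data = grid.intensities
    if method == "otsu":
        if float(data.max()) == float(data.min()):
            raise SpheroidGeomError("flat image: Otsu threshold undefined")
        thr = float(threshold_otsu(data, nbins=256))
    elif method == "fixed":
        if level is None:
            raise SpheroidGeomError("fixed thresholding requires a level")
        thr = float(level)
    else:
        raise SpheroidGeomError(f"unknown threshold method {method!r}")
    mask = data > thr
    frac = float(mask.mean())
    if frac < MIN_FOREGROUND_FRACTION:
        warnings.warn(
            f"foreground fraction {frac:.2e} below {MIN_FOREGROUND_FRACTION:.0e}; "
            "envelope extraction may fail (uneven staining?)",
            stacklevel=2,
        )
    return BinaryGrid(mask, grid.spacing)


def _voxel_centers_um(mask: np.ndarray, spacing) -> np.ndarray:
    dz, dy, dx = spacing
    iz, iy, ix = np.nonzero(mask)
    return np.column_stack([ix * dx, iy * dy, iz * dz]).astype(float)


def extract_convex_hull(
    binary: BinaryGrid,
    largest_component: bool = False,
    boundary_only: bool | None = None,
) -> TriangleMesh:
    """Smallest convex polyhedron containing all foreground voxel centres.

    Voxel centres are converted to µm before hulling so anisotropic spacing
    is handled in the physical frame.  For large masks the hull is computed
    on the boundary voxels only (mask minus its 6-connected erosion), which
    has the same hull as the solid set; pass ``boundary_only`` explicitly to
    force either behaviour.  ``largest_component=True`` first keeps only the
    largest connected foreground component (useful for noisy stacks; off by
    default).
    """
    mask = binary.mask
    if largest_component:
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    n_fg = int(mask.sum())
    if n_fg < 4:
        raise DegenerateInputError("need at least 4 foreground voxels")
    if boundary_only is None:
        boundary_only = n_fg > 100_000
    if boundary_only:
        interior = ndimage.binary_erosion(mask)
        shell = mask & ~interior
        if int(shell.sum()) >= 4:
            mask = shell
    points = _voxel_centers_um(mask, binary.spacing)
    return convex_hull_mesh(points)


def depth_from_surface(p, mesh: TriangleMesh) -> float:
    """Distance (µm) of a point to the hull surface; 0 on the hull."""
    _, _, d = closest_surface_point(mesh, p)
    return d


def read_tiff(path, spacing: tuple[float, float, float]) -> VoxelGrid:
    """Read a multi-page TIFF z-stack as a :class:`VoxelGrid`.

    ``spacing = (dz, dy, dx)`` in µm must be supplied by the caller (TIFFs
    from light-sheet acquisitions rarely carry reliable z metadata); the
    acquisition default is a 1 µm z-step.
    """
    import tifffile

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return VoxelGrid(data, spacing)


def write_tiff(path, grid: VoxelGrid) -> None:
    """Write a stack as a multi-page TIFF (one page per z-plane)."""
    import tifffile

    tifffile.imwrite(path, grid.intensities, photometric="minisblack")
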