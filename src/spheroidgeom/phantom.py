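"""Ground-truthed synthetic spheroid phantoms.

Every pipeline stage is testable without external image data: this module
generates (1) nucleus ellipsoids with controlled aspect-ratio and
orientation statistics inside a spheroid of known shape, (2) tri-view
boundary-point annotations of each nucleus, (3) a rendered fluorescence
z-stack with PSF blur, depth attenuation and Poisson + Gaussian noise, and
(4) mitosis event tables with controlled phase-duration distributions.
All stages are bit-reproducible for a fixed seed.

The spheroid is modelled as a ball (default radius 325 µm, i.e. a 650 µm
spheroid); an axis-scaled "ellipsoid" shape variant exercises non-spherical
hulls without claiming to model gel mechanics.  Orientation modes set the
nucleus long axis e1 relative to the local outward surface direction:
``tangential`` (in the tangent plane, plus angular noise), ``radial``
(along the outward direction) or ``isotropic`` (uniform on the direction
sphere; the null in which cos(angle) is uniform and the median angle is
60 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .ellipsoid import AnnotationSet, Ellipsoid
from .errors import SpheroidGeomError
from .geometry import angle_to_normal
from .surface import VoxelGrid
from .timing import DEFAULT_FRAME_INTERVAL_MIN, MitosisEvent

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_ground_truth",
    "sample_annotations",
    "render_volume",
    "generate_mitosis_events",
    "make_plate_track",
    "truncated_normal_mean",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic spheroid.

    Geometry defaults mimic the imaged samples: a 650 µm-diameter spheroid
    (radius 325), 1 µm z-step with 0.65 µm pixels, lognormal aspect ratios
    with median 1.83 (the control cohort median) and L3 = 4 µm nuclei.
    """

    spheroid_radius_um: float = 325.0
    shape: str = "ball"  # 'ball' | 'ellipsoid'
    shape_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)  # x,y,z semiaxis factors
    n_nuclei: int = 100
    ratio_log_mu: float = math.log(1.83)
    ratio_log_sigma: float = 0.25
    l3_um: float = 4.0
    orientation_mode: str = "tangential"  # 'tangential' | 'radial' | 'isotropic'
    orientation_noise_deg: float = 10.0
    #: cytoplasmic rim: minimum gap (µm) between a nucleus envelope and the
    #: spheroid surface.  Peripheral nuclei sit inside cells, not on the
    #: spheroid boundary; without this rim the PSF tails of bright nuclei
    #: tangent to the surface would bulge the thresholded envelope.
    surface_clearance_um: float = 5.0
    spacing: tuple[float, float, float] = (1.0, 0.65, 0.65)  # (dz, dy, dx) µm
    background_intensity: float = 0.0
    cytoplasm_intensity: float = 40.0
    nucleus_intensity: float = 200.0
    psf_sigma_um: float = 1.0
    read_noise_sd: float = 5.0
    poisson_scale: float = 1.0  # photons per intensity unit; 0 disables shot noise
    attenuation_per_um: float = 0.002
    margin_um: float = 8.0  # background border around the spheroid in the stack
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spheroid_radius_um <= 0 or self.n_nuclei < 1:
            raise SpheroidGeomError("radius must be > 0 and n_nuclei >= 1")
        if min(self.read_noise_sd, self.poisson_scale, self.attenuation_per_um) < 0:
            raise SpheroidGeomError("noise parameters must be >= 0")
        if self.orientation_mode not in ("tangential", "radial", "isotropic"):
            raise SpheroidGeomError(f"unknown orientation mode {self.orientation_mode!r}")
        if self.shape not in ("ball", "ellipsoid"):
            raise SpheroidGeomError(f"unknown shape {self.shape!r}")

    @property
    def semi_axes_um(self) -> np.ndarray:
        """Spheroid semi-axes (x, y, z) in µm."""
        return self.spheroid_radius_um * np.asarray(self.shape_scale, dtype=float)

    def grid_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) of the rendering grid that holds this phantom."""
        dz, dy, dx = self.spacing
        half = self.semi_axes_um + self.margin_um
        nx = int(np.ceil(2 * half[0] / dx)) + 1
        ny = int(np.ceil(2 * half[1] / dy)) + 1
        nz = int(np.ceil(2 * half[2] / dz)) + 1
        return nz, ny, nx

    @property
    def center_um(self) -> np.ndarray:
        """Spheroid centre (x, y, z) in the stack's physical frame.

        The stack frame maps voxel (iz, iy, ix) to (ix*dx, iy*dy, iz*dz);
        the phantom sits at the grid centre so hull meshes extracted from
        the rendered stack and the ground truth share one frame.
        """
        nz, ny, nx = self.grid_shape()
        dz, dy, dx = self.spacing
        return np.array(
            [(nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0, (nz - 1) * dz / 2.0]
        )


@dataclass
class GroundTruth:
    """True nuclei and surface of one phantom, plus per-nucleus truths.

    Nucleus centres are expressed in the rendered stack's physical frame
    (spheroid centre at ``spec.center_um``).
    """

    spec: PhantomSpec
    nuclei: list[Ellipsoid]
    true_angles_deg: np.ndarray  # e1 vs local outward normal
    true_depths_um: np.ndarray  # centre depth below the ideal surface

    def outward_normal(self, p: np.ndarray) -> np.ndarray:
        return _outward_normal(
            np.asarray(p, dtype=float) - self.spec.center_um,
            self.spec.semi_axes_um,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _outward_normal(p: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    """Outward normal direction of the (scaled-ball) surface nearest to p.

    Gradient of the implicit function sum((p_i/a_i)^2) evaluated at p; for
    a ball this is the radial direction.
    """
    g = p / semi_axes**2
    n = np.linalg.norm(g)
    if n == 0:  # exact centre: any direction; pick +z deterministically
        return np.array([0.0, 0.0, 1.0])
    return g / n


def _surface_depth(p: np.ndarray, semi_axes: np.ndarray) -> float:
    """Depth of p below the ideal surface.

    Exact (R - |p|) for a ball; for the scaled variant the first-order
    estimate along the implicit-function gradient is used.
    """
    if np.allclose(semi_axes, semi_axes[0]):
        return float(semi_axes[0] - np.linalg.norm(p))
    f = float(np.sum((p / semi_axes) ** 2))
    grad = 2.0 * p / semi_axes**2
    gn = float(np.linalg.norm(grad))
    if gn == 0:
        return float(semi_axes.min())
    return (1.0 - f) / gn


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _orient_long_axis(
    normal: np.ndarray, mode: str, noise_deg: float, rng: np.random.Generator
) -> np.ndarray:
    if mode == "isotropic":
        return _random_unit_vector(rng)
    if mode == "radial":
        e1 = normal.copy()
    else:  # tangential: uniform direction in the tangent plane
        t = np.cross(normal, _random_unit_vector(rng))
        while np.linalg.norm(t) < 1e-9:
            t = np.cross(normal, _random_unit_vector(rng))
        e1 = _unit(t)
    if noise_deg > 0:
        # tilt by a normal-distributed angle about a random axis orthogonal to e1
        tilt = math.radians(rng.normal(0.0, noise_deg))
        axis = np.cross(e1, _random_unit_vector(rng))
        while np.linalg.norm(axis) < 1e-9:
            axis = np.cross(e1, _random_unit_vector(rng))
        e1 = _unit(_rotate_about(e1, _unit(axis), tilt))
    return e1


def _complete_frame(e1: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Right-handed orthonormal frame with given first row."""
    helper = _random_unit_vector(rng)
    while abs(helper @ e1) > 0.99:
        helper = _random_unit_vector(rng)
    e2 = _unit(np.cross(e1, helper))
    e3 = np.cross(e1, e2)
    return np.vstack([e1, e2, e3])


def generate_ground_truth(spec: PhantomSpec, max_attempts: int = 5000) -> GroundTruth:
    """Sample non-overlapping nucleus ellipsoids inside the spheroid.

    Centres are uniform in the spheroid volume (kept at least L1 inside the
    surface so nuclei do not protrude); overlap is rejected when two
    centres come closer than L1_i + L1_j.  Aspect ratios L1/L3 are
    lognormal; L2 is the geometric mean of L1 and L3.  Deterministic for a
    fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    semi = spec.semi_axes_um
    nuclei: list[Ellipsoid] = []
    centers: list[np.ndarray] = []
    l1s: list[float] = []
    angles: list[float] = []
    depths: list[float] = []
    for _ in range(spec.n_nuclei):
        ratio = float(rng.lognormal(spec.ratio_log_mu, spec.ratio_log_sigma))
        ratio = max(ratio, 1.0)
        l3 = spec.l3_um
        l1 = ratio * l3
        l2 = math.sqrt(l1 * l3)
        placed = False
        for _attempt in range(max_attempts):
            u = rng.random() ** (1.0 / 3.0)  # uniform in the unit ball
            direction = _random_unit_vector(rng)
            # margin keeps the nucleus (plus its cytoplasmic rim) inside
            c = direction * u * (semi - l1 - spec.surface_clearance_um)
            if all(
                np.linalg.norm(c - co) >= l1 + lo for co, lo in zip(centers, l1s)
            ):
                placed = True
                break
        if not placed:
            raise SpheroidGeomError(
                f"could not place {spec.n_nuclei} nuclei of L1~{l1:.1f} µm in a "
                f"{spec.spheroid_radius_um:.0f} µm spheroid after {max_attempts} tries"
            )
        normal = _outward_normal(c, semi)
        e1 = _orient_long_axis(normal, spec.orientation_mode, spec.orientation_noise_deg, rng)
        axes = _complete_frame(e1, rng)
        ell = Ellipsoid(
            center=spec.center_um + c, axes=axes, lengths=np.array([l1, l2, l3])
        )
        nuclei.append(ell)
        centers.append(c)
        l1s.append(l1)
        angles.append(angle_to_normal(e1, normal))
        depths.append(_surface_depth(c, semi))
    return GroundTruth(
        spec=spec,
        nuclei=nuclei,
        true_angles_deg=np.asarray(angles),
        true_depths_um=np.asarray(depths),
    )


def sample_annotations(
    e: Ellipsoid,
    points_per_view: int = 5,
    jitter_sd_um: float = 0.0,
    seed: int | np.random.Generator = 0,
    nucleus_id: str = "",
) -> AnnotationSet:
    """Tri-view boundary points of an ellipsoid, with optional jitter.

    Points lie on the intersection of the ellipsoid surface with the three
    world coordinate planes (xy, yz, xz) through its centre — the curves a
    user traces when clicking the boundary on orthogonal views of a central
    plane — plus isotropic Gaussian jitter of ``jitter_sd_um``.
    """
    if points_per_view < 3:
        raise SpheroidGeomError("need at least 3 points per view")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    plane_normals = {
        "xy": np.array([0.0, 0.0, 1.0]),
        "yz": np.array([1.0, 0.0, 0.0]),
        "xz": np.array([0.0, 1.0, 0.0]),
    }
    # ellipsoid frame: q = R (p - c), surface q^T D q = 1
    D = np.diag(1.0 / e.lengths**2)
    points = []
    views = []
    for view, n_world in plane_normals.items():
        m = e.axes @ n_world  # plane normal in the ellipsoid frame
        # orthonormal basis (u, v) of the plane m-perp
        helper = np.array([1.0, 0.0, 0.0])
        if abs(helper @ m) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = _unit(np.cross(m, helper))
        v = np.cross(m, u)
        ts = rng.uniform(0.0, 2.0 * math.pi, size=points_per_view)
        for t in ts:
            w = math.cos(t) * u + math.sin(t) * v
            r = 1.0 / math.sqrt(w @ D @ w)
            p = e.center + (r * w) @ e.axes  # back to world frame
            points.append(p)
            views.append(view)
    points = np.asarray(points)
    if jitter_sd_um > 0:
        points = points + rng.normal(0.0, jitter_sd_um, size=points.shape)
    return AnnotationSet(nucleus_id=nucleus_id, points=points, views=views)


def render_volume(gt: GroundTruth) -> VoxelGrid:
    """Render the phantom as a float32 fluorescence z-stack.

    Voxels inside a nucleus take the nucleus intensity, cytoplasm (inside
    the spheroid) the cytoplasm intensity, background the background level.
    Intensities are attenuated as exp(-attenuation x depth-below-surface),
    blurred with a Gaussian PSF, then Poisson shot noise (if
    ``poisson_scale > 0``) and Gaussian read noise are applied.
    Deterministic for the spec seed.
    """
    spec = gt.spec
    semi = spec.semi_axes_um  # (x, y, z)
    dz, dy, dx = spec.spacing
    nz, ny, nx = spec.grid_shape()
    center = spec.center_um
    # physical voxel-centre coordinates in the stack frame (ix*dx, ...)
    xs = (np.arange(nx) * dx).astype(np.float32)
    ys = (np.arange(ny) * dy).astype(np.float32)
    zs = (np.arange(nz) * dz).astype(np.float32)
    if 2 * (semi[0] + spec.margin_um) > nx * dx + dx or 2 * (
        semi[2] + spec.margin_um
    ) > nz * dz + dz:
        raise SpheroidGeomError("spheroid exceeds the rendering grid")

    rho2 = (
        ((zs[:, None, None] - center[2]) / semi[2]) ** 2
        + ((ys[None, :, None] - center[1]) / semi[1]) ** 2
        + ((xs[None, None, :] - center[0]) / semi[0]) ** 2
    ).astype(np.float32)
    img = np.full((nz, ny, nx), spec.background_intensity, dtype=np.float32)
    inside = rho2 <= 1.0
    img[inside] = spec.cytoplasm_intensity

    for ell in gt.nuclei:
        c = ell.center  # (x, y, z)
        r = float(ell.lengths[0])
        ix0 = max(int(np.searchsorted(xs, c[0] - r) - 1), 0)
        ix1 = min(int(np.searchsorted(xs, c[0] + r) + 1), nx)
        iy0 = max(int(np.searchsorted(ys, c[1] - r) - 1), 0)
        iy1 = min(int(np.searchsorted(ys, c[1] + r) + 1), ny)
        iz0 = max(int(np.searchsorted(zs, c[2] - r) - 1), 0)
        iz1 = min(int(np.searchsorted(zs, c[2] + r) + 1), nz)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        gz, gy, gx = np.meshgrid(
            zs[iz0:iz1], ys[iy0:iy1], xs[ix0:ix1], indexing="ij"
        )
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        q = (pts - c) @ ell.axes.T / ell.lengths
        in_nuc = (q**2).sum(axis=1) <= 1.0
        block = img[iz0:iz1, iy0:iy1, ix0:ix1].reshape(-1)
        block[in_nuc] = spec.nucleus_intensity
        img[iz0:iz1, iy0:iy1, ix0:ix1] = block.reshape(
            iz1 - iz0, iy1 - iy0, ix1 - ix0
        )

    if spec.attenuation_per_um > 0:
        if np.allclose(semi, semi[0]):
            depth = np.maximum(semi[0] * (1.0 - np.sqrt(rho2)), 0.0)
        else:
            depth = np.maximum(semi.min() * (1.0 - np.sqrt(rho2)), 0.0)
        img *= np.exp(-spec.attenuation_per_um * depth).astype(np.float32)
    del rho2

    if spec.psf_sigma_um > 0:
        img = ndimage.gaussian_filter(
            img, sigma=[spec.psf_sigma_um / s for s in spec.spacing]
        )

    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from placement
    if spec.poisson_scale > 0:
        img = rng.poisson(np.maximum(img, 0.0) * spec.poisson_scale).astype(
            np.float32
        ) / np.float32(spec.poisson_scale)
    if spec.read_noise_sd > 0:
        img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape).astype(
            np.float32
        )
    return VoxelGrid(img.astype(np.float32), spec.spacing)


def make_plate_track(
    e1_direction: np.ndarray,
    center: np.ndarray,
    cell_id: str = "",
    plate_radius_um: float = 4.0,
    plate_thickness_um: float = 1.2,
    frames: tuple[int, ...] = (3, 5, 7),
    anaphase_frame: int | None = 8,
    seed: int | np.random.Generator = 0,
):
    """Build a metaphase-plate track whose division axis is ``e1_direction``.

    The plate is a flattened ellipsoid with its *shortest* axis along the
    requested division axis; combined with :func:`generate_ground_truth`
    this turns a nucleus-orientation phantom into a division-axis phantom.
    """
    from .division import PlateTrack

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    axis = _unit(np.asarray(e1_direction, dtype=float))
    frame3 = _complete_frame(axis, rng)
    # shortest axis along the division axis; in-plane axes from the frame
    axes = np.vstack([frame3[1], frame3[2], axis])
    plate = Ellipsoid(
        center=np.asarray(center, dtype=float),
        axes=axes,
        lengths=np.array([plate_radius_um, plate_radius_um, plate_thickness_um]),
    )
    plates = [plate] * len(frames)
    return PlateTrack(
        cell_id=cell_id,
        frames=list(frames),
        plates=plates,
        anaphase_frame=anaphase_frame,
    )


def truncated_normal_mean(mu: float, sigma: float, lower: float) -> float:
    """Mean of a normal(mu, sigma) truncated to [lower, inf) — the oracle
    against which simulated cohorts are checked."""
    a = (lower - mu) / sigma
    return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sigma))


def generate_mitosis_events(
    n: int,
    prometaphase_mu_min: float = 14.4,
    prometaphase_sigma_min: float = 7.6,
    metaphase_mu_min: float = 13.0,
    metaphase_sigma_min: float = 5.0,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    recording_length_frames: int = 60,
    min_duration_min: float = 4.0,
    seed: int = 0,
) -> list[MitosisEvent]:
    """Simulate mitosis event tables with truncated-normal phase durations.

    Default duration parameters are the control-cohort values (prometaphase
    14.4 +/- 7.6 min, metaphase 13 +/- 5 min); durations are truncated at
    ``min_duration_min`` (one frame) and discretised to whole frames.
    Condensation times are uniform from one typical prometaphase before the
    movie starts (those cells enter censored) to the end of the recording,
    so a realistic share of events is censored on either side.
    Deterministic for a fixed seed.
    """
    if min(prometaphase_mu_min, prometaphase_sigma_min, metaphase_mu_min,
           metaphase_sigma_min) <= 0 or n < 1:
        raise SpheroidGeomError("cohort parameters must be positive")
    rng = np.random.default_rng(seed)

    def draw(mu: float, sigma: float, size: int) -> np.ndarray:
        a = (min_duration_min - mu) / sigma
        return stats.truncnorm.rvs(
            a, np.inf, loc=mu, scale=sigma, size=size, random_state=rng
        )

    t_end = recording_length_frames * frame_interval_min
    events: list[MitosisEvent] = []
    while len(events) < n:
        pro = float(draw(prometaphase_mu_min, prometaphase_sigma_min, 1)[0])
        met = float(draw(metaphase_mu_min, metaphase_sigma_min, 1)[0])
        t0 = float(rng.uniform(-prometaphase_mu_min, t_end))
        if t0 + pro < 0:
            continue  # plate formed before the movie: mitosis never annotated
        censored = t0 < 0
        cond_frame = max(int(round(t0 / frame_interval_min)), 0)
        meta_frame = int(round((t0 + pro) / frame_interval_min))
        ana_frame = int(round((t0 + pro + met) / frame_interval_min))
        meta_f = meta_frame if meta_frame <= recording_length_frames else None
        ana_f = (
            ana_frame
            if meta_f is not None and ana_frame <= recording_length_frames
            else None
        )
        if meta_f is not None and meta_f < cond_frame:
            meta_f = cond_frame  # rounding guard
        events.append(
            MitosisEvent(
                cell_id=f"cell{len(events):04d}",
                condensation_frame=cond_frame,
                metaphase_frame=meta_f,
                anaphase_frame=ana_f,
                condensation_censored=censored,
                last_observed_frame=recording_length_frames,
                frame_interval_min=frame_interval_min,
            )
        )
    return events
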