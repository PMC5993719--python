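"""Envelope extraction: denoise, threshold, convex hull, depth queries."""

import numpy as np
import pytest
from scipy import ndimage

from spheroidgeom.errors import DegenerateInputError, SpheroidGeomError
from spheroidgeom.surface import (
    BinaryGrid,
    VoxelGrid,
    binarize,
    denoise,
    depth_from_surface,
    extract_convex_hull,
    read_tiff,
    write_tiff,
)


def ball_mask(radius_vox: int, pad: int = 2) -> np.ndarray:
    n = 2 * (radius_vox + pad) + 1
    c = n // 2
    z, y, x = np.ogrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2


def test_denoise_zero_sigma_is_identity(rng):
    grid = VoxelGrid(rng.random((5, 6, 7)), (1.0, 0.65, 0.65))
    out = denoise(grid, 0.0)
    np.testing.assert_array_equal(out.intensities, grid.intensities)


def test_denoise_constant_image_unchanged():
    grid = VoxelGrid(np.full((8, 8, 8), 3.5), (1.0, 1.0, 1.0))
    out = denoise(grid, 2.0)
    np.testing.assert_allclose(out.intensities, 3.5, atol=1e-5)


def test_denoise_matches_direct_convolution():
    """Single bright voxel, isotropic spacing: output is symmetric and equals
    an explicit truncated-Gaussian convolution."""
    img = np.zeros((21, 21, 21), dtype=np.float32)
    img[10, 10, 10] = 1.0
    out = denoise(VoxelGrid(img, (1.0, 1.0, 1.0)), sigma_um=1.5).intensities
    np.testing.assert_allclose(out, out[::-1], atol=1e-7)
    np.testing.assert_allclose(out, np.swapaxes(out, 0, 2), atol=1e-7)
    assert out.sum() == pytest.approx(1.0, abs=1e-5)
    # independent direct convolution with the same truncated kernel
    r = int(4 * 1.5 + 0.5)
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-(ax**2) / (2 * 1.5**2))
    k1 /= k1.sum()
    expected = img.copy()
    for axis in range(3):
        expected = ndimage.convolve1d(expected, k1, axis=axis, mode="constant")
    np.testing.assert_allclose(out, expected, atol=1e-6)


def test_denoise_anisotropic_sigma_scaling():
    """Physical sigma, anisotropic voxels: the blur must be wider (in voxels)
    along the finer-sampled axes."""
    img = np.zeros((31, 31, 31), dtype=np.float32)
    img[15, 15, 15] = 1.0
    out = denoise(VoxelGrid(img, (2.0, 0.5, 0.5)), sigma_um=2.0).intensities
    profile_z = out[:, 15, 15]
    profile_y = out[15, :, 15]
    width_z = (profile_z > profile_z.max() / 2).sum()
    width_y = (profile_y > profile_y.max() / 2).sum()
    assert width_y > width_z


def test_negative_sigma_rejected(rng):
    grid = VoxelGrid(rng.random((4, 4, 4)), (1, 1, 1))
    with pytest.raises(SpheroidGeomError):
        denoise(grid, -1.0)


def test_binarize_two_level_image():
    img = np.full((6, 6, 6), 10.0)
    img[2:4, 2:4, 2:4] = 200.0
    grid = VoxelGrid(img, (1, 1, 1))
    otsu = binarize(grid, "otsu")
    fixed = binarize(grid, "fixed", level=100.0)
    np.testing.assert_array_equal(otsu.mask, img == 200.0)
    np.testing.assert_array_equal(otsu.mask, fixed.mask)


def test_binarize_flat_image_rejected():
    grid = VoxelGrid(np.full((4, 4, 4), 7.0), (1, 1, 1))
    with pytest.raises(SpheroidGeomError):
        binarize(grid, "otsu")
    with pytest.raises(SpheroidGeomError):
        binarize(grid, "fixed")  # fixed without a level


def test_cube_corner_hull():
    mask = np.zeros((3, 3, 3), dtype=bool)
    for z in (0, 2):
        for y in (0, 2):
            for x in (0, 2):
                mask[z, y, x] = True
    mesh = extract_convex_hull(BinaryGrid(mask, (1.0, 1.0, 1.0)))
    assert len(mesh.vertices) == 8
    assert mesh.n_faces == 12
    # hull volume via the divergence theorem using the outward face normals
    tri = mesh.triangles()
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    vol = np.sum(areas * np.einsum("ij,ij->i", mesh.face_normals, tri[:, 0])) / 3.0
    assert vol == pytest.approx(8.0, abs=1e-9)


def test_digitized_ball_hull_vertex_radii():
    mask = ball_mask(radius_vox=25)
    mesh = extract_convex_hull(BinaryGrid(mask, (1.0, 1.0, 1.0)))
    center = np.array(mask.shape[::-1], dtype=float) // 2
    radii = np.linalg.norm(mesh.vertices - center, axis=1)
    diag = np.sqrt(3.0)
    assert np.all(np.abs(radii - 25.0) <= diag)


def test_hull_convexity_bruteforce(rng):
    """No foreground voxel centre lies strictly outside any hull face plane."""
    mask = np.zeros((30, 30, 30), dtype=bool)
    idx = rng.integers(0, 30, size=(10_000, 3))
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    spacing = (1.0, 0.7, 0.5)
    mesh = extract_convex_hull(BinaryGrid(mask, spacing), boundary_only=False)
    iz, iy, ix = np.nonzero(mask)
    pts = np.column_stack([ix * spacing[2], iy * spacing[1], iz * spacing[0]])
    a = mesh.triangles()[:, 0, :]
    d = mesh.face_normals @ pts.T - np.einsum(
        "ij,ij->i", mesh.face_normals, a
    )[:, None]
    assert d.max() <= 1e-9 * 30


def test_hull_idempotent(rng):
    pts_mask = np.zeros((20, 20, 20), dtype=bool)
    idx = rng.integers(0, 20, size=(500, 3))
    pts_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    mesh = extract_convex_hull(BinaryGrid(pts_mask, (1, 1, 1)))
    from spheroidgeom.geometry import convex_hull_mesh

    mesh2 = convex_hull_mesh(mesh.vertices)
    assert len(mesh2.vertices) == len(mesh.vertices)


def test_boundary_reduction_preserves_hull():
    mask = ball_mask(radius_vox=15)
    full = extract_convex_hull(BinaryGrid(mask, (1, 1, 1)), boundary_only=False)
    shell = extract_convex_hull(BinaryGrid(mask, (1, 1, 1)), boundary_only=True)
    assert sorted(map(tuple, full.vertices)) == sorted(map(tuple, shell.vertices))


def test_too_few_foreground_rejected():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[0, 0, :3] = True
    with pytest.raises(DegenerateInputError):
        extract_convex_hull(BinaryGrid(mask, (1, 1, 1)))


def test_depth_examples_digitized_ball():
    mask = ball_mask(radius_vox=30)
    mesh = extract_convex_hull(BinaryGrid(mask, (1.0, 1.0, 1.0)))
    center = np.array(mask.shape[::-1], dtype=float) // 2
    diag = np.sqrt(3.0)
    assert depth_from_surface(mesh.vertices[0], mesh) == pytest.approx(0.0, abs=1e-9)
    assert depth_from_surface(center, mesh) == pytest.approx(30.0, abs=diag)
    p = center + np.array([0.4 * 30, 0, 0])
    assert depth_from_surface(p, mesh) == pytest.approx(0.6 * 30, abs=diag)


def test_depth_is_lipschitz(rng):
    mask = ball_mask(radius_vox=10)
    mesh = extract_convex_hull(BinaryGrid(mask, (1, 1, 1)))
    for _ in range(30):
        p = rng.uniform(0, 24, 3)
        q = rng.uniform(0, 24, 3)
        dp = depth_from_surface(p, mesh)
        dq = depth_from_surface(q, mesh)
        assert abs(dp - dq) <= np.linalg.norm(p - q) + 1e-9


def test_tiff_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    grid = VoxelGrid(rng.random((4, 5, 6)).astype(np.float32), (1.0, 0.65, 0.65))
    path = tmp_path / "stack.tif"
    write_tiff(path, grid)
    back = read_tiff(path, (1.0, 0.65, 0.65))
    np.testing.assert_array_equal(back.intensities, grid.intensities)
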