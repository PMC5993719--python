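"""Algebraic ellipsoid fitting and its geometric parameters."""

import math

import numpy as np
import pytest

from conftest import random_rotation
from spheroidgeom.ellipsoid import (
    AnnotationSet,
    Ellipsoid,
    aspect_ratio,
    fit_ellipsoid,
    is_elongated,
    orientation_reliable,
    quadric_to_ellipsoid,
)
from spheroidgeom.errors import (
    DegenerateInputError,
    NotAnEllipsoidError,
    TooFewPointsError,
)
from spheroidgeom.geometry import angle_to_normal
from spheroidgeom.phantom import sample_annotations


def ellipsoid_points(center, axes, lengths, n=40, seed=0):
    """Exact surface points of an ellipsoid, roughly uniform directions."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return np.asarray(center) + (u * np.asarray(lengths)) @ np.asarray(axes)


SPHERE_14 = np.vstack(
    [
        np.eye(3),
        -np.eye(3),
        np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        / math.sqrt(3),
    ]
)


def test_unit_sphere_identity():
    e = fit_ellipsoid(SPHERE_14)
    np.testing.assert_allclose(e.center, 0.0, atol=1e-6)
    np.testing.assert_allclose(e.lengths, 1.0, atol=1e-6)


def test_axis_aligned_ellipsoid_recovered():
    """Exact points on semi-axes (3,2,1) at centre (10,5,2); residual of the
    fitted quadric is zero at every input point."""
    center = np.array([10.0, 5.0, 2.0])
    pts = ellipsoid_points(center, np.eye(3), [3.0, 2.0, 1.0], n=30, seed=1)
    e = fit_ellipsoid(pts)
    np.testing.assert_allclose(e.center, center, atol=1e-6)
    np.testing.assert_allclose(e.lengths, [3.0, 2.0, 1.0], atol=1e-6)
    np.testing.assert_allclose(e.implicit(pts), 0.0, atol=1e-8)


def test_fit_rotation_equivariance(rng):
    """Fitting rotated points gives rotated axes (up to line sign)."""
    center = np.array([1.0, -2.0, 3.0])
    pts = ellipsoid_points(center, np.eye(3), [3.0, 2.0, 1.0], n=30, seed=2)
    R = random_rotation(rng)
    e_plain = fit_ellipsoid(pts)
    e_rot = fit_ellipsoid(pts @ R.T)
    np.testing.assert_allclose(e_rot.center, R @ center, atol=1e-6)
    np.testing.assert_allclose(e_rot.lengths, e_plain.lengths, atol=1e-6)
    for i in range(3):
        expected = R @ e_plain.axes[i]
        dot = abs(expected @ e_rot.axes[i])
        assert dot == pytest.approx(1.0, abs=1e-6)


def test_fit_translation_equivariance(rng):
    pts = ellipsoid_points([0, 0, 0], np.eye(3), [3.0, 2.0, 1.0], n=25, seed=3)
    shift = np.array([100.0, -50.0, 7.0])
    e0 = fit_ellipsoid(pts)
    e1 = fit_ellipsoid(pts + shift)
    np.testing.assert_allclose(e1.center, e0.center + shift, atol=1e-6)
    np.testing.assert_allclose(e1.lengths, e0.lengths, atol=1e-6)


def test_too_few_points_rejected():
    with pytest.raises(TooFewPointsError):
        fit_ellipsoid(SPHERE_14[:8])


def test_coplanar_points_rejected():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(20, 3))
    pts[:, 2] = 5.0
    with pytest.raises(DegenerateInputError):
        fit_ellipsoid(pts)


def test_non_ellipsoid_cloud_rejected(rng):
    """Points on a hyperbolic surface must raise, not return garbage."""
    x = rng.uniform(-2, 2, 60)
    y = rng.uniform(-2, 2, 60)
    z = np.sqrt(1 + x**2 + y**2) * np.where(rng.random(60) < 0.5, -1, 1)
    with pytest.raises(NotAnEllipsoidError):
        fit_ellipsoid(np.column_stack([x, y, z]))


@pytest.mark.parametrize(
    "coeffs, lengths",
    [
        ((1, 1, 1, 0, 0, 0, 0, 0, 0, -1), (1.0, 1.0, 1.0)),  # unit sphere
        ((1 / 9, 1 / 4, 1, 0, 0, 0, 0, 0, 0, -1), (3.0, 2.0, 1.0)),  # canonical
    ],
)
def test_quadric_decomposition(coeffs, lengths):
    e = quadric_to_ellipsoid(coeffs)
    np.testing.assert_allclose(e.center, 0.0, atol=1e-12)
    np.testing.assert_allclose(e.lengths, lengths, atol=1e-12)


def test_quadric_canonical_axes():
    e = quadric_to_ellipsoid((1 / 9, 1 / 4, 1, 0, 0, 0, 0, 0, 0, -1))
    np.testing.assert_allclose(np.abs(e.axes), np.eye(3), atol=1e-12)


def test_hyperboloid_rejected():
    with pytest.raises(NotAnEllipsoidError):
        quadric_to_ellipsoid((1, 1, -1, 0, 0, 0, 0, 0, 0, -1))


@pytest.mark.parametrize(
    "lengths, expected",
    [((1.0, 1.0, 1.0), 1.0), ((3.0, 2.0, 1.0), 3.0), ((1.83, 1.2, 1.0), 1.83)],
)
def test_aspect_ratio(lengths, expected):
    e = Ellipsoid(center=np.zeros(3), axes=np.eye(3), lengths=np.array(lengths))
    assert aspect_ratio(e) == pytest.approx(expected)
    assert aspect_ratio(e) >= 1.0


@pytest.mark.parametrize(
    "ratio, expected", [(1.83, True), (1.5, False), (1.0, False)]
)
def test_is_elongated_strict_threshold(ratio, expected):
    e = Ellipsoid(
        center=np.zeros(3), axes=np.eye(3), lengths=np.array([ratio, 1.0, 1.0])
    )
    assert is_elongated(e) is expected


def test_orientation_reliability_flag():
    near_oblate = Ellipsoid(
        center=np.zeros(3), axes=np.eye(3), lengths=np.array([1.01, 1.0, 0.5])
    )
    prolate = Ellipsoid(
        center=np.zeros(3), axes=np.eye(3), lengths=np.array([2.0, 1.0, 1.0])
    )
    assert not orientation_reliable(near_oblate)
    assert orientation_reliable(prolate)


def test_annotation_roundtrip_exact():
    """Noiseless tri-view annotations refit to the generating ellipsoid."""
    rng = np.random.default_rng(5)
    R = random_rotation(rng)
    truth = Ellipsoid(
        center=np.array([12.0, 7.0, -3.0]), axes=R, lengths=np.array([6.0, 4.5, 3.0])
    )
    ann = sample_annotations(truth, points_per_view=5, jitter_sd_um=0.0, seed=6)
    assert len(ann.points) == 15
    np.testing.assert_allclose(truth.implicit(ann.points), 0.0, atol=1e-9)
    e = fit_ellipsoid(ann)
    np.testing.assert_allclose(e.center, truth.center, atol=1e-6)
    np.testing.assert_allclose(e.lengths, truth.lengths, atol=1e-6)


def test_noise_robust_long_axis_recovery():
    """With 2%-of-L3 point jitter the median long-axis error over 200
    elongated nuclei stays below 5 degrees."""
    rng = np.random.default_rng(7)
    errors = []
    for i in range(200):
        R = random_rotation(rng)
        ratio = rng.uniform(1.5, 3.0)
        l3 = 4.0
        truth = Ellipsoid(
            center=rng.uniform(-50, 50, 3),
            axes=R,
            lengths=np.array([ratio * l3, math.sqrt(ratio) * l3, l3]),
        )
        ann = sample_annotations(
            truth, points_per_view=5, jitter_sd_um=0.02 * l3, seed=rng
        )
        e = fit_ellipsoid(ann)
        errors.append(angle_to_normal(e.e1, truth.e1))
    assert np.median(errors) < 5.0


def test_annotation_set_view_tags():
    with pytest.raises(DegenerateInputError):
        AnnotationSet(nucleus_id="n", points=np.zeros((3, 3)), views=["xy"])
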