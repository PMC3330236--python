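"""Perimeter and strain: exact identities, invariances, phantom round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselastica import (ContourSeries, ValidationError, VesselPhantomSpec,
                          circumferential_length, generate_phantom,
                          strain_series)
from vesselastica.kinematics import fourier_smooth_contour, resample_closed_contour

from conftest import circle_contour


def test_unit_square_perimeter_is_four():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    assert circumferential_length(square) == pytest.approx(4.0, abs=0.0)


def test_regular_360gon_matches_circle_perimeter():
    contour = circle_contour(4.0, n=360)
    assert circumferential_length(contour) == pytest.approx(2 * np.pi * 4.0, rel=1e-4)


def test_perimeter_scales_homogeneously():
    contour = circle_contour(2.5, n=32)
    assert circumferential_length(1.1 * contour) == pytest.approx(
        1.1 * circumferential_length(contour), rel=1e-14)


def test_perimeter_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        circumferential_length(np.array([[0.0, 0.0], [1.0, 1.0]]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-50, 50), dy=st.floats(-50, 50),
       n=st.integers(8, 40))
def test_perimeter_invariant_under_rigid_motion(angle, dx, dy, n):
    rng = np.random.default_rng(n)
    contour = circle_contour(3.0, n=n) * (1 + 0.1 * rng.standard_normal((n, 1)))
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    moved = contour @ rot.T + [dx, dy]
    assert circumferential_length(moved) == pytest.approx(
        circumferential_length(contour), rel=1e-9)


def test_resampling_preserves_vertices_on_boundary():
    square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
    res = resample_closed_contour(square, 8)
    assert res.shape == (8, 2)
    # all resampled points lie on the square's boundary
    on_edge = (np.isclose(res, 0) | np.isclose(res, 2)).any(axis=1)
    assert on_edge.all()


def test_fourier_smoothing_recovers_circle_from_noisy_polygon():
    rng = np.random.default_rng(0)
    noisy = circle_contour(4.0, n=64) * (1 + 0.02 * rng.standard_normal((64, 1)))
    smooth = fourier_smooth_contour(noisy, n_harmonics=4)
    radii = np.hypot(smooth[:, 0], smooth[:, 1])
    assert np.std(radii) < np.std(np.hypot(noisy[:, 0], noisy[:, 1]))
    assert circumferential_length(smooth) == pytest.approx(2 * np.pi * 4.0, rel=0.01)


def test_identical_frames_give_zero_strain():
    contour = circle_contour(3.0, n=16)
    series = ContourSeries(timestamps=[0.0, 0.1, 0.2],
                           contours=[contour, contour.copy(), contour.copy()])
    strain = strain_series(series)
    np.testing.assert_array_equal(strain.strains, 0.0)


def test_doubled_perimeter_gives_unit_strain():
    contour = circle_contour(2.0, n=16)
    series = ContourSeries(timestamps=[0.0, 0.1], contours=[contour, 2.0 * contour])
    strain = strain_series(series, reference="first-frame")
    assert strain.strains[0] == 0.0
    assert strain.strains[1] == pytest.approx(1.0, rel=1e-12)


def test_strain_invariant_under_common_rescaling():
    rng = np.random.default_rng(1)
    base = circle_contour(3.0, n=32) * (1 + 0.05 * rng.standard_normal((32, 1)))
    series = ContourSeries(timestamps=[0.0, 0.1], contours=[base, 1.07 * base])
    scaled = ContourSeries(timestamps=[0.0, 0.1], contours=[3 * base, 3 * 1.07 * base])
    np.testing.assert_allclose(strain_series(series).strains,
                               strain_series(scaled).strains, rtol=1e-12)


def test_circular_strain_equals_diameter_strain():
    """For circles, perimeter strain and radius strain coincide exactly."""
    r0, r1 = 3.0, 3.21
    series = ContourSeries(timestamps=[0.0, 0.1],
                           contours=[circle_contour(r0, 64), circle_contour(r1, 64)])
    strain = strain_series(series)
    assert strain.strains[1] == pytest.approx((r1 - r0) / r0, abs=1e-9)


def test_phantom_strain_matches_generating_radius_trace():
    spec = VesselPhantomSpec(n_frames=40, frame_rate=20.0, seed=5)
    contours, pressure, truth = generate_phantom(spec)
    strain = strain_series(contours, reference="min-pressure-frame", pressure=pressure)
    r = truth["radii"]
    expected = (r - r[strain.reference_index]) / r[strain.reference_index]
    np.testing.assert_allclose(strain.strains, expected, atol=1e-12)
    assert strain.strains.max() == pytest.approx(truth["strain_max"], abs=1e-9)


def test_min_pressure_reference_requires_pressure():
    contour = circle_contour(3.0, n=16)
    series = ContourSeries(timestamps=[0.0, 0.1], contours=[contour, contour * 1.1])
    with pytest.raises(ValidationError, match="pressure"):
        strain_series(series, reference="min-pressure-frame")


def test_contour_series_validation():
    contour = circle_contour(3.0, n=16)
    with pytest.raises(ValidationError, match="timestamps"):
        ContourSeries(timestamps=[0.0], contours=[contour])
    with pytest.raises(ValidationError, match="vertices"):
        ContourSeries(timestamps=[0.0, 0.1], contours=[contour[:5], contour[:5]])
    bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]] * 2, dtype=float) \
        + np.arange(8)[:, None] * 1e-6
    with pytest.raises(ValidationError):
        ContourSeries(timestamps=[0.0, 0.1], contours=[bowtie, bowtie])
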