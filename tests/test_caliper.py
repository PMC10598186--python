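import numpy as np
import pytest

import airquant as aq
from airquant.caliper import (
    CaliperConfig,
    extract_patch,
    fit_spline,
    measure_fwhm_ellipse,
    measure_segment,
    sampling_interval,
)
from airquant.core_io import ImageVolume
from conftest import analytic_patch


# ------------------------------------------------------- sampling interval
@pytest.mark.parametrize(
    "spacing,expected",
    [((0.8, 0.8, 1.0), 0.4), ((1.0, 1.0, 1.0), 0.5), ((0.6, 0.8, 1.25), 0.3)],
)
def test_sampling_interval_is_half_smallest_voxel(spacing, expected):
    assert sampling_interval(spacing) == pytest.approx(expected)


def test_sampling_interval_rejects_nonpositive_spacing():
    with pytest.raises(ValueError):
        sampling_interval((0.8, 0.0, 1.0))


# ---------------------------------------------------------------- splines
def test_straight_path_arc_equals_euclidean():
    path = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]])
    sp = fit_spline(path, (1, 1, 1))
    assert sp.arc_length_mm == pytest.approx(sp.euclidean_length_mm, rel=1e-6)


def test_two_point_path_is_exact_chord():
    path = np.array([[0, 0, 0], [3.0, 4.0, 0]])
    sp = fit_spline(path, (1, 1, 1))
    assert sp.euclidean_length_mm == pytest.approx(5.0)
    assert sp.arc_length_mm == pytest.approx(5.0, rel=1e-6)


def test_sinusoid_arc_length_matches_quadrature_oracle():
    """Analytic sinusoid sampled at voxel density: spline arc within 1% of
    the quadrature value on the continuous curve."""
    A, lam = 3.0, 40.0
    t = np.linspace(0, lam, 81)
    path = np.stack([A * np.sin(2 * np.pi * t / lam), np.zeros_like(t), t], axis=1)
    t_fine = np.linspace(0, lam, 20001)
    dz = np.gradient(t_fine)
    dx = np.gradient(A * np.sin(2 * np.pi * t_fine / lam))
    oracle = np.sum(np.hypot(dx, dz))
    sp = fit_spline(path, (0.5, 0.5, 0.5))
    assert sp.arc_length_mm == pytest.approx(oracle, rel=0.01)


def test_degenerate_path_rejected():
    with pytest.raises(ValueError):
        fit_spline(np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]), (1, 1, 1))


def test_tortuosity_precursor_at_least_one(narrowing_tree):
    for seg in narrowing_tree["graph"].segments():
        if seg.spline is not None:
            assert seg.spline.arc_length_mm >= seg.spline.euclidean_length_mm - 1e-9


# ---------------------------------------------------------------- patches
def _const_volume(value=-650.0, shape=(40, 40, 40), spacing=(1, 1, 1)):
    return ImageVolume(data=np.full(shape, value, np.float32), spacing=spacing)


def test_patch_constant_volume_is_constant():
    vol = _const_volume(shape=(60, 60, 60))
    patch = extract_patch(
        vol, np.array([30.0, 30, 30]), np.array([0, 0, 1.0]), 0.5, max_extent=20.0
    )
    assert np.allclose(patch.image, -650.0)
    assert patch.oob_fraction == 0.0


def test_axial_patch_matches_axial_slice():
    rng = np.random.default_rng(1)
    data = rng.normal(-500, 150, (30, 30, 30)).astype(np.float32)
    vol = ImageVolume(data=data, spacing=(1, 1, 1))
    patch = extract_patch(
        vol, np.array([15.0, 15.0, 15.0]), np.array([0, 0, 1.0]), pitch=1.0,
        max_extent=10.0,
    )
    half = patch.image.shape[0] // 2
    # tangent +z: basis is (t x z fallback) -> in-plane axes map to x/y
    for di in (-2, 0, 2):
        for dj in (-2, 0, 2):
            got = patch.image[half + di, half + dj]
            world = (
                patch.centre_world + di * patch.basis[0] + dj * patch.basis[1]
            )
            idx = np.round(vol.world_to_index(world)).astype(int)
            assert got == pytest.approx(data[tuple(idx)], abs=1e-3)


def test_patch_extent_respects_cap():
    vol = _const_volume(shape=(80, 80, 80))
    patch = extract_patch(vol, np.array([40.0, 40, 40]), np.array([0, 0, 1.0]), 0.5)
    assert patch.extent_mm <= 40.0


def test_patch_centre_outside_volume_errors():
    vol = _const_volume()
    with pytest.raises(ValueError):
        extract_patch(vol, np.array([100.0, 0, 0]), np.array([0, 0, 1.0]), 0.5)


# ------------------------------------------------------------ FWHM ellipse
def test_circular_lumen_diameter_recovered():
    patch = analytic_patch(r_u=3.0, sigma=0.5, pitch=0.3)
    fit = measure_fwhm_ellipse(patch)
    assert fit.valid
    assert fit.diameter_mm == pytest.approx(6.0, abs=max(0.5 * 0.3, 0.03 * 6.0))


def test_elliptical_lumen_geometric_mean_diameter():
    patch = analytic_patch(r_u=2.0, r_v=4.5, sigma=0.5, pitch=0.3)
    fit = measure_fwhm_ellipse(patch)
    truth = 2.0 * np.sqrt(2.0 * 4.5)
    assert fit.valid
    assert fit.diameter_mm == pytest.approx(truth, rel=0.03)
    assert fit.minor_radius_mm == pytest.approx(2.0, rel=0.1)
    assert fit.major_radius_mm == pytest.approx(4.5, rel=0.1)


def test_flat_patch_is_rejected():
    from airquant.caliper import PerpendicularPatch

    img = np.full((101, 101), -900.0, np.float32)
    patch = PerpendicularPatch(
        image=img, pitch_mm=0.4, centre_index=(50.0, 50.0),
        centre_world=np.zeros(3), basis=(np.eye(3)[0], np.eye(3)[1]),
        oob_fraction=0.0,
    )
    fit = measure_fwhm_ellipse(patch)
    assert not fit.valid


def test_diameter_invariant_to_patch_rotation():
    """Rotating the in-plane basis by 90 degrees (image transpose) changes
    the measured diameter by < 1%."""
    patch = analytic_patch(r_u=2.0, r_v=4.5, sigma=0.5, pitch=0.3)
    from dataclasses import replace

    rotated = replace(patch, image=np.ascontiguousarray(patch.image.T))
    d0 = measure_fwhm_ellipse(patch).diameter_mm
    d90 = measure_fwhm_ellipse(rotated).diameter_mm
    assert d90 == pytest.approx(d0, rel=0.01)


def test_nested_lumens_measure_monotonically():
    prev = 0.0
    for r in (1.5, 2.5, 3.5, 5.0):
        fit = measure_fwhm_ellipse(analytic_patch(r_u=r, sigma=0.5, pitch=0.3))
        assert fit.valid and fit.diameter_mm > prev
        prev = fit.diameter_mm


# --------------------------------------------------------- whole segments
def test_straight_tube_segment_measurement(tube_case, tube_graph):
    vol = tube_case["volume"]
    seg = tube_graph.segments()[0]
    aq.measure_graph(vol, tube_graph)
    m = seg.measurement
    assert m.valid
    truth_d = tube_case["truth"].mean_diameter_mm.iloc[0]
    tol = max(0.5 * min(vol.spacing), 0.05 * truth_d)
    assert m.mean_diameter_mm == pytest.approx(truth_d, abs=tol)


def test_tapering_cone_matches_arc_weighted_mean_radius():
    spec = aq.single_tube_spec(
        radius_mm=4.0, radius_distal_mm=2.0, length_mm=50.0, spacing=(0.6, 0.6, 0.7)
    )
    vol, mask, truth = aq.rasterize(spec)
    g = aq.build_airway_graph(mask)
    aq.measure_graph(vol, g)
    seg = g.segments()[0]
    # oracle: analytic mean diameter over the measured arc span
    b = spec.branches[0]
    assert seg.measurement.valid
    # the measured span is trimmed at both ends; compare against the
    # analytic mean over the central portion
    t = np.linspace(0.15, 0.85, 2001)
    oracle = float(2 * b.radius(t).mean())
    assert seg.measurement.mean_diameter_mm == pytest.approx(oracle, rel=0.05)


def test_segment_leaving_volume_flags_invalid_samples():
    spec = aq.single_tube_spec(radius_mm=3.0, length_mm=50.0, spacing=(0.6, 0.6, 0.7))
    vol, mask, truth = aq.rasterize(spec)
    # crop the volume in z so part of the tube pokes out of the grid
    cropped = ImageVolume(
        data=vol.data[:, :, : vol.shape[2] // 2].copy(),
        spacing=vol.spacing,
        origin=vol.origin,
    )
    g = aq.build_airway_graph(mask)
    seg = g.segments()[0]
    sp = fit_spline(g.path_world(seg), g.spacing)
    m = measure_segment(cropped, sp)
    assert any(not f.valid for f in m.fits)
    valid_d = [f.diameter_mm for f in m.fits if f.valid]
    if m.valid:
        assert m.mean_diameter_mm == pytest.approx(np.mean(valid_d))


def test_refinement_reduces_diameter_error():
    """Halving the voxel size of the same phantom does not increase the
    absolute diameter error."""
    errs = []
    for sp in (1.2, 0.6):
        spec = aq.single_tube_spec(radius_mm=3.0, length_mm=40.0, spacing=(sp, sp, sp))
        vol, mask, truth = aq.rasterize(spec)
        g = aq.build_airway_graph(mask)
        aq.measure_graph(vol, g)
        errs.append(abs(g.segments()[0].measurement.mean_diameter_mm - 6.0))
    assert errs[1] <= errs[0] + 1e-6
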