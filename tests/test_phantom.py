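import numpy as np
import pytest

import airquant as aq
from airquant.phantom import PhantomBranch, PhantomSpec, standard_cohort


def test_cylinder_truth_is_analytic():
    spec = aq.single_tube_spec(radius_mm=3.0, length_mm=50.0)
    truth = spec.truth_table()
    assert truth.mean_diameter_mm.iloc[0] == pytest.approx(6.0)
    assert truth.tortuosity.iloc[0] == pytest.approx(1.0)
    assert truth.euclidean_length_mm.iloc[0] == pytest.approx(50.0)


def test_sinusoid_truth_matches_quadrature_and_exceeds_one():
    spec = aq.single_tube_spec(radius_mm=3.0, length_mm=30.0, amplitude_mm=2.0, cycles=1)
    b = spec.branches[0]
    t = np.linspace(0, 1, 200001)
    pts = b.centreline(t)
    oracle = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() / b.chord_length
    truth = spec.truth_table()
    assert truth.tortuosity.iloc[0] == pytest.approx(oracle, abs=1e-5)
    assert truth.tortuosity.iloc[0] > 1.0


def test_two_generation_truth_tapering_is_25pct():
    spec = aq.y_tree_spec(radius_mm=4.0, child_ratio=0.75)
    truth = spec.truth_table().set_index("branch_id")
    assert np.isnan(truth.loc[0, "tapering_vs_parent_pct"])
    assert truth.loc[1, "tapering_vs_parent_pct"] == pytest.approx(25.0)
    assert truth.loc[2, "tapering_vs_parent_pct"] == pytest.approx(25.0)


def test_truth_arc_at_least_euclidean(narrowing_tree):
    truth = narrowing_tree["truth"]
    assert (truth.arc_length_mm >= truth.euclidean_length_mm - 1e-9).all()
    assert len(truth) == len(narrowing_tree["spec"].branches)


def test_rasterize_same_seed_bit_identical():
    spec = aq.single_tube_spec(radius_mm=2.5, length_mm=25.0, noise_sigma_hu=10.0, seed=7)
    v1, m1, _ = aq.rasterize(spec)
    v2, m2, _ = aq.rasterize(spec)
    np.testing.assert_array_equal(v1.data, v2.data)
    np.testing.assert_array_equal(m1.data, m2.data)


def test_mask_volume_scales_quadratically_with_radius():
    counts = {}
    for r in (2.0, 4.0):
        spec = aq.single_tube_spec(radius_mm=r, length_mm=30.0)
        _, mask, _ = aq.rasterize(spec)
        counts[r] = int(mask.data.sum())
    assert counts[4.0] / counts[2.0] == pytest.approx(4.0, rel=0.10)


def test_wall_halfmax_sits_on_lumen_boundary():
    """The rendered radial profile crosses (peak+lumen)/2 at the lumen radius."""
    spec = aq.single_tube_spec(radius_mm=4.0, length_mm=30.0, spacing=(0.4, 0.4, 0.4))
    vol, mask, _ = aq.rasterize(spec)
    b = spec.branches[0]
    centre = b.centreline(np.array([0.5]))[0]
    idx = np.round(vol.world_to_index(centre)).astype(int)
    profile = vol.data[idx[0] :, idx[1], idx[2]]
    r_mm = np.arange(len(profile)) * 0.4
    peak_i = int(np.argmax(profile))
    half = (profile[peak_i] + profile[0]) / 2.0
    crossings = np.where(np.diff(np.sign(profile[: peak_i + 1] - half)))[0]
    r_half = r_mm[crossings[0]]
    assert r_half == pytest.approx(4.0, abs=0.5)


def test_overlapping_unrelated_branches_rejected():
    branches = [
        PhantomBranch(0, None, (0, 0, 60), (0, 0, 30), 3, 3),
        PhantomBranch(1, 0, (0, 0, 30), (20, 0, 15), 2, 2),
        PhantomBranch(2, 0, (0, 0, 30), (-20, 0, 15), 2, 2),
        # grandchild curling back into its uncle
        PhantomBranch(3, 1, (20, 0, 15), (-18, 0, 14), 2, 2),
    ]
    spec = PhantomSpec(branches=branches)
    with pytest.raises(ValueError, match="overlap"):
        aq.rasterize(spec)


def test_branch_exiting_grid_rejected():
    spec = aq.single_tube_spec(radius_mm=3.0, length_mm=30.0)
    spec.shape = (10, 10, 10)
    spec.origin = (0.0, 0.0, 0.0)
    with pytest.raises(ValueError, match="exits the grid"):
        aq.rasterize(spec)


def test_child_start_must_touch_parent_end():
    with pytest.raises(ValueError, match="start"):
        PhantomSpec(
            branches=[
                PhantomBranch(0, None, (0, 0, 50), (0, 0, 20), 3, 3),
                PhantomBranch(1, 0, (5, 5, 20), (10, 5, 5), 2, 2),
            ]
        )


def test_spec_json_roundtrip(tmp_path):
    spec = aq.y_tree_spec()
    spec.to_json(tmp_path / "spec.json")
    back = PhantomSpec.from_json(tmp_path / "spec.json")
    assert len(back.branches) == len(spec.branches)
    assert back.spacing == spec.spacing
    np.testing.assert_allclose(back.branches[1].end, spec.branches[1].end)


def test_cohort_is_deterministic_and_distinct():
    c1 = standard_cohort(3, seed=11, max_generation=3)
    c2 = standard_cohort(3, seed=11, max_generation=3)
    tapers1 = [c["taper_fraction"] for c in c1]
    assert tapers1 == [c["taper_fraction"] for c in c2]
    assert len(set(tapers1)) == 3
    t1 = c1[0]["spec"].truth_table()
    t2 = c2[0]["spec"].truth_table()
    assert t1.equals(t2)


def test_cohort_truth_matches_requested_parameters():
    """Recompute per-case taper from the truth table: it must equal the
    sampled taper fraction exactly (radii are constructed from it)."""
    for case in standard_cohort(3, seed=5, max_generation=3):
        truth = case["spec"].truth_table()
        child = truth[truth.parent_id >= 0]
        got = child.tapering_vs_parent_pct.median()
        assert got == pytest.approx(100 * case["taper_fraction"], abs=1e-6)
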