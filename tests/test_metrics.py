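import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import airquant as aq
from airquant.anatomy import assign_generations, classify_lobes
from airquant.metrics import (
    export_survival_table,
    intersegmental_tapering,
    summarize_patient,
    tortuosity,
)
from conftest import attach_measurement, make_graph, straight_path


# ------------------------------------------------------------- arithmetic
@pytest.mark.parametrize(
    "d_p,d,expected",
    [(5.0, 5.0, 0.0), (10.0, 7.0, 30.0), (8.0, 9.0, -12.5)],
)
def test_tapering_values(d_p, d, expected):
    assert intersegmental_tapering(d_p, d) == pytest.approx(expected)


def test_tapering_rejects_nonpositive_diameters():
    with pytest.raises(ValueError):
        intersegmental_tapering(0.0, 5.0)
    with pytest.raises(ValueError):
        intersegmental_tapering(5.0, -1.0)


@pytest.mark.parametrize("la,le,expected", [(10.0, 10.0, 1.0), (12.0, 10.0, 1.2)])
def test_tortuosity_values(la, le, expected):
    assert tortuosity(la, le) == pytest.approx(expected)


def test_tortuosity_clips_marginal_and_rejects_bad_lengths():
    assert tortuosity(9.9999999, 10.0) == 1.0
    with pytest.raises(ValueError):
        tortuosity(10.0, 0.0)
    with pytest.raises(ValueError):
        tortuosity(8.0, 10.0)


def test_half_sine_arc_tortuosity_matches_quadrature():
    """Half sine arc x = A sin(pi z / L): ratio against numeric quadrature."""
    A, L = 4.0, 30.0
    z = np.linspace(0, L, 50001)
    x = A * np.sin(np.pi * z / L)
    la = np.sum(np.hypot(np.diff(x), np.diff(z)))
    assert tortuosity(la, L) == pytest.approx(la / L, abs=1e-9)
    assert tortuosity(la, L) > 1.0


@settings(max_examples=60, deadline=None)
@given(
    d_p=st.floats(0.5, 20),
    scale=st.floats(0.1, 10),
    ratio=st.floats(0.2, 1.5),
)
def test_tapering_is_scale_invariant(d_p, scale, ratio):
    d = d_p * ratio
    assert intersegmental_tapering(d_p * scale, d * scale) == pytest.approx(
        intersegmental_tapering(d_p, d), rel=1e-9, abs=1e-9
    )


# ------------------------------------------------------- patient summaries
def _measured_tree(diams: dict[int, float]):
    """Trachea -> two mains -> four lobar children, straight paths."""
    paths = {
        (0, 1): straight_path((20, 20, 40), (20, 20, 30)),
        (1, 2): straight_path((20, 20, 30), (28, 20, 24)),
        (1, 3): straight_path((20, 20, 30), (12, 20, 24)),
        (2, 4): straight_path((28, 20, 24), (32, 20, 30)),
        (2, 5): straight_path((28, 20, 24), (32, 20, 16)),
        (3, 6): straight_path((12, 20, 24), (8, 20, 30)),
        (3, 7): straight_path((12, 20, 24), (8, 20, 16)),
    }
    g = make_graph(paths, root=0)
    assign_generations(g)
    classify_lobes(g)
    attach_measurement(g, diams)
    return g


def test_median_of_three_window_values():
    # gen-2 segments get taperings {10, 20, 60} against their gen-1 parents
    g = _measured_tree({0: 10.0, 1: 8.0, 2: 8.0, 3: 7.2, 4: 3.2, 5: 6.4, 6: 6.4})
    summ = summarize_patient(g, gen_lo=2, gen_hi=6)
    assert summ.valid
    assert summ.median_intersegmental_tapering_pct == pytest.approx(20.0)


def test_straight_synthetic_tree_median_tortuosity_is_one():
    g = _measured_tree({i: 5.0 for i in range(7)})
    summ = summarize_patient(g)
    assert summ.median_tortuosity == pytest.approx(1.0, abs=1e-3)


def test_summary_counts_all_segments_but_medians_only_window():
    g = _measured_tree({i: 5.0 for i in range(7)})
    summ = summarize_patient(g, gen_lo=2, gen_hi=6)
    assert summ.total_segment_count == 7
    assert summ.n_window_segments == 4


def test_summary_invalid_when_no_valid_window_segments():
    g = _measured_tree({0: 10.0, 1: 8.0, 2: 8.0})  # no gen-2 diameters
    summ = summarize_patient(g, gen_lo=2, gen_hi=6)
    assert not summ.valid


def test_even_count_median_uses_midpoint():
    g = _measured_tree({0: 10.0, 1: 10.0, 2: 10.0, 3: 9.0, 4: 8.0, 5: 7.0, 6: 6.0})
    # taperings for gen-2: {10, 20, (9->)} parents differ; compute directly
    summ = summarize_patient(g)
    rows = aq.compute_segment_metrics(g)
    window = sorted(
        r.intersegmental_tapering_pct
        for r in rows
        if r.generation == 2 and np.isfinite(r.intersegmental_tapering_pct)
    )
    assert summ.median_intersegmental_tapering_pct == pytest.approx(
        (window[1] + window[2]) / 2
    )


def test_phantom_tree_median_tapering_recovers_truth(narrowing_tree):
    summ = summarize_patient(narrowing_tree["graph"])
    assert abs(summ.median_intersegmental_tapering_pct - 25.0) <= 3.0


# ------------------------------------------------------- survival export
def _summary(pid, taper=20.0, tort=1.1, count=40):
    from airquant.metrics import PatientSummary

    return PatientSummary(
        patient_id=pid,
        median_intersegmental_tapering_pct=taper,
        median_tortuosity=tort,
        total_segment_count=count,
        n_window_segments=10,
        n_valid_window_segments=10,
        gen_lo=2,
        gen_hi=6,
        valid=True,
    )


def test_survival_table_shape_without_clinical():
    table = export_survival_table([_summary("a"), _summary("b"), _summary("c")])
    assert table.shape == (3, 4)
    assert list(table.columns)[0] == "patient_id"


def test_survival_table_joins_clinical_covariates():
    clinical = pd.DataFrame({"patient_id": ["a", "b"], "fvc_pct": [77.0, 65.0]})
    table = export_survival_table([_summary("a"), _summary("b")], clinical)
    assert "fvc_pct" in table.columns
    assert table.loc[table.patient_id == "b", "fvc_pct"].iloc[0] == 65.0


def test_survival_table_rejects_duplicate_ids():
    with pytest.raises(ValueError, match="duplicate"):
        export_survival_table([_summary("a"), _summary("a")])
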