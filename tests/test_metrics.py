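"""Overlap and surface-distance metrics, aggregation, percentage difference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcseg import (aggregate_folds, distance_metrics, evaluate_case,
                    overlap_metrics, percentage_difference)

SPACING = (3.0, 1.0, 1.0)


def _mask_from_counts(na, nb, ninter, shape=(4, 10, 10)):
    """Deterministic masks with |A|=na, |B|=nb, |A∩B|=ninter."""
    a = np.zeros(shape, bool).ravel()
    b = np.zeros(shape, bool).ravel()
    a[:na] = True
    b[na - ninter:na - ninter + nb] = True
    return a.reshape(shape), b.reshape(shape)


def test_perfect_prediction_scores():
    m = np.zeros((3, 8, 8), bool)
    m[1, 2:5, 2:5] = True
    out = evaluate_case(m, m, SPACING)
    assert out["dsc_pct"] == 100 and out["iou_pct"] == 100
    assert out["ppv_pct"] == 100 and out["sensitivity_pct"] == 100
    assert out["rve_pct"] == 0
    assert out["assd_mm"] == 0 and out["hausdorff_mm"] == 0


def test_hand_computed_overlap_example():
    a, b = _mask_from_counts(60, 100, 50)
    out = overlap_metrics(a, b)
    assert out["dsc_pct"] == pytest.approx(62.5)
    assert out["iou_pct"] == pytest.approx(100 * 50 / 110)
    assert out["ppv_pct"] == pytest.approx(100 * 50 / 60)
    assert out["sensitivity_pct"] == pytest.approx(50.0)
    assert out["rve_pct"] == pytest.approx(40.0)


def test_disjoint_masks_score_zero():
    a, b = _mask_from_counts(10, 10, 0)
    out = overlap_metrics(a, b)
    assert (out["dsc_pct"], out["iou_pct"], out["ppv_pct"],
            out["sensitivity_pct"]) == (0, 0, 0, 0)


def test_empty_mask_conventions():
    empty = np.zeros((2, 4, 4), bool)
    full = np.zeros((2, 4, 4), bool)
    full[0, 1, 1] = True
    both = overlap_metrics(empty, empty)
    assert both["dsc_pct"] == 100 and both["rve_pct"] == 0
    pred_empty = overlap_metrics(empty, full)
    assert pred_empty["dsc_pct"] == 0 and pred_empty["rve_pct"] == 100


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        overlap_metrics(np.zeros((2, 4, 4)), np.zeros((2, 4, 5)))


@given(seed=st.integers(0, 1000))
@settings(max_examples=50, deadline=None)
def test_dsc_iou_identity_per_sample(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((3, 6, 6)) > 0.6
    b = rng.random((3, 6, 6)) > 0.6
    out = overlap_metrics(a, b)
    iou = out["iou_pct"] / 100
    assert out["dsc_pct"] / 100 == pytest.approx(2 * iou / (1 + iou))


def test_axis_permutation_invariance(rng):
    a = rng.random((4, 4, 4)) > 0.5
    b = rng.random((4, 4, 4)) > 0.5
    assert overlap_metrics(a, b) == overlap_metrics(a.transpose(2, 0, 1),
                                                    b.transpose(2, 0, 1))


# ---- distances -----------------------------------------------------------

def test_single_voxel_offset_distance():
    a = np.zeros((1, 9, 9), bool)
    b = np.zeros((1, 9, 9), bool)
    a[0, 2, 4] = True
    b[0, 5, 4] = True  # 3 voxels apart along rows at 1 mm spacing
    out = distance_metrics(a, b, SPACING)
    assert out["assd_mm"] == pytest.approx(3.0)
    assert out["hausdorff_mm"] == pytest.approx(3.0)


def test_distances_respect_anisotropic_spacing():
    a = np.zeros((5, 5, 5), bool)
    b = np.zeros((5, 5, 5), bool)
    a[1, 2, 2] = True
    b[3, 2, 2] = True  # 2 slices apart at 3 mm slice spacing
    out = distance_metrics(a, b, SPACING)
    assert out["hausdorff_mm"] == pytest.approx(6.0)


def test_symmetric_hausdorff_is_symmetric(rng):
    a = rng.random((4, 8, 8)) > 0.7
    b = rng.random((4, 8, 8)) > 0.7
    ab = distance_metrics(a, b, SPACING)
    ba = distance_metrics(b, a, SPACING)
    assert ab["hausdorff_mm"] == pytest.approx(ba["hausdorff_mm"])
    assert ab["assd_mm"] == pytest.approx(ba["assd_mm"])


def test_empty_mask_reports_nan_with_warning():
    a = np.zeros((2, 4, 4), bool)
    b = np.zeros((2, 4, 4), bool)
    b[0, 1, 1] = True
    with pytest.warns(UserWarning, match="empty"):
        out = distance_metrics(a, b, SPACING)
    assert np.isnan(out["assd_mm"]) and np.isnan(out["hausdorff_mm"])


# ---- percentage difference and aggregation -------------------------------

@pytest.mark.parametrize("frozen,full,expected", [
    (68.89, 61.75, 11.56),
    (64.95, 49.55, 31.08),
    (42.0, 42.0, 0.00),
])
def test_percentage_difference_examples(frozen, full, expected):
    assert percentage_difference(frozen, full) == pytest.approx(expected)


def test_percentage_difference_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        percentage_difference(10.0, 0.0)


def test_aggregate_single_report_has_zero_std():
    table = aggregate_folds([{"dsc_pct": 70.0}])
    assert table.loc["all", "dsc_pct_mean"] == 70.0
    assert table.loc["all", "dsc_pct_std"] == 0.0


def test_aggregate_textbook_mean_std():
    table = aggregate_folds([{"m": 1.0}, {"m": 2.0}, {"m": 3.0}])
    assert table.loc["all", "m_mean"] == pytest.approx(2.0)
    assert table.loc["all", "m_std"] == pytest.approx(1.0)  # sample std


def test_aggregate_matches_brute_force(rng):
    reports = [{"a": float(v), "b": float(w)}
               for v, w in rng.random((20, 2))]
    table = aggregate_folds(reports)
    a = np.array([r["a"] for r in reports])
    assert table.loc["all", "a_mean"] == pytest.approx(a.mean())
    assert table.loc["all", "a_std"] == pytest.approx(a.std(ddof=1))


def test_aggregate_grouped_by_fold():
    reports = [{"fold": i % 2, "dsc_pct": 50.0 + i} for i in range(6)]
    table = aggregate_folds(reports, grouping="fold")
    assert set(table.index) == {0, 1}
    assert table.loc[0, "dsc_pct_mean"] == pytest.approx(np.mean([50, 52, 54]))


def test_mean_iou_below_mean_dsc_on_varied_cases(rng):
    """Averaged IoU penalizes poor cases harder than averaged DSC."""
    reports = []
    for seed in range(10):
        r = np.random.default_rng(seed)
        a = r.random((3, 8, 8)) > 0.5
        b = r.random((3, 8, 8)) > 0.5
        reports.append(overlap_metrics(a, b))
    table = aggregate_folds(reports)
    assert table.loc["all", "iou_pct_mean"] < table.loc["all", "dsc_pct_mean"]
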