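"""Wound-coverage and invasion-index quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tissuetension.assay_quant import (
    InvasionCounts,
    WoundSeries,
    invasion_index,
    invasion_index_per_replicate,
    wound_coverage,
)


def _series(times, areas):
    return WoundSeries(np.asarray(times, float), np.asarray(areas, float))


def test_three_quarters_closed():
    """A wound shrinking from 100 to 25 area units is 75% covered."""
    df = wound_coverage(_series([0, 24], [100, 25]))
    assert df.loc[df.time_h == 24, "coverage"].iloc[0] == pytest.approx(0.75)


def test_unchanged_wound_zero_coverage():
    df = wound_coverage(_series([0, 24], [100, 100]))
    assert df.loc[df.time_h == 24, "coverage"].iloc[0] == 0.0


def test_closed_wound_full_coverage():
    df = wound_coverage(_series([0, 24, 48], [100, 40, 0]))
    assert df.loc[df.time_h == 48, "coverage"].iloc[0] == 1.0


def test_missing_t0_rejected():
    with pytest.raises(ValueError, match="t = 0"):
        _series([24, 48], [100, 50])


def test_regrowth_clipped_not_negative():
    df = wound_coverage(_series([0, 24], [100, 120]))
    assert df.loc[df.time_h == 24, "coverage"].iloc[0] == 0.0


def test_coverage_monotone_for_shrinking_wound():
    areas = [100, 80, 55, 30, 5, 0]
    df = wound_coverage(_series([0, 6, 12, 24, 36, 48], areas))
    assert (np.diff(df["coverage"]) >= 0).all()


def test_coverage_pixel_scale_invariant():
    a = wound_coverage(_series([0, 24], [100, 40]))["coverage"]
    b = wound_coverage(_series([0, 24], [100 * 4, 40 * 4]))["coverage"]
    np.testing.assert_allclose(a, b)


def test_masks_to_areas():
    m0 = np.zeros((10, 10), bool)
    m0[:, 3:7] = True
    m1 = np.zeros((10, 10), bool)
    m1[:, 4:6] = True
    series = WoundSeries.from_masks([0, 24], [m0, m1])
    df = wound_coverage(series)
    assert df.loc[df.time_h == 24, "coverage"].iloc[0] == pytest.approx(0.5)


def _counts(condition, per_rep):
    return InvasionCounts(condition=condition, counts={f"rep{i}": v for i, v in enumerate(per_rep)})


def test_control_index_is_exactly_one():
    ctrl = _counts("NT", [[10, 12, 8], [9, 11, 13]])
    assert invasion_index(ctrl, ctrl) == 1.0


def test_reported_fold_scale():
    """A 6.5x mean count gives invasion index 6.5."""
    ctrl = _counts("NT", [[10, 10, 10]])
    test = _counts("KO", [[65, 65, 65]])
    assert invasion_index(test, ctrl) == pytest.approx(6.5)


def test_zero_invasion_index():
    ctrl = _counts("NT", [[10, 10]])
    test = _counts("KO", [[0, 0]])
    assert invasion_index(test, ctrl) == 0.0


def test_empty_or_zero_control_rejected():
    test = _counts("KO", [[5, 5]])
    with pytest.raises(ValueError, match="control"):
        invasion_index(test, _counts("NT", [[0, 0]]))


def test_negative_or_fractional_counts_rejected():
    with pytest.raises(ValueError):
        _counts("NT", [[-1, 2]])
    with pytest.raises(ValueError):
        _counts("NT", [[1.5, 2.0]])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(k=st.integers(1, 50))
def test_index_scale_invariant(k):
    """Multiplying every count by the same factor leaves the index fixed."""
    ctrl = _counts("NT", [[10, 14, 8]])
    test = _counts("KO", [[20, 25, 31]])
    scaled_ctrl = _counts("NT", [[10 * k, 14 * k, 8 * k]])
    scaled_test = _counts("KO", [[20 * k, 25 * k, 31 * k]])
    assert invasion_index(scaled_test, scaled_ctrl) == pytest.approx(invasion_index(test, ctrl))


def test_index_invariant_under_replicate_permutation():
    ctrl = _counts("NT", [[10, 12], [8, 9]])
    test_a = InvasionCounts("KO", {"rep0": [30, 35], "rep1": [28, 33]})
    test_b = InvasionCounts("KO", {"rep0": [28, 33], "rep1": [30, 35]})
    assert invasion_index(test_a, ctrl) == pytest.approx(invasion_index(test_b, ctrl))


def test_per_replicate_indices():
    ctrl = InvasionCounts("NT", {"r1": [10, 10], "r2": [20, 20]})
    test = InvasionCounts("KO", {"r1": [30, 30], "r2": [40, 40]})
    df = invasion_index_per_replicate(test, ctrl)
    assert sorted(df["index"]) == [2.0, 3.0]
    assert df["mean_index"].iloc[0] == pytest.approx(2.5)


def test_from_dataframe():
    df = pd.DataFrame(
        {
            "condition": ["NT"] * 4 + ["KO"] * 4,
            "replicate": ["r1", "r1", "r2", "r2"] * 2,
            "field": [1, 2, 1, 2] * 2,
            "count": [10, 12, 9, 11, 60, 70, 66, 64],
        }
    )
    ctrl = InvasionCounts.from_dataframe(df, "NT")
    test = InvasionCounts.from_dataframe(df, "KO")
    assert invasion_index(test, ctrl) == pytest.approx(np.mean([60, 70, 66, 64]) / np.mean([10, 12, 9, 11]))
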