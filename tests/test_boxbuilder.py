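import numpy as np
import pytest

from cardiobox import (
    ANCHOR_PROBS,
    Parameter,
    Population,
    ReferenceTable,
    Strategy,
    build_all,
    build_box_limits,
    display_bounds,
)
from cardiobox.boxbuilder import (
    displayed_from_csv,
    limits_from_json,
    limits_to_csv,
    limits_to_json,
)
from cardiobox.errors import InconsistentReferenceError, InvalidInputError
from cardiobox.reference import PercentileSummary


def _summary(param, pop, *, minimum, p1, median, p99, maximum, n=100):
    """Build a summary with the five values the box builder consumes."""
    interior = np.linspace(p1, p99, 9)  # p1..p99 occupy anchor slots 1..9
    anchors = [minimum, *interior.tolist(), maximum]
    anchors[5] = median
    anchors = np.maximum.accumulate(anchors).tolist()
    return PercentileSummary(param, pop, n, tuple(anchors))


def _pair(param=Parameter.AID, *, h=(0.49, 0.56, 0.75, 1.00, 1.23), t=(0.35, 0.58, 0.80, 1.52, 2.22)):
    healthy = _summary(param, Population.HEALTHY, minimum=h[0], p1=h[1], median=h[2], p99=h[3], maximum=h[4])
    total = _summary(param, Population.TOTAL, minimum=t[0], p1=t[1], median=t[2], p99=t[3], maximum=t[4], n=400)
    return healthy, total


def test_lviddn_boundaries_match_published_grid(reference_table):
    limits = build_box_limits(
        reference_table.summary(Parameter.LVIDD, Population.HEALTHY),
        reference_table.summary(Parameter.LVIDD, Population.TOTAL),
    )
    b = limits.boundaries
    assert b[4] == pytest.approx(1.31, abs=1e-9)
    assert b[5] == pytest.approx(1.50, abs=1e-9)
    assert b[7] == pytest.approx(2.075, abs=1e-9)
    assert b[8] == pytest.approx(2.46, abs=1e-9)


def test_aidn_boundaries_match_published_grid(reference_table):
    limits = build_box_limits(
        reference_table.summary(Parameter.AID, Population.HEALTHY),
        reference_table.summary(Parameter.AID, Population.TOTAL),
    )
    b = limits.boundaries
    assert b[1] == pytest.approx(0.42, abs=1e-9)
    assert b[2] == pytest.approx(0.49, abs=1e-9)
    assert b[7] == pytest.approx(1.26, abs=1e-9)
    assert b[8] == pytest.approx(1.52, abs=1e-9)


def test_anchor_boundaries_preserved_under_both_strategies():
    healthy, total = _pair()
    for strategy in Strategy:
        b = build_box_limits(healthy, total, strategy).boundaries
        assert b[0] == total.minimum
        assert b[3] == healthy.p1
        assert b[6] == healthy.p99
        assert b[9] == total.maximum
    b = build_box_limits(healthy, total, Strategy.TABLE_CONSISTENT).boundaries
    assert b[8] == total.p99


def test_partition_covers_range_with_equal_width_regions():
    healthy, total = _pair()
    for strategy in Strategy:
        b = build_box_limits(healthy, total, strategy).boundaries
        assert all(x < y for x, y in zip(b, b[1:]))
        low_widths = np.diff(b[:4])
        norm_widths = np.diff(b[3:7])
        assert np.allclose(low_widths, low_widths[0])
        assert np.allclose(norm_widths, norm_widths[0])
        if strategy is Strategy.PROSE_EQUAL_THIRDS:
            up_widths = np.diff(b[6:])
            assert np.allclose(up_widths, up_widths[0])
        else:
            assert b[7] - b[6] == pytest.approx(b[8] - b[7])


def test_strategies_coincide_at_the_analytic_crossover():
    """When total P99 sits two thirds of the way up the upper region the
    midpoint rule and the equal-thirds rule give the same b7, b8."""
    h_p99, t_max = 1.00, 1.30
    t_p99 = (h_p99 + 2.0 * t_max) / 3.0  # solves t_p99 = h_p99 + 2 (t_max - t_p99)
    healthy, total = _pair(h=(0.49, 0.56, 0.75, h_p99, 1.23), t=(0.35, 0.58, 0.80, t_p99, t_max))
    b_table = build_box_limits(healthy, total, Strategy.TABLE_CONSISTENT).boundaries
    b_prose = build_box_limits(healthy, total, Strategy.PROSE_EQUAL_THIRDS).boundaries
    assert b_table[7] == pytest.approx(b_prose[7])
    assert b_table[8] == pytest.approx(b_prose[8])


@pytest.mark.parametrize(
    ("h", "t", "message"),
    [
        ((0.35, 0.35, 0.75, 1.00, 1.23), (0.35, 0.58, 0.80, 1.52, 2.22), "lower region"),
        ((0.49, 0.56, 0.56, 0.56, 1.23), (0.35, 0.58, 0.80, 1.52, 2.22), "normal range"),
        ((0.49, 0.56, 0.75, 2.22, 2.22), (0.35, 0.58, 0.80, 1.52, 2.22), "upper region"),
    ],
)
def test_degenerate_regions_are_hard_errors(h, t, message):
    healthy, total = _pair(h=h, t=t)
    with pytest.raises(InconsistentReferenceError, match=message):
        build_box_limits(healthy, total)


def test_table_consistent_needs_total_p99_inside_upper_region():
    healthy, total = _pair(t=(0.35, 0.58, 0.80, 0.90, 2.22))  # total P99 < healthy P99
    with pytest.raises(InconsistentReferenceError, match="total P99"):
        build_box_limits(healthy, total, Strategy.TABLE_CONSISTENT)
    # the prose rule does not involve total P99 and still works
    build_box_limits(healthy, total, Strategy.PROSE_EQUAL_THIRDS)


def test_median_offset_diagnostic(reference_table):
    limits = build_box_limits(
        reference_table.summary(Parameter.AID, Population.HEALTHY),
        reference_table.summary(Parameter.AID, Population.TOTAL),
    )
    # centre of box 5 is (b4 + b5)/2 = 0.78; healthy median is 0.75
    assert limits.median_offset == pytest.approx(0.75 - 0.78, abs=1e-9)


# ---- displayed bounds ---------------------------------------------------


def test_display_aidn_lower_region(limits_set):
    displayed = limits_set[Parameter.AID].displayed
    assert displayed[0] == (0.35, 0.41)
    assert displayed[1] == (0.42, 0.48)
    assert displayed[2] == (0.49, 0.55)


def test_display_exact_grid_boundaries():
    pairs = display_bounds(tuple(float(k) for k in range(10)), precision=0.01)
    assert pairs[0] == (0.00, 0.99)
    assert pairs[1] == (1.00, 1.99)
    assert pairs[2] == (2.00, 2.99)


def test_display_single_cell_box(limits_set):
    # PLVWDn box 7 collapses to a single grid cell
    assert limits_set[Parameter.PLVWD].displayed[6] == (0.63, 0.63)


def test_display_rejects_bad_input():
    with pytest.raises(InvalidInputError):
        display_bounds((0.1, 0.1, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0))
    with pytest.raises(InvalidInputError):
        display_bounds(tuple(float(k) for k in range(10)), precision=-0.01)


def test_displayed_pairs_are_ordered(limits_set):
    for limits in limits_set.values():
        flat = [x for pair in limits.displayed for x in pair]
        assert flat == sorted(flat)
        for lo, hi in limits.displayed:
            assert lo <= hi


# ---- build_all and serialisation ----------------------------------------


def test_build_all_empty_reference_gives_empty_map():
    assert build_all(ReferenceTable()) == {}


def test_build_all_single_parameter_equals_direct_build(reference_table):
    healthy = reference_table.summary(Parameter.IVSS, Population.HEALTHY)
    total = reference_table.summary(Parameter.IVSS, Population.TOTAL)
    single = ReferenceTable([healthy, total])
    result = build_all(single)
    assert set(result) == {Parameter.IVSS}
    assert result[Parameter.IVSS].boundaries == build_box_limits(healthy, total).boundaries


def test_limits_serialisation_round_trip(tmp_path, limits_set):
    json_path = tmp_path / "limits.json"
    limits_to_json(limits_set, json_path)
    loaded = limits_from_json(json_path)
    for param, limits in limits_set.items():
        assert loaded[param].boundaries == limits.boundaries
        assert loaded[param].displayed == limits.displayed
        assert loaded[param].strategy == limits.strategy

    csv_path = tmp_path / "limits.csv"
    limits_to_csv(limits_set, csv_path)
    displayed = displayed_from_csv(csv_path)
    for param, limits in limits_set.items():
        assert displayed[param] == limits.displayed
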