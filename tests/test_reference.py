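import math

import numpy as np
import pytest

from cardiobox import (
    ANCHOR_PROBS,
    Group,
    MeasurementRecord,
    Parameter,
    Population,
    ReferenceTable,
    build_reference_table,
    compute_percentile_summary,
)
from cardiobox.errors import (
    EmptyDataError,
    InsufficientReferenceError,
    InvalidDataError,
    InvalidSummaryError,
)
from cardiobox.reference import PercentileSummary


def quantile_oracle(values, p):
    """Brute-force interpolated order statistic (sort + linear interpolation).

    Independent of numpy's quantile routine: explicit h = p*(n-1) split.
    """
    xs = sorted(values)
    h = p * (len(xs) - 1)
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def test_constant_sample_collapses_all_anchors():
    s = compute_percentile_summary([0.5] * 100, Parameter.AID, Population.HEALTHY)
    assert all(a == 0.5 for a in s.anchors)


def test_median_of_1_to_100_is_50_5():
    s = compute_percentile_summary(range(1, 101), Parameter.AID, Population.HEALTHY)
    assert s.median == pytest.approx(50.5)
    assert s.median == pytest.approx(quantile_oracle(range(1, 101), 0.5))


def test_extremes_are_sample_min_and_max():
    rng = np.random.default_rng(7)
    values = rng.normal(size=57)
    s = compute_percentile_summary(values, Parameter.LVIDD, Population.TOTAL)
    assert s.minimum == values.min()
    assert s.maximum == values.max()


def test_agrees_with_brute_force_oracle_on_all_small_samples():
    """Exhaustive check against the independent oracle for every n <= 12."""
    rng = np.random.default_rng(42)
    for n in range(1, 13):
        values = rng.uniform(0.1, 3.0, size=n)
        s = compute_percentile_summary(values, Parameter.AID, Population.HEALTHY)
        for p, got in zip(ANCHOR_PROBS, s.anchors):
            assert got == pytest.approx(quantile_oracle(values, p), rel=1e-12), (n, p)


def test_empty_and_nan_inputs_rejected():
    with pytest.raises(EmptyDataError):
        compute_percentile_summary([], Parameter.AID, Population.HEALTHY)
    with pytest.raises(InvalidDataError):
        compute_percentile_summary([1.0, float("nan")], Parameter.AID, Population.HEALTHY)


def test_summary_rejects_non_monotone_anchors():
    with pytest.raises(InvalidSummaryError):
        PercentileSummary(
            Parameter.AID, Population.HEALTHY, 10,
            anchors=(0.1, 0.3, 0.2) + (0.4,) * 8,
        )


# ---- table construction -------------------------------------------------


def _record(i, group, aid, weight=5.0):
    return MeasurementRecord(f"s{i}", weight, group, {Parameter.AID: aid})


def test_group_bookkeeping(exponents):
    records = [
        _record(0, Group.HEALTHY, 0.6),
        _record(1, Group.HEALTHY, 0.7),
        _record(2, Group.HEALTHY, 0.8),
        _record(3, Group.CARDIAC, 1.4),
        _record(4, Group.CARDIAC, 1.8),
    ]
    table = build_reference_table(records, exponents)
    assert table.summary(Parameter.AID, Population.HEALTHY).n == 3
    assert table.summary(Parameter.AID, Population.TOTAL).n == 5


def test_all_healthy_makes_populations_identical(exponents):
    records = [_record(i, Group.HEALTHY, 0.5 + 0.1 * i) for i in range(6)]
    table = build_reference_table(records, exponents)
    healthy = table.summary(Parameter.AID, Population.HEALTHY)
    total = table.summary(Parameter.AID, Population.TOTAL)
    assert healthy.anchors == total.anchors


def test_zero_healthy_records_is_an_error(exponents):
    with pytest.raises(InsufficientReferenceError):
        build_reference_table([_record(0, Group.CARDIAC, 1.0)], exponents)


def test_permutation_invariance(exponents):
    rng = np.random.default_rng(3)
    records = [
        _record(i, Group.HEALTHY if i % 3 else Group.CARDIAC, v, weight=w)
        for i, (v, w) in enumerate(zip(rng.uniform(0.5, 2, 30), rng.uniform(2, 20, 30)))
    ]
    shuffled = [records[i] for i in rng.permutation(len(records))]
    t1 = build_reference_table(records, exponents)
    t2 = build_reference_table(shuffled, exponents)
    for pop in Population:
        assert t1.summary(Parameter.AID, pop).anchors == t2.summary(Parameter.AID, pop).anchors


def test_missing_parameters_are_skipped_per_parameter(exponents):
    records = [
        MeasurementRecord("a", 4.0, Group.HEALTHY, {Parameter.AID: 0.7, Parameter.LVIDD: 2.0}),
        MeasurementRecord("b", 6.0, Group.HEALTHY, {Parameter.AID: 0.8}),
    ]
    table = build_reference_table(records, exponents)
    assert table.summary(Parameter.AID, Population.HEALTHY).n == 2
    assert table.summary(Parameter.LVIDD, Population.HEALTHY).n == 1
    assert (Parameter.IVSS, Population.HEALTHY) not in table


def test_total_range_contains_healthy_range(exponents):
    rng = np.random.default_rng(11)
    records = [
        _record(i, Group.HEALTHY if i < 20 else Group.CARDIAC, v)
        for i, v in enumerate(rng.uniform(0.4, 2.5, 35))
    ]
    table = build_reference_table(records, exponents)
    h = table.summary(Parameter.AID, Population.HEALTHY)
    t = table.summary(Parameter.AID, Population.TOTAL)
    assert t.minimum <= h.minimum
    assert t.maximum >= h.maximum


# ---- packaged fixture and serialisation ---------------------------------


def test_packaged_reference_is_complete_and_monotone(reference_table):
    assert len(reference_table.parameters) == 7
    for param in reference_table.parameters:
        h = reference_table.summary(param, Population.HEALTHY)
        t = reference_table.summary(param, Population.TOTAL)
        assert h.n == 802 and t.n == 2967
        assert all(a <= b for a, b in zip(h.anchors, h.anchors[1:]))
        assert t.minimum <= h.minimum and t.maximum >= h.maximum


def test_packaged_healthy_aid_median(reference_table):
    s = reference_table.summary(Parameter.AID, Population.HEALTHY)
    assert s.median == 0.75
    assert s.p1 == 0.56 and s.p99 == 1.00


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_serialisation_round_trip(tmp_path, reference_table, fmt):
    path = tmp_path / f"ref.{fmt}"
    if fmt == "csv":
        reference_table.to_csv(path)
        loaded = ReferenceTable.from_csv(path)
    else:
        reference_table.to_json(path)
        loaded = ReferenceTable.from_json(path)
    for param in reference_table.parameters:
        for pop in Population:
            a = reference_table.summary(param, pop)
            b = loaded.summary(param, pop)
            assert a.anchors == b.anchors and a.n == b.n
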