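"""Annual aggregation: interpolation, sward filtering and the yield identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gqay.aggregate import (
    aggregate_annual,
    dropped_richness_histogram,
    filter_swards,
    interpolate_quality,
)


def make_cuts(sward_specs):
    """Cut table from {sward_id: (biomass list, me list)} with NaN chemistry defaults."""
    rows = []
    for sid, (biomass, me) in sward_specs.items():
        h = len(biomass)
        for c, (b, q) in enumerate(zip(biomass, me), start=1):
            rows.append({
                "sward_id": sid, "cuts_per_year": h, "cut": c, "biomass": b,
                "me": q, "nel": q / 2, "milk_potential": q / 6.4, "cp": 150.0,
                "om": 900.0, "ndf": 450.0, "ucp": 140.0 if c == 1 else np.nan,
                "richness": 4, "management": "less_intensive",
            })
    return pd.DataFrame(rows)


class TestInterpolation:
    def test_equally_spaced_series(self):
        assert interpolate_quality(12.0, 9.0, 4) == pytest.approx([12, 11, 10, 9])

    def test_flat_and_two_point_cases(self):
        assert interpolate_quality(7.0, 7.0, 3) == pytest.approx([7, 7, 7])
        assert interpolate_quality(10.0, 8.0, 2) == pytest.approx([10, 8])
        assert interpolate_quality(5.0, 5.0, 1) == pytest.approx([5.0])

    def test_rejects_zero_cuts(self):
        with pytest.raises(ValueError):
            interpolate_quality(1.0, 2.0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(q1=st.floats(-100, 100), q2=st.floats(-100, 100), h=st.integers(2, 8))
    def test_series_is_monotone_between_ordered_endpoints(self, q1, q2, h):
        series = interpolate_quality(q1, q2, h)
        assert series[0] == pytest.approx(q1)
        assert series[-1] == pytest.approx(q2)
        diffs = np.diff(series)
        assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)


class TestFilter:
    def test_missing_cut_drops_sward(self):
        cuts = make_cuts({"a": ([200, np.nan], [10, 9]), "b": ([200, 250], [10, 9])})
        kept, report = filter_swards(cuts, min_biomass=1.0)
        assert set(kept.sward_id) == {"b"}
        assert report.loc[report.sward_id == "a", "reason"].item() == "missing"

    def test_small_biomass_threshold(self):
        cuts = make_cuts({
            "a": ([200.0, 220.0], [10, 9]),
            "b": ([0.5, 300.0], [10, 9]),
            "c": ([150.0, 180.0], [10, 9]),
        })
        kept, report = filter_swards(cuts, min_biomass=1.0)
        assert set(kept.sward_id) == {"a", "c"}
        assert report.loc[report.sward_id == "b", "reason"].item() == "small_biomass"
        assert dropped_richness_histogram(report).to_dict() == {4: 1}

    def test_zero_threshold_keeps_everything(self):
        cuts = make_cuts({"a": ([0.0, 10.0], [10, 9]), "b": ([5.0, 5.0], [10, 9])})
        kept, report = filter_swards(cuts, min_biomass=0.0)
        assert report.empty and len(kept) == 4


class TestAnnual:
    def test_worked_two_cut_example(self):
        cuts = make_cuts({"a": ([200.0, 300.0], [10.0, 8.0])})
        annual = aggregate_annual(cuts)
        row = annual.iloc[0]
        assert row.biomass_yield == pytest.approx(500.0)
        assert row.quality_me == pytest.approx(8.8)
        assert row.qa_me == pytest.approx(4.4)

    def test_single_cut_collapse(self):
        cuts = make_cuts({"a": ([400.0], [9.5])})
        row = aggregate_annual(cuts).iloc[0]
        assert row.quality_me == pytest.approx(9.5)
        assert row.qa_me == pytest.approx(400 * 9.5 / 1000)

    def test_equal_biomass_gives_unweighted_mean(self):
        cuts = make_cuts({"a": ([250.0, 250.0], [10.0, 8.0])})
        assert aggregate_annual(cuts).iloc[0].quality_me == pytest.approx(9.0)

    def test_ucp_uses_first_cut_only(self):
        cuts = make_cuts({"a": ([200.0, 300.0], [10.0, 8.0])})
        row = aggregate_annual(cuts).iloc[0]
        assert row.quality_ucp == pytest.approx(140.0)
        assert row.qa_ucp == pytest.approx(200.0 * 140.0 / 1000)

    def test_unfiltered_missing_cut_is_an_internal_error(self):
        cuts = make_cuts({"a": ([200.0, np.nan], [10.0, 8.0])})
        with pytest.raises(RuntimeError, match="filter"):
            aggregate_annual(cuts)

    @settings(derandomize=True, max_examples=50)
    @given(
        biomass=st.lists(st.floats(1, 1000), min_size=1, max_size=4),
        me0=st.floats(5, 12), me1=st.floats(5, 12), k=st.floats(0.1, 10),
    )
    def test_identity_permutation_and_scaling(self, biomass, me0, me1, k):
        h = len(biomass)
        me = list(np.linspace(me0, me1, h))
        annual = aggregate_annual(make_cuts({"a": (biomass, me)}), interpolate=False)
        row = annual.iloc[0]
        # Identity: quality-adjusted yield equals total biomass x weighted quality
        assert row.qa_me == pytest.approx(
            row.biomass_yield * row.quality_me / 1000, rel=1e-12)
        # Permutation invariance of the annual sums
        perm = aggregate_annual(
            make_cuts({"a": (biomass[::-1], me[::-1])}), interpolate=False).iloc[0]
        assert perm.biomass_yield == pytest.approx(row.biomass_yield, rel=1e-12)
        assert perm.qa_me == pytest.approx(row.qa_me, rel=1e-12)
        # Scaling biomass by k scales yields by k, leaves weighted quality alone
        scaled = aggregate_annual(
            make_cuts({"a": ([k * b for b in biomass], me)}), interpolate=False).iloc[0]
        assert scaled.biomass_yield == pytest.approx(k * row.biomass_yield, rel=1e-9)
        assert scaled.qa_me == pytest.approx(k * row.qa_me, rel=1e-9)
        assert scaled.quality_me == pytest.approx(row.quality_me, rel=1e-9)
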