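"""Replicate averaging: spot statistics, outlier elimination, bookkeeping."""

import math

import numpy as np
import pytest

from glyarray import (ChannelFeatures, OutlierRule, QuantOptions, ScanResult,
                      SpotRecord, eliminate_outliers, process, spot_value)
from glyarray.geometry import ArrayGeometry, SpotAssignment


def make_spot(f_mean=500.0, f_median=480.0, b_mean=50.0, b_median=45.0,
              flags=0, block=1, row=1, column=1):
    return SpotRecord(block=block, row=row, column=column, name="s",
                      probe_key="PK",
                      channel_features={532: ChannelFeatures(
                          f_mean, f_median, b_mean, b_median)},
                      flags=flags)


def slide_from_values(values_by_probe, flags_by_probe=None):
    """One block, one row per probe, replicates along columns."""
    spots, assignments = [], []
    for r, (probe, values) in enumerate(values_by_probe.items(), start=1):
        flags = (flags_by_probe or {}).get(probe, [0] * len(values))
        for c, (v, fl) in enumerate(zip(values, flags), start=1):
            spots.append(SpotRecord(
                block=1, row=r, column=c, name=probe, probe_key=probe,
                channel_features={532: ChannelFeatures(v, v, 0.0, 0.0)},
                flags=fl))
            assignments.append(SpotAssignment(1, r, c, probe))
    scan = ScanResult(slide_id="t", channels=[532], spots=spots)
    geom = ArrayGeometry(layout_id="t", n_blocks=1,
                         spot_assignments=assignments)
    return scan, geom


class TestSpotValue:
    @pytest.mark.parametrize("statistic,expected", [
        ("mean", 500.0), ("median", 480.0),
        ("mean_minus_bg", 450.0), ("median_minus_bg", 435.0)])
    def test_four_statistics(self, statistic, expected):
        assert spot_value(make_spot(), 532, statistic) == expected

    def test_negative_background_subtraction_kept_signed(self):
        spot = make_spot(f_mean=30.0, b_mean=80.0)
        assert spot_value(spot, 532, "mean_minus_bg") == -50.0

    def test_nan_propagates(self):
        spot = make_spot(f_mean=math.nan)
        assert math.isnan(spot_value(spot, 532, "mean_minus_bg"))

    def test_unknown_channel_errors(self):
        with pytest.raises(KeyError):
            spot_value(make_spot(), 635, "mean")


class TestEliminateOutliers:
    def test_mad_zero_fallback_catches_wild_value(self):
        mask, reasons = eliminate_outliers([10, 10, 10, 1000], OutlierRule())
        assert mask == [True, True, True, False]
        assert reasons == ["", "", "", "outlier"]

    def test_zero_dispersion_survives_both_methods(self):
        for method in ("mad", "drop_min_max"):
            mask, _ = eliminate_outliers([5, 5, 5, 5],
                                         OutlierRule(method=method))
            assert mask == [True] * 4

    def test_rule_suppressed_below_min_survivors(self):
        mask, reasons = eliminate_outliers([1, 100], OutlierRule())
        assert mask == [True, True]
        assert reasons == ["rule-suppressed"] * 2

    def test_drop_min_max_removes_one_of_each(self):
        mask, _ = eliminate_outliers([1, 5, 6, 7, 100],
                                     OutlierRule(method="drop_min_max"))
        assert mask == [False, True, True, True, False]

    def test_drop_min_max_needs_four(self):
        mask, reasons = eliminate_outliers([1, 2, 100],
                                           OutlierRule(method="drop_min_max"))
        assert mask == [True] * 3 and reasons == ["rule-suppressed"] * 3

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            eliminate_outliers([], OutlierRule())


class TestProcess:
    def test_plain_mean_arithmetic(self):
        scan, geom = slide_from_values({"PK1": [100, 110, 90, 100]})
        ds = process(scan, geom, QuantOptions())
        (pi,) = ds.intensities
        assert pi.value == 100 and pi.n_used == 4 and pi.n_spots == 4
        assert pi.sd == pytest.approx(np.std([100, 110, 90, 100], ddof=1))
        assert pi.percent_cv == pytest.approx(100 * pi.sd / 100)

    def test_flagged_spot_excluded_with_bookkeeping(self):
        scan, geom = slide_from_values({"PK1": [100, 110, 90, 100, 55]},
                                       {"PK1": [0, 0, 0, 0, -100]})
        ds = process(scan, geom, QuantOptions())
        (pi,) = ds.intensities
        assert pi.n_spots == 5 and pi.n_used == 4 and pi.value == 100
        assert pi.excluded == [((1, 1, 5), "flagged")]

    def test_flag_exclusion_can_be_disabled(self):
        scan, geom = slide_from_values({"PK1": [100, 100]},
                                       {"PK1": [0, -75]})
        ds = process(scan, geom, QuantOptions(exclude_flagged=False))
        assert ds.intensities[0].n_used == 2

    def test_nan_spots_excluded_with_reason(self):
        scan, geom = slide_from_values({"PK1": [100, math.nan, 100]})
        ds = process(scan, geom, QuantOptions())
        (pi,) = ds.intensities
        assert pi.n_used == 2 and pi.excluded == [((1, 1, 2), "nan")]

    def test_outlier_elimination_equals_plain_when_nothing_excluded(self):
        scan, geom = slide_from_values({"PK1": [100, 101, 99, 100]})
        plain = process(scan, geom, QuantOptions(averaging="plain_mean"))
        elim = process(scan, geom,
                       QuantOptions(averaging="outlier_eliminated_mean"))
        assert plain.intensities[0].value == elim.intensities[0].value

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(100, 1000, size=6).tolist()
        scan1, geom = slide_from_values({"PK1": values})
        scan2, _ = slide_from_values({"PK1": values[::-1]})
        opts = QuantOptions(averaging="outlier_eliminated_mean")
        v1 = process(scan1, geom, opts).intensities[0].value
        v2 = process(scan2, geom, opts).intensities[0].value
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_group_with_no_usable_spot_goes_to_rejects(self):
        scan, geom = slide_from_values({"PK1": [100, 100], "PK2": [50, 60]},
                                       {"PK1": [-100, -100]})
        ds = process(scan, geom, QuantOptions())
        assert [pi.probe_key for pi in ds.intensities] == ["PK2"]
        (rej,) = ds.rejects
        assert rej["probe_key"] == "PK1" and len(rej["excluded"]) == 2

    def test_every_spot_accounted_exactly_once(self, small_slide):
        opts = QuantOptions(spot_statistic="mean_minus_bg",
                            averaging="outlier_eliminated_mean")
        ds = process(small_slide.scan, small_slide.geometry, opts,
                     analyte_ref="acct")
        used = sum(pi.n_used for pi in ds.intensities)
        excluded = sum(len(pi.excluded) for pi in ds.intensities)
        rejected = sum(len(r["excluded"]) for r in ds.rejects)
        n_probe_spots = sum(
            1 for a in small_slide.geometry.spot_assignments
            if a.probe_key != "EMPTY")
        assert used + excluded + rejected == n_probe_spots

    def test_matches_direct_group_means(self, small_slide):
        """With no flags/NaN and no outlier rule, process == plain group mean."""
        ds = process(small_slide.scan, small_slide.geometry,
                     QuantOptions(spot_statistic="mean"))
        by_probe = {}
        for spot, a in zip(small_slide.scan.spots,
                           small_slide.geometry.spot_assignments):
            if a.probe_key != "EMPTY":
                by_probe.setdefault(a.probe_key, []).append(
                    spot.channel_features[532].f_mean)
        for pi in ds.intensities:
            assert pi.value == pytest.approx(
                float(np.mean(by_probe[pi.probe_key])), rel=1e-12)

    def test_zero_mean_group_has_undefined_cv(self):
        scan, geom = slide_from_values({"PK1": [-10.0, 10.0]})
        ds = process(scan, geom, QuantOptions())
        assert ds.intensities[0].percent_cv == "undefined"


# ---------------------------------------------------------------------------
# property: outlier elimination invariants

from hypothesis import given, settings, strategies as st


@settings(max_examples=150, derandomize=True)
@given(values=st.lists(st.floats(min_value=0, max_value=1e5,
                                 allow_nan=False, allow_infinity=False),
                       min_size=1, max_size=12),
       method=st.sampled_from(["mad", "drop_min_max"]))
def test_outlier_rule_invariants(values, method):
    """Survivor count never drops below min_survivors; mask aligns with
    reasons; survivors are always a sub-multiset of the input."""
    rule = OutlierRule(method=method)
    mask, reasons = eliminate_outliers(values, rule)
    assert len(mask) == len(reasons) == len(values)
    assert sum(mask) >= min(rule.min_survivors, len(values))
    assert all((m and r in ("", "rule-suppressed")) or (not m and r == "outlier")
               for m, r in zip(mask, reasons))
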