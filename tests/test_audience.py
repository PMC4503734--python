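import datetime as dt

import numpy as np
import pytest
import shapely
from shapely.geometry import box

from babblercalls import audience
from babblercalls.audience import (
    BANDS,
    EXPECTED_PROPORTIONS,
    band_counts,
    border_stat,
    border_stat_from_inclusion,
    buffer_polygon,
    classify_band,
    dedupe_locations,
    expected_band_counts,
    filter_eligible_callers,
    inclusion_area,
    paired_border_tables,
    weight_cost_pairs,
)
from babblercalls.core_io import WeightSession
from babblercalls.locoh import Territory
from babblercalls.pedigree import NeighbourProfile

from conftest import make_calls


def square_terr(gid, cx, size95):
    """Concentric square isopleths centred at (cx, 0)."""
    isopleths = {
        0.50: box(cx - size95 / 4, -size95 / 4, cx + size95 / 4, size95 / 4),
        0.75: box(cx - size95 / 3, -size95 / 3, cx + size95 / 3, size95 / 3),
        0.95: box(cx - size95 / 2, -size95 / 2, cx + size95 / 2, size95 / 2),
    }
    return Territory(gid, "t", isopleths, {q: g.area / 1e4 for q, g in isopleths.items()}, 1.0, 100)


class TestDedupe:
    def test_repeated_point_collapses(self):
        calls = make_calls([(10, 10)] * 5)
        (loc,) = dedupe_locations(calls)
        assert loc.n_calls == 5

    def test_distinct_points_stay_distinct(self):
        assert len(dedupe_locations(make_calls([(0, 0), (10, 0), (20, 0)]))) == 3

    def test_sub_metre_jitter_merges_under_rounding(self):
        calls = make_calls([(100.0, 200.0), (100.4, 200.3)])
        assert len(dedupe_locations(calls, round_m=1.0)) == 1

    def test_total_calls_preserved(self):
        calls = make_calls([(0, 0), (0.2, 0.1), (50, 50), (80, 80), (80.3, 79.9)])
        locs = dedupe_locations(calls)
        assert sum(l.n_calls for l in locs) == len(calls)


class TestEligibility:
    @pytest.mark.parametrize("n,included", [(9, False), (10, True), (11, True)])
    def test_minimum_call_boundary(self, n, included):
        calls = make_calls([(0, 0)] * n)
        assert ("C1" in filter_eligible_callers(calls)) is included

    def test_empty(self):
        assert filter_eligible_callers([]) == set()


class TestBands:
    def test_innermost_band_wins(self, square_territory):
        assert classify_band((0, 0), square_territory) == "core50"
        assert classify_band((75, 0), square_territory) == "band50_75"
        assert classify_band((150, 0), square_territory) == "band75_95"
        assert classify_band((500, 0), square_territory) == "outside95"

    def test_boundary_points_are_inside(self, square_territory):
        assert classify_band((50, 0), square_territory) == "core50"
        assert classify_band((200, 0), square_territory) == "band75_95"

    def test_expected_counts_for_forty_calls(self):
        assert expected_band_counts(40) == {
            "core50": 20.0,
            "band50_75": 10.0,
            "band75_95": 8.0,
        }
        assert expected_band_counts(0) == {b: 0.0 for b in EXPECTED_PROPORTIONS}

    def test_expected_shares_are_unnormalised(self):
        assert sum(EXPECTED_PROPORTIONS.values()) == pytest.approx(0.95)

    def test_band_counts_sum_to_total(self, square_territory):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-300, 300, (57, 2))
        bc = band_counts(pts, square_territory)
        assert bc.total == 57
        assert sum(bc.expected.values()) == pytest.approx(0.95 * 57)


class TestBuffers:
    def test_zero_distance_is_identity(self):
        sq = box(0, 0, 100, 100)
        assert buffer_polygon(sq, 0.0).equals(sq)

    def test_convex_square_closed_form(self):
        # Minkowski sum area: A + P*d + pi*d^2
        sq = box(0, 0, 100, 100)
        d = 100.0
        expected = 10_000 + 400 * d + np.pi * d**2
        assert buffer_polygon(sq, d).area == pytest.approx(expected, rel=1e-3)

    def test_contains_original_vertices(self):
        sq = box(0, 0, 100, 100)
        buffered = buffer_polygon(sq, 37.0)
        assert buffered.contains(sq)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            buffer_polygon(box(0, 0, 1, 1), -1.0)


class TestInclusionArea:
    def test_far_apart_is_empty(self):
        a, b = box(0, 0, 100, 100), box(500, 0, 600, 100)
        assert inclusion_area(a, b, 100.0).area == 0.0

    def test_abutting_km_squares_strip(self):
        focal = box(0, 0, 1000, 1000)
        neighbour = box(1000, 0, 2000, 1000)
        inc = inclusion_area(focal, neighbour, 100.0)
        assert inc.area / 1e4 == pytest.approx(10.0, rel=1e-3)  # 100 m x 1 km strip

    def test_bounded_by_focal(self):
        focal = box(0, 0, 300, 300)
        neighbour = box(200, 0, 600, 300)
        assert inclusion_area(focal, neighbour, 100.0).area <= focal.area + 1e-9


class TestBorderStat:
    def test_expected_formula_arithmetic(self):
        # 30 calls, focal 60 ha, inclusion 12 ha -> expected 6
        focal = square_terr("F", 0, np.sqrt(60e4))  # 95% square of 60 ha
        calls = make_calls([(0, 0)] * 30)
        inc = box(0, 0, 300, 400)  # 12 ha
        s = border_stat_from_inclusion(calls, 60.0, inc, "N")
        assert s.expected_calls == pytest.approx(6.0)

    def test_expected_saturates_at_total(self):
        focal = square_terr("F", 0, 1000)
        neighbour = square_terr("N", 0, 3000)  # buffer swallows the focal territory
        calls = make_calls([(0, 0)] * 20)
        s = border_stat(calls, focal, neighbour, distance=100.0)
        assert s.expected_calls == pytest.approx(20.0, rel=1e-6)
        assert s.observed_calls == 20

    def test_uniform_calls_match_expectation_binomially(self):
        """Uniformly placed calls: observed close to area-proportional expected."""
        rng = np.random.default_rng(11)
        focal = square_terr("F", 0, 1000)  # 100 ha
        neighbour = square_terr("N", 1000, 1000)
        n = 400
        pts = rng.uniform(-500, 500, (n, 2))
        calls = make_calls(pts)
        s = border_stat(calls, focal, neighbour, distance=100.0)
        p = s.inclusion_area_ha / 100.0
        sd = np.sqrt(n * p * (1 - p))
        assert abs(s.observed_calls - s.expected_calls) < 4 * sd

    def test_rates_are_observed_over_area(self):
        calls = make_calls([(50, 50)] * 8 + [(5000, 5000)] * 2)
        inc = box(0, 0, 1000, 1000)  # 100 ha
        s = border_stat_from_inclusion(calls, 200.0, inc, "N")
        assert s.observed_calls == 8
        assert s.calls_per_ha == pytest.approx(8 / 100.0)
        assert s.observed_locations == 2 - 1  # one deduped location inside
        assert s.locations_per_ha == pytest.approx(1 / 100.0)


def _profile(caller, nb, related, adults, partners, same_sex):
    return NeighbourProfile(caller, nb, related, adults, partners, same_sex)


def _stat(caller, nb, area, calls, locs):
    return audience.BorderStat(
        caller, nb, area, calls, locs, 0.0, 0.0, calls / area, locs / area
    )


class TestPairedTables:
    def test_eligibility_and_selection(self):
        profiles = {
            "C1": [
                _profile("C1", "A", True, 5, 0, 1),
                _profile("C1", "B", False, 3, 4, 2),
                _profile("C1", "D", False, 8, 1, 0),
            ],
            "C2": [_profile("C2", "A", False, 5, 2, 1)],  # single neighbour
        }
        stats = {
            "C1": [_stat("C1", "A", 10, 5, 3), _stat("C1", "B", 5, 10, 4), _stat("C1", "D", 10, 2, 2)],
            "C2": [_stat("C2", "A", 10, 5, 3)],
        }
        tables = paired_border_tables(profiles, stats)
        rel = tables["related_vs_unrelated"]
        assert list(rel["caller"]) == ["C1"]
        # pooled unrelated rate = (10+2)/(5+10)
        assert rel["calls_per_ha_low"].iloc[0] == pytest.approx(12 / 15)
        partners = tables["max_vs_min_partners"]
        assert list(partners[["high_neighbour", "low_neighbour"]].iloc[0]) == ["B", "A"]
        largest = tables["largest_vs_smallest_group"]
        assert list(largest[["high_neighbour", "low_neighbour"]].iloc[0]) == ["D", "B"]
        # C2 has one neighbour -> excluded everywhere
        for name in tables:
            assert "C2" not in set(tables[name]["caller"])

    def test_tie_break_is_lexicographic(self):
        profiles = {
            "C1": [
                _profile("C1", "B", False, 4, 2, 1),
                _profile("C1", "A", False, 4, 2, 1),
            ]
        }
        stats = {"C1": [_stat("C1", "A", 10, 4, 2), _stat("C1", "B", 10, 6, 3)]}
        t = paired_border_tables(profiles, stats)["max_vs_min_partners"]
        assert t["high_neighbour"].iloc[0] == "A"  # smallest id on ties
        assert t["low_neighbour"].iloc[0] == "B"


def _ws(ind, day, change, bouts, start=80.0):
    return WeightSession(ind, dt.date(2010, 10, 1) + dt.timedelta(days=day), start, start + change, bouts)


class TestWeightPairs:
    def test_pairs_within_window(self):
        sessions = [_ws("I1", 0, 1.0, 8), _ws("I1", 11, 2.5, 0)]
        pairs = weight_cost_pairs(sessions)
        assert len(pairs) == 1
        assert pairs["difference_g"].iloc[0] == pytest.approx(-1.5)

    def test_outside_window_excluded(self):
        sessions = [_ws("I1", 0, 1.0, 8), _ws("I1", 15, 2.5, 0)]
        assert len(weight_cost_pairs(sessions)) == 0

    def test_below_bout_threshold_not_a_calling_day(self):
        sessions = [_ws("I1", 0, 1.0, 5), _ws("I1", 3, 2.5, 0)]
        assert len(weight_cost_pairs(sessions)) == 0

    def test_nearest_quiet_day_chosen(self):
        sessions = [_ws("I1", 5, 1.0, 7), _ws("I1", 0, 9.9, 0), _ws("I1", 7, 2.0, 0)]
        pairs = weight_cost_pairs(sessions)
        assert pairs["change_noncalling_g"].iloc[0] == pytest.approx(2.0)

    def test_one_pair_per_individual(self):
        sessions = [
            _ws("I1", 0, 1.0, 7),
            _ws("I1", 2, 0.5, 0),
            _ws("I1", 20, 3.0, 9),
            _ws("I1", 21, 0.2, 0),
            _ws("I2", 0, -1.0, 6),
            _ws("I2", 4, 0.0, 0),
        ]
        pairs = weight_cost_pairs(sessions)
        assert list(pairs["individual_id"]) == ["I1", "I2"]

    def test_identical_changes_give_zero_difference(self):
        sessions = [_ws("I1", 0, 1.5, 8), _ws("I1", 4, 1.5, 0)]
        assert weight_cost_pairs(sessions)["difference_g"].iloc[0] == 0.0
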