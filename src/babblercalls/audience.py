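"""Audience-targeting analysis of advertisement call placement.

Four questions are asked of a focal subordinate's located loud-calls:

1. Do calls follow group movement?  Calls are classified into territory
   bands (inside the 50% isopleth, between 50 and 75%, between 75 and 95%,
   outside 95%) and compared with the movement-proportional expectation of
   50% / 25% / 20% for the three inner bands.
2. Are calls concentrated near particular neighbours?  A 100 m buffer is
   drawn around each neighbouring group's 95% isopleth; its intersection
   with the focal 95% isopleth is the *inclusion area*, and the
   area-proportional expectation for calls falling there is
   total_calls / focal_area_ha * inclusion_area_ha.
3. Which neighbours are targeted?  Paired comparisons of per-hectare call
   (and calling-location) rates between related and unrelated borders, the
   largest and smallest neighbouring group, and the neighbours with the
   most/fewest potential breeding partners (plus a same-sex control).
4. Does calling carry a mass cost?  Daily weight change on heavy-calling
   days (>= 6 bouts) is paired with the nearest non-calling day within two
   weeks.

Both raw call counts and deduplicated calling locations (1 m coordinate
rounding) are analysed throughout, mirroring the paired presentation of
count and location results.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .core_io import CallRecord, WeightSession
from .locoh import Territory, area_hectares
from .pedigree import NeighbourProfile

logger = logging.getLogger(__name__)

BANDS = ("core50", "band50_75", "band75_95", "outside95")
#: movement-proportional expected shares for the three inner bands; they sum
#: to 0.95 by design (the outside-95% share is reported but not tested).
EXPECTED_PROPORTIONS: dict[str, float] = {
    "core50": 0.50,
    "band50_75": 0.25,
    "band75_95": 0.20,
}
BUFFER_DISTANCE_M = 100.0
MIN_CALLS = 10
LOCATION_ROUND_M = 1.0
BUFFER_QUAD_SEGS = 64  # circle-arc resolution; area error ~1e-4 relative


@dataclass(frozen=True)
class CallingLocation:
    """A deduplicated calling position and how many calls were given there."""

    x: float
    y: float
    n_calls: int


@dataclass
class BandCounts:
    counts: dict[str, int]
    expected: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class BorderStat:
    """Observed and expected calling at one focal/neighbour border."""

    caller: str
    neighbour: str
    inclusion_area_ha: float
    observed_calls: int
    observed_locations: int
    expected_calls: float
    expected_locations: float
    calls_per_ha: float
    locations_per_ha: float


def dedupe_locations(
    calls: Sequence[CallRecord], round_m: float = LOCATION_ROUND_M
) -> list[CallingLocation]:
    """Collapse repeated calls from the same spot into calling locations.

    Coordinates are snapped to a ``round_m`` grid (1 m by default, well
    inside handheld-GPS accuracy); order follows first occurrence.
    """
    if round_m <= 0:
        raise ValueError("round_m must be positive")
    buckets: dict[tuple[float, float], int] = {}
    for c in calls:
        key = (round(c.x / round_m) * round_m, round(c.y / round_m) * round_m)
        buckets[key] = buckets.get(key, 0) + 1
    return [CallingLocation(x, y, n) for (x, y), n in buckets.items()]


def filter_eligible_callers(
    calls: Sequence[CallRecord], min_calls: int = MIN_CALLS
) -> set[str]:
    """Callers with at least ``min_calls`` located calls (inclusive)."""
    tally: dict[str, int] = {}
    for c in calls:
        tally[c.caller_id] = tally.get(c.caller_id, 0) + 1
    return {caller for caller, n in tally.items() if n >= min_calls}


def classify_band(point: tuple[float, float], territory: Territory) -> str:
    """Innermost isopleth band containing the point (boundary inclusive)."""
    return classify_bands(np.asarray([point], dtype=float), territory)[0]


def classify_bands(points: np.ndarray, territory: Territory) -> list[str]:
    """Vectorised band classification for an (n, 2) coordinate array."""
    pts = shapely.points(np.asarray(points, dtype=float))
    result = np.full(len(pts), "outside95", dtype=object)
    undecided = np.ones(len(pts), dtype=bool)
    for level, band in ((0.50, "core50"), (0.75, "band50_75"), (0.95, "band75_95")):
        iso = territory.isopleths[level]
        hit = undecided & shapely.covers(iso, pts)
        result[hit] = band
        undecided &= ~hit
    return list(result)


def expected_band_counts(total_calls: float) -> dict[str, float]:
    """Movement-proportional expectations for the three inner bands.

    Deliberately unnormalised: the shares (0.5, 0.25, 0.20) sum to 0.95, so
    the three-band goodness-of-fit has df = 2 and the outside-95% remainder
    is reported separately.
    """
    if total_calls < 0:
        raise ValueError("total_calls must be non-negative")
    return {band: p * total_calls for band, p in EXPECTED_PROPORTIONS.items()}


def band_counts(
    points: Sequence[tuple[float, float]] | np.ndarray, territory: Territory
) -> BandCounts:
    """Observed counts per band plus movement-proportional expectations."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    bands = classify_bands(pts, territory)
    counts = {band: 0 for band in BANDS}
    for b in bands:
        counts[b] += 1
    return BandCounts(counts=counts, expected=expected_band_counts(len(pts)))


def buffer_polygon(
    polygon: BaseGeometry, distance: float = BUFFER_DISTANCE_M
) -> BaseGeometry:
    """Minkowski dilation of the polygon by a disc (round joins)."""
    if not polygon.is_valid:
        raise ValueError("invalid polygon passed to buffer_polygon")
    if distance < 0:
        raise ValueError("buffer distance must be non-negative")
    if distance == 0:
        return polygon
    return polygon.buffer(distance, quad_segs=BUFFER_QUAD_SEGS)


def inclusion_area(
    focal_95: BaseGeometry,
    neighbour_95: BaseGeometry,
    distance: float = BUFFER_DISTANCE_M,
) -> BaseGeometry:
    """Part of the focal territory within ``distance`` of a neighbour.

    The neighbour's 95% isopleth is buffered and intersected with the focal
    95% isopleth, so the result is clipped to the focal territory (the
    denominator of the area-proportional expectation); may be empty.
    """
    return focal_95.intersection(buffer_polygon(neighbour_95, distance))


def _covered_count(geom: BaseGeometry, xy: np.ndarray) -> int:
    if len(xy) == 0 or geom.is_empty:
        return 0
    return int(shapely.covers(geom, shapely.points(xy)).sum())


def border_stat(
    caller_calls: Sequence[CallRecord],
    focal_territory: Territory,
    neighbour_territory: Territory,
    distance: float = BUFFER_DISTANCE_M,
    round_m: float = LOCATION_ROUND_M,
) -> BorderStat:
    """Observed vs area-proportional expected calling at one border.

    expected = total_calls / focal_95_area_ha * inclusion_area_ha, i.e. the
    count expected were calling spread evenly over the focal territory.
    Rates are per hectare of inclusion area (NaN when the border is empty).
    """
    focal_ha = focal_territory.areas_ha[0.95]
    inclusion = inclusion_area(
        focal_territory.isopleths[0.95], neighbour_territory.isopleths[0.95], distance
    )
    return border_stat_from_inclusion(
        caller_calls,
        focal_ha,
        inclusion,
        neighbour_territory.group_id,
        round_m,
        focal_group=focal_territory.group_id,
    )


def border_stat_from_inclusion(
    caller_calls: Sequence[CallRecord],
    focal_area_ha: float,
    inclusion: BaseGeometry,
    neighbour_id: str,
    round_m: float = LOCATION_ROUND_M,
    focal_group: str = "",
) -> BorderStat:
    """As :func:`border_stat` but with the inclusion polygon precomputed
    (used when many call sets are scored against fixed territories)."""
    focal_ha = focal_area_ha
    if focal_ha <= 0:
        raise ValueError("focal 95% isopleth has zero area")
    inc_ha = area_hectares(inclusion)
    calls_xy = np.asarray([(c.x, c.y) for c in caller_calls], dtype=float).reshape(-1, 2)
    locations = dedupe_locations(caller_calls, round_m)
    locs_xy = np.asarray([(l.x, l.y) for l in locations], dtype=float).reshape(-1, 2)
    obs_calls = _covered_count(inclusion, calls_xy)
    obs_locs = _covered_count(inclusion, locs_xy)
    if inc_ha == 0 and (obs_calls or obs_locs):
        logger.warning(
            "calls observed inside an empty inclusion area for %s vs %s",
            focal_group,
            neighbour_id,
        )
    caller = caller_calls[0].caller_id if caller_calls else ""
    return BorderStat(
        caller=caller,
        neighbour=neighbour_id,
        inclusion_area_ha=inc_ha,
        observed_calls=obs_calls,
        observed_locations=obs_locs,
        expected_calls=len(caller_calls) / focal_ha * inc_ha,
        expected_locations=len(locations) / focal_ha * inc_ha,
        calls_per_ha=obs_calls / inc_ha if inc_ha > 0 else float("nan"),
        locations_per_ha=obs_locs / inc_ha if inc_ha > 0 else float("nan"),
    )


# ---------------------------------------------------------------------------
# paired comparison tables

PAIRED_TABLES = (
    "related_vs_unrelated",
    "largest_vs_smallest_group",
    "max_vs_min_partners",
    "max_vs_min_same_sex",
)

_METRIC = {
    "largest_vs_smallest_group": "n_adults",
    "max_vs_min_partners": "n_potential_partners",
    "max_vs_min_same_sex": "n_same_sex_unrelated_adults",
}

_COLUMNS = [
    "caller",
    "high_neighbour",
    "low_neighbour",
    "calls_per_ha_high",
    "calls_per_ha_low",
    "locations_per_ha_high",
    "locations_per_ha_low",
]


def _pooled_rate(stats: Sequence[BorderStat]) -> tuple[float, float]:
    area = sum(s.inclusion_area_ha for s in stats)
    if area <= 0:
        return float("nan"), float("nan")
    return (
        sum(s.observed_calls for s in stats) / area,
        sum(s.observed_locations for s in stats) / area,
    )


def _pick(profiles: Sequence[NeighbourProfile], metric: str, maximise: bool) -> NeighbourProfile:
    # deterministic tie-break: lexicographically smallest group id, logged
    key = lambda p: getattr(p, metric)
    extreme = max(key(p) for p in profiles) if maximise else min(key(p) for p in profiles)
    tied = sorted((p for p in profiles if key(p) == extreme), key=lambda p: p.neighbour_group)
    if len(tied) > 1:
        logger.info(
            "tie on %s=%s for caller %s among %s; keeping %s",
            metric,
            extreme,
            tied[0].focal_caller,
            [p.neighbour_group for p in tied],
            tied[0].neighbour_group,
        )
    return tied[0]


def paired_border_tables(
    profiles: Mapping[str, Sequence[NeighbourProfile]],
    border_stats: Mapping[str, Sequence[BorderStat]],
) -> dict[str, pd.DataFrame]:
    """Assemble the four per-caller paired comparisons.

    ``profiles`` and ``border_stats`` map caller id to that caller's
    neighbour profiles / border statistics.  Table 1 pairs the pooled
    related-border rate against the pooled unrelated-border rate (callers
    need at least one of each); tables 2-4 pair the neighbour maximising a
    composition metric against the one minimising it (callers need >= 2
    neighbours).  Ineligible callers are excluded per table and logged.
    """
    rows: dict[str, list[list]] = {name: [] for name in PAIRED_TABLES}
    for caller in sorted(profiles):
        profs = list(profiles[caller])
        stats = {s.neighbour: s for s in border_stats.get(caller, [])}
        usable = [p for p in profs if p.neighbour_group in stats]
        related = [stats[p.neighbour_group] for p in usable if p.related]
        unrelated = [stats[p.neighbour_group] for p in usable if not p.related]
        if related and unrelated:
            rc, rl = _pooled_rate(related)
            uc, ul = _pooled_rate(unrelated)
            rows["related_vs_unrelated"].append(
                [
                    caller,
                    "|".join(sorted(s.neighbour for s in related)),
                    "|".join(sorted(s.neighbour for s in unrelated)),
                    rc,
                    uc,
                    rl,
                    ul,
                ]
            )
        else:
            logger.info(
                "caller %s excluded from related_vs_unrelated (related=%d unrelated=%d)",
                caller,
                len(related),
                len(unrelated),
            )
        for name, metric in _METRIC.items():
            if len(usable) < 2:
                logger.info("caller %s excluded from %s (<2 neighbours)", caller, name)
                continue
            hi = _pick(usable, metric, maximise=True)
            lo_pool = [p for p in usable if p is not hi]
            lo = _pick(lo_pool, metric, maximise=False)
            s_hi = stats[hi.neighbour_group]
            s_lo = stats[lo.neighbour_group]
            rows[name].append(
                [
                    caller,
                    hi.neighbour_group,
                    lo.neighbour_group,
                    s_hi.calls_per_ha,
                    s_lo.calls_per_ha,
                    s_hi.locations_per_ha,
                    s_lo.locations_per_ha,
                ]
            )
    return {
        name: pd.DataFrame(data, columns=_COLUMNS) for name, data in rows.items()
    }


# ---------------------------------------------------------------------------
# weight-cost pairing


def weight_cost_pairs(
    weights: Sequence[WeightSession],
    min_bouts: int = 6,
    window_days: int = 14,
) -> pd.DataFrame:
    """Pair each individual's heaviest-calling day with a quiet day.

    A *calling day* has >= ``min_bouts`` advertisement bouts; it is paired
    with the nearest-in-date zero-bout session within ``window_days``.  One
    pair is kept per individual — the pair with the smallest date gap,
    earliest calling date on ties.  Individuals with no admissible pair are
    excluded.

    Returns a DataFrame with the paired daily mass changes (grams) and their
    difference (calling minus non-calling).
    """
    by_ind: dict[str, list[WeightSession]] = {}
    for w in weights:
        by_ind.setdefault(w.individual_id, []).append(w)
    rows = []
    for ind in sorted(by_ind):
        sessions = by_ind[ind]
        calling = sorted(
            (s for s in sessions if s.n_calling_bouts >= min_bouts),
            key=lambda s: s.date,
        )
        quiet = [s for s in sessions if s.n_calling_bouts == 0]
        best: tuple[int, dt.date, WeightSession, WeightSession] | None = None
        for c in calling:
            for q in quiet:
                gap = abs((c.date - q.date).days)
                if gap > window_days:
                    continue
                cand = (gap, c.date, c, q)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            logger.info("individual %s has no weight pair within %d days", ind, window_days)
            continue
        _, _, c, q = best
        rows.append(
            [
                ind,
                c.date,
                q.date,
                abs((c.date - q.date).days),
                c.mass_change,
                q.mass_change,
                c.mass_change - q.mass_change,
            ]
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "calling_date",
            "noncalling_date",
            "gap_days",
            "change_calling_g",
            "change_noncalling_g",
            "difference_g",
        ],
    )
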