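"""End-to-end run: territories -> call placement -> targeting -> costs.

``run_all`` executes the whole analysis on a validated Dataset and returns a
RunReport whose every number is recomputable from the inputs plus the
AnalysisConfig.  ``write_report`` persists the tables (delimited text), the
inclusion-area GeoJSON, and a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .core_io import Dataset, ValidationError, write_polygons
from .locoh import DEFAULT_LEVELS, Territory, estimate_territory
from .pedigree import (
    ADULT_AGE_DAYS,
    RELATEDNESS_THRESHOLD,
    NeighbourProfile,
    profile_neighbour,
    relatedness_matrix,
)
from .audience import (
    BANDS,
    BUFFER_DISTANCE_M,
    LOCATION_ROUND_M,
    MIN_CALLS,
    BandCounts,
    BorderStat,
    band_counts,
    border_stat,
    dedupe_locations,
    expected_band_counts,
    filter_eligible_callers,
    inclusion_area,
    paired_border_tables,
    weight_cost_pairs,
)
from .stats import ChiSqResult, PairedTResult, chisq_gof, paired_t

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    levels: tuple[float, ...] = DEFAULT_LEVELS
    buffer_m: float = BUFFER_DISTANCE_M
    min_calls: int = MIN_CALLS
    relatedness_threshold: float = RELATEDNESS_THRESHOLD
    adult_age_days: int = ADULT_AGE_DAYS
    min_bouts: int = 6
    pairing_window_days: int = 14
    location_round_m: float = LOCATION_ROUND_M
    min_border_ha: float = 1.0  # a neighbour must share at least this much border
    a_value: float | None = None  # None -> max pairwise distance per group
    reference_date: dt.date = dt.date(2011, 1, 15)
    season: str = ""


@dataclass
class RunReport:
    config: AnalysisConfig
    territories: dict[str, Territory]
    band_by_caller: dict[str, BandCounts]
    location_band_by_caller: dict[str, BandCounts]
    band_test_calls: ChiSqResult | None
    band_test_locations: ChiSqResult | None
    profiles: dict[str, list[NeighbourProfile]]
    border_stats: dict[str, list[BorderStat]]
    related_test_calls: ChiSqResult | None
    related_test_locations: ChiSqResult | None
    paired_tables: dict[str, pd.DataFrame]
    paired_tests: dict[str, dict[str, PairedTResult | None]]
    weight_pairs: pd.DataFrame
    weight_test: PairedTResult | None
    eligible_callers: list[str]
    multi_assigned_calls: int
    provenance: dict


def _pooled_band_test(per_caller: Mapping[str, BandCounts]) -> ChiSqResult | None:
    """Pool per-caller band counts, then test the three inner bands (df = 2)."""
    if not per_caller:
        return None
    obs = [sum(bc.counts[b] for bc in per_caller.values()) for b in BANDS[:3]]
    exp = [sum(bc.expected[b] for bc in per_caller.values()) for b in BANDS[:3]]
    if any(e <= 0 for e in exp):
        return None
    return chisq_gof(obs, exp)


def _related_unrelated_test(
    profiles: Mapping[str, list[NeighbourProfile]],
    border_stats: Mapping[str, list[BorderStat]],
    use_locations: bool = False,
) -> ChiSqResult | None:
    """Pooled related vs unrelated border counts against area-proportional
    expectations (two categories, df = 1)."""
    obs = [0.0, 0.0]
    exp = [0.0, 0.0]
    for caller, plist in profiles.items():
        related_groups = {p.neighbour_group for p in plist if p.related}
        for s in border_stats.get(caller, []):
            k = 0 if s.neighbour in related_groups else 1
            if use_locations:
                obs[k] += s.observed_locations
                exp[k] += s.expected_locations
            else:
                obs[k] += s.observed_calls
                exp[k] += s.expected_calls
    if min(exp) <= 0:
        return None
    return chisq_gof(obs, exp)


def run_all(dataset: Dataset, config: AnalysisConfig = AnalysisConfig()) -> RunReport:
    dataset.validate()
    by_group_fixes = dataset.fixes_by_group()
    by_group_ind = dataset.individuals_by_group()
    ind_by_id = {i.id: i for i in dataset.individuals}

    territories: dict[str, Territory] = {}
    for gid, fixes in sorted(by_group_fixes.items()):
        territories[gid] = estimate_territory(
            fixes, gid, season=config.season, a=config.a_value, levels=config.levels
        )

    matrix = relatedness_matrix(dataset.pedigree)
    calls_by_caller = dataset.calls_by_caller()
    eligible = sorted(filter_eligible_callers(dataset.calls, config.min_calls))
    if not eligible:
        logger.warning("no caller reaches %d located calls; analysis tables empty", config.min_calls)

    band_by_caller: dict[str, BandCounts] = {}
    loc_band_by_caller: dict[str, BandCounts] = {}
    profiles: dict[str, list[NeighbourProfile]] = {}
    border_stats: dict[str, list[BorderStat]] = {}
    multi_assigned = 0

    for caller in eligible:
        calls = calls_by_caller[caller]
        gid = calls[0].group_id
        if gid not in territories:
            logger.warning("caller %s group %s has no fixes; skipped", caller, gid)
            continue
        terr = territories[gid]
        xy = np.array([(c.x, c.y) for c in calls])
        band_by_caller[caller] = band_counts(xy, terr)
        locs = dedupe_locations(calls, config.location_round_m)
        loc_band_by_caller[caller] = band_counts(
            np.array([(l.x, l.y) for l in locs]), terr
        )

        caller_ind = ind_by_id[caller]
        plist: list[NeighbourProfile] = []
        slist: list[BorderStat] = []
        per_call_hits = np.zeros(len(calls), dtype=int)
        for nb, nb_terr in sorted(territories.items()):
            if nb == gid:
                continue
            inc = inclusion_area(
                terr.isopleths[0.95], nb_terr.isopleths[0.95], config.buffer_m
            )
            if inc.is_empty or inc.area < config.min_border_ha * 10_000.0:
                continue  # sliver contact, not a shared border
            members = by_group_ind.get(nb, [])
            if not members:
                continue
            plist.append(
                profile_neighbour(
                    caller_ind,
                    members,
                    matrix,
                    config.reference_date,
                    config.relatedness_threshold,
                    config.adult_age_days,
                )
            )
            s = border_stat(calls, terr, nb_terr, config.buffer_m, config.location_round_m)
            slist.append(s)
            per_call_hits += shapely.covers(inc, shapely.points(xy)).astype(int)
        profiles[caller] = plist
        border_stats[caller] = slist
        multi_assigned += int((per_call_hits > 1).sum())

    band_test_calls = _pooled_band_test(band_by_caller)
    band_test_locations = _pooled_band_test(loc_band_by_caller)
    related_calls = _related_unrelated_test(profiles, border_stats, use_locations=False)
    related_locs = _related_unrelated_test(profiles, border_stats, use_locations=True)

    tables = paired_border_tables(profiles, border_stats)
    paired_tests: dict[str, dict[str, PairedTResult | None]] = {}
    for name, table in tables.items():
        tests: dict[str, PairedTResult | None] = {"calls_per_ha": None, "locations_per_ha": None}
        clean = table.dropna()
        if len(clean) >= 2:
            tests["calls_per_ha"] = paired_t(
                clean["calls_per_ha_high"], clean["calls_per_ha_low"]
            )
            tests["locations_per_ha"] = paired_t(
                clean["locations_per_ha_high"], clean["locations_per_ha_low"]
            )
        paired_tests[name] = tests

    wp = weight_cost_pairs(dataset.weights, config.min_bouts, config.pairing_window_days)
    weight_test = (
        paired_t(wp["change_calling_g"], wp["change_noncalling_g"])
        if len(wp) >= 2
        else None
    )

    provenance = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "a_values": {g: t.a_value for g, t in territories.items()},
        "n_fixes": {g: t.n_fixes for g, t in territories.items()},
        "eligible_callers": eligible,
        "caller_groups": {
            c: calls_by_caller[c][0].group_id for c in eligible if c in calls_by_caller
        },
    }
    return RunReport(
        config=config,
        territories=territories,
        band_by_caller=band_by_caller,
        location_band_by_caller=loc_band_by_caller,
        band_test_calls=band_test_calls,
        band_test_locations=band_test_locations,
        profiles=profiles,
        border_stats=border_stats,
        related_test_calls=related_calls,
        related_test_locations=related_locs,
        paired_tables=tables,
        paired_tests=paired_tests,
        weight_pairs=wp,
        weight_test=weight_test,
        eligible_callers=eligible,
        multi_assigned_calls=multi_assigned,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# persistence


def band_table(report: RunReport) -> pd.DataFrame:
    rows = []
    for unit, mapping in (
        ("calls", report.band_by_caller),
        ("locations", report.location_band_by_caller),
    ):
        for caller, bc in sorted(mapping.items()):
            for band in BANDS:
                rows.append(
                    [unit, caller, band, bc.counts[band], bc.expected.get(band, float("nan"))]
                )
    return pd.DataFrame(rows, columns=["unit", "caller", "band", "observed", "expected"])


def border_table(report: RunReport) -> pd.DataFrame:
    rows = []
    for caller, slist in sorted(report.border_stats.items()):
        related = {p.neighbour_group: p.related for p in report.profiles.get(caller, [])}
        for s in slist:
            rows.append(
                [
                    s.caller,
                    s.neighbour,
                    related.get(s.neighbour),
                    s.inclusion_area_ha,
                    s.observed_calls,
                    s.expected_calls,
                    s.calls_per_ha,
                    s.observed_locations,
                    s.expected_locations,
                    s.locations_per_ha,
                ]
            )
    return pd.DataFrame(
        rows,
        columns=[
            "caller",
            "neighbour",
            "related",
            "inclusion_area_ha",
            "observed_calls",
            "expected_calls",
            "calls_per_ha",
            "observed_locations",
            "expected_locations",
            "locations_per_ha",
        ],
    )


def tests_table(report: RunReport) -> pd.DataFrame:
    rows = []

    def chi(name: str, r: ChiSqResult | None) -> None:
        if r is not None:
            rows.append([name, "chisq", r.statistic, r.df, r.p, None])

    def tt(name: str, r: PairedTResult | None) -> None:
        if r is not None:
            rows.append([name, "paired_t", r.t, r.df, r.p, r.n])

    chi("band_calls", report.band_test_calls)
    chi("band_locations", report.band_test_locations)
    chi("related_border_calls", report.related_test_calls)
    chi("related_border_locations", report.related_test_locations)
    for name, tests in report.paired_tests.items():
        tt(f"{name}_calls_per_ha", tests.get("calls_per_ha"))
        tt(f"{name}_locations_per_ha", tests.get("locations_per_ha"))
    tt("weight_cost", report.weight_test)
    return pd.DataFrame(
        rows, columns=["analysis", "test", "statistic", "df", "p", "n"]
    )


def write_report(report: RunReport, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    band_table(report).to_csv(out / "band_counts.csv", index=False)
    border_table(report).to_csv(out / "border_stats.csv", index=False)
    paired = []
    for name, table in report.paired_tables.items():
        t = table.copy()
        t.insert(0, "comparison", name)
        paired.append(t)
    pd.concat(paired, ignore_index=True).to_csv(out / "paired_tables.csv", index=False)
    report.weight_pairs.to_csv(out / "weight_pairs.csv", index=False)
    tests_table(report).to_csv(out / "tests.csv", index=False)

    polys = {}
    props = {}
    for gid, terr in report.territories.items():
        for level, geom in terr.isopleths.items():
            polys[(gid, level)] = geom
            props[(gid, level)] = {"a_value": terr.a_value, "n_fixes": terr.n_fixes}
    write_polygons(polys, out / "territories.geojson", props)

    _write_inclusions(report, out / "inclusion_areas.geojson")

    (out / "report.txt").write_text(render_summary(report))


def _write_inclusions(report: RunReport, path: Path) -> None:
    """Rebuild and persist each analysed border's inclusion polygon."""
    caller_groups: Mapping[str, str] = report.provenance.get("caller_groups", {})
    features = {}
    for caller, slist in report.border_stats.items():
        focal_gid = caller_groups.get(caller)
        if focal_gid is None:
            continue
        for s in slist:
            inc = inclusion_area(
                report.territories[focal_gid].isopleths[0.95],
                report.territories[s.neighbour].isopleths[0.95],
                report.config.buffer_m,
            )
            features[(f"{caller}->{s.neighbour}", 0.95)] = inc
    write_polygons(features, path)


def render_summary(report: RunReport) -> str:
    lines = [
        f"babblercalls v{report.provenance['version']} run report",
        "=" * 50,
        f"territories: {len(report.territories)}  eligible callers: {len(report.eligible_callers)}",
        f"multi-assigned calls (inside two borders): {report.multi_assigned_calls}",
        "",
        "territory areas (ha):",
    ]
    for gid, terr in sorted(report.territories.items()):
        areas = ", ".join(f"{q:.0%}: {a:.1f}" for q, a in sorted(terr.areas_ha.items()))
        lines.append(f"  {gid}: {areas}  (a = {terr.a_value:.0f} m, n = {terr.n_fixes})")
    lines.append("")
    lines.append("tests:")
    for _, row in tests_table(report).iterrows():
        n = "" if pd.isna(row["n"]) or row["n"] is None else f", n = {int(row['n'])}"
        lines.append(
            f"  {row['analysis']}: {row['test']} statistic = {row['statistic']:.3f}, "
            f"df = {int(row['df'])}, P = {row['p']:.4g}{n}"
        )
    return "\n".join(lines) + "\n"
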