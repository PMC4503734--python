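"""Synthetic study populations with planted, recoverable effects.

No field dataset accompanies the analysis, so this module generates complete
Datasets with the statistical structure the pipeline assumes:

* territorial groups on a jittered grid whose mean-reverting (AR(1)) group
  movement yields a dense central utilisation with nested 50/75/95%
  isopleths, neighbouring territories abutting;
* 2-15-member groups with exactly one dominant pair; subordinates are
  pedigree offspring of their group's dominants, and a configurable subset
  of neighbour dominants are full siblings of the focal caller (dispersers
  from the caller's natal group), making those neighbours *related*;
* one focal subordinate caller per group producing 10-38 located loud-calls
  with a configurable border bias (probability a call is placed in a border
  inclusion area rather than at a random movement fix) and partner
  preference (border choice weighted by (1 + n_potential_partners)^gamma
  among unrelated neighbours);
* daily weighing sessions pairing a heavy-calling day with a quiet day 2-11
  days apart, with a configurable mass-change effect of calling.

Defaults emulate the field scales: 300 fixes per group-season, 26 calls per
caller, ~2 km territory diameter, 75-95 g birds.  The same seed always
produces an identical Dataset.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry

from .core_io import CallRecord, Dataset, Fix, Individual, Pedigree, WeightSession
from .locoh import Territory, estimate_territory
from .pedigree import NeighbourProfile, profile_neighbour, relatedness_matrix
from .audience import BUFFER_DISTANCE_M, inclusion_area

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MovementParams:
    """Mean-reverting walk: x[t+1] = x[t] + theta*(centre - x[t]) + sigma*eps."""

    theta: float = 0.1  # reversion fraction per 15-min step, in (0, 1]
    sigma: float = 180.0  # step noise, metres


@dataclass(frozen=True)
class CallerParams:
    n_calls: int = 26  # located calls per caller-season (field mean ~26)
    border_bias: float = 0.5  # P(call placed in a border inclusion area)
    partner_exponent: float = 2.0  # border weight ~ (1 + partners)^gamma


@dataclass(frozen=True)
class WeightParams:
    baseline_gain: float = 2.0  # grams gained over a session, quiet day
    calling_effect: float = 0.0  # additional change on heavy-calling days
    noise_sd: float = 1.0  # session-level noise, grams


@dataclass(frozen=True)
class SimConfig:
    n_groups: int = 6
    territory_spacing: float = 1600.0  # metres between grid centres
    grid_jitter: float = 0.05  # centre jitter, fraction of spacing
    n_fixes_per_group: int = 300
    movement: MovementParams = MovementParams()
    caller: CallerParams = CallerParams()
    group_size_range: tuple[int, int] = (2, 15)
    ensure_caller: bool = True  # bump size-2 groups to 3 so a caller exists
    sex_ratio: float = 0.5
    related_neighbour_prob: float = 0.5
    neighbour_radius_factor: float = 1.3  # neighbours: centres within factor*spacing
    buffer_m: float = BUFFER_DISTANCE_M
    min_border_ha: float = 1.0  # smaller inclusion areas are not real borders
    weights: WeightParams = WeightParams()
    n_weighed: int = 8
    season: str = "2010-2011"
    season_start: dt.date = dt.date(2010, 9, 1)
    reference_date: dt.date = dt.date(2011, 1, 15)
    seed: int = 0


@dataclass
class Landscape:
    centres: dict[str, np.ndarray]
    individuals: list[Individual]
    pedigree: Pedigree
    callers: dict[str, str]  # caller id -> group id
    neighbours: dict[str, list[str]]  # group id -> adjacent group ids


@dataclass
class SimResult:
    """A generated Dataset plus the landscape truth used to build it."""

    config: SimConfig
    dataset: Dataset
    landscape: Landscape
    fixes_xy: dict[str, np.ndarray]
    territories: dict[str, Territory]
    profiles: dict[str, list[NeighbourProfile]]
    inclusions: dict[tuple[str, str], BaseGeometry]


# ---------------------------------------------------------------------------
# landscape


def simulate_landscape(config: SimConfig, rng: np.random.Generator) -> Landscape:
    """Group centres on a jittered grid plus compositions and pedigree."""
    if config.n_groups < 2:
        raise ValueError("need at least two groups")
    if config.territory_spacing <= 0:
        raise ValueError("territory spacing must be positive")
    s = config.territory_spacing
    ncols = int(math.ceil(math.sqrt(config.n_groups)))
    centres: dict[str, np.ndarray] = {}
    for g in range(config.n_groups):
        gid = f"G{g + 1:02d}"
        base = np.array([(g % ncols) * s, (g // ncols) * s])
        jitter = rng.uniform(-config.grid_jitter * s, config.grid_jitter * s, size=2)
        centres[gid] = base + jitter

    lo, hi = config.group_size_range
    if not (2 <= lo <= hi):
        raise ValueError("group_size_range must satisfy 2 <= lo <= hi")
    individuals: list[Individual] = []
    parents: dict[str, tuple[str | None, str | None]] = {}
    callers: dict[str, str] = {}
    dominants: dict[str, tuple[str, str]] = {}  # gid -> (female id, male id)
    ref = config.reference_date
    for gid in centres:
        size = int(rng.integers(lo, hi + 1))
        if config.ensure_caller and size < 3:
            size = 3
        dom_f, dom_m = f"{gid}-DF", f"{gid}-DM"
        dominants[gid] = (dom_f, dom_m)
        for ind, sex in ((dom_f, "female"), (dom_m, "male")):
            hatch = ref - dt.timedelta(days=int(rng.integers(1500, 3000)))
            individuals.append(Individual(ind, sex, hatch, gid, "dominant"))
            parents[ind] = (None, None)
        for k in range(size - 2):
            ind = f"{gid}-S{k + 1}"
            sex = "female" if rng.random() < config.sex_ratio else "male"
            # subordinate ages span juveniles (<1 y) and adults
            hatch = ref - dt.timedelta(days=int(rng.integers(200, 1450)))
            individuals.append(Individual(ind, sex, hatch, gid, "subordinate"))
            parents[ind] = (dom_f, dom_m)

    by_group: dict[str, list[Individual]] = {}
    for i in individuals:
        by_group.setdefault(i.group_id, []).append(i)
    for gid, members in by_group.items():
        adults = [
            m
            for m in members
            if m.rank == "subordinate" and m.is_adult(ref) and m.sex != "unknown"
        ]
        if adults:
            callers[max(adults, key=lambda m: m.age_days(ref)).id] = gid

    gids = sorted(centres)
    radius = config.neighbour_radius_factor * s
    neighbours: dict[str, list[str]] = {g: [] for g in gids}
    for i, g in enumerate(gids):
        for h in gids[i + 1 :]:
            if np.linalg.norm(centres[g] - centres[h]) <= radius:
                neighbours[g].append(h)
                neighbours[h].append(g)

    # kin links: with probability related_neighbour_prob, one dominant of a
    # neighbouring group is a disperser from the other group's dominant pair,
    # i.e. a full sibling of that group's subordinates (r = 0.5)
    for i, g in enumerate(gids):
        for h in neighbours[g]:
            if h <= g:
                continue
            if rng.random() >= config.related_neighbour_prob:
                continue
            natal, away = (g, h) if rng.random() < 0.5 else (h, g)
            nf, nm = dominants[natal]
            migrant = dominants[away][int(rng.integers(0, 2))]
            # only link founders, so the pedigree stays acyclic
            if parents[migrant] == (None, None) and parents[nf] == (None, None) and parents[nm] == (None, None):
                parents[migrant] = (nf, nm)

    return Landscape(
        centres=centres,
        individuals=individuals,
        pedigree=Pedigree(parents),
        callers=callers,
        neighbours=neighbours,
    )


# ---------------------------------------------------------------------------
# movement


def simulate_movement(
    centre: Sequence[float],
    n_fixes: int,
    theta: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Discrete mean-reverting walk around the territory centre.

    Starts at the centre; stationary per-coordinate variance is
    sigma^2 / (theta * (2 - theta)).
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    c = np.asarray(centre, dtype=float)
    steps = rng.standard_normal((n_fixes, 2)) * sigma
    xy = np.empty((n_fixes, 2))
    pos = c.copy()
    for t in range(n_fixes):
        pos = pos + theta * (c - pos) + steps[t]
        xy[t] = pos
    return xy


def _fix_timestamps(start: dt.date, n: int, per_day: int = 12) -> list[dt.datetime]:
    out = []
    for k in range(n):
        day, slot = divmod(k, per_day)
        out.append(
            dt.datetime.combine(start + dt.timedelta(days=day), dt.time(6, 0))
            + dt.timedelta(minutes=15 * slot)
        )
    return out


# ---------------------------------------------------------------------------
# calls


def _uniform_in_polygon(
    polygon: BaseGeometry, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    import shapely

    if polygon.is_empty or polygon.area == 0:
        raise ValueError("cannot sample from an empty polygon")
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = cand[shapely.covers(polygon, shapely.points(cand))]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


def simulate_calls(
    caller_id: str,
    group_id: str,
    fixes_xy: np.ndarray,
    border_polygons: Mapping[str, BaseGeometry],
    border_partners: Mapping[str, int],
    n_calls: int,
    border_bias: float,
    partner_exponent: float,
    rng: np.random.Generator,
    season_start: dt.date = dt.date(2010, 9, 1),
) -> list[CallRecord]:
    """Place a caller's loud-calls with a planted border/partner preference.

    Each call independently: with probability ``border_bias`` it is placed
    uniformly inside one *unrelated-border* inclusion polygon, chosen with
    probability proportional to (1 + n_potential_partners)^partner_exponent;
    otherwise it is placed at a uniformly chosen movement fix.  With no
    usable unrelated border the call falls back to movement placement.
    """
    if not 0 <= border_bias <= 1:
        raise ValueError("border_bias must be in [0, 1]")
    if partner_exponent < 0:
        raise ValueError("partner_exponent must be non-negative")
    usable = {
        nb: poly
        for nb, poly in border_polygons.items()
        if not poly.is_empty and poly.area > 0
    }
    if border_bias > 0 and not usable:
        logger.info(
            "caller %s has no usable unrelated border; calls follow movement", caller_id
        )
    names = sorted(usable)
    if names:
        w = np.array(
            [(1.0 + border_partners.get(nb, 0)) ** partner_exponent for nb in names]
        )
        w = w / w.sum()
    records: list[CallRecord] = []
    for k in range(n_calls):
        at_border = names and rng.random() < border_bias
        if at_border:
            nb = names[int(rng.choice(len(names), p=w))]
            xy = _uniform_in_polygon(usable[nb], 1, rng)[0]
        else:
            xy = fixes_xy[int(rng.integers(0, len(fixes_xy)))]
        ts = dt.datetime.combine(
            season_start + dt.timedelta(days=int(rng.integers(0, 200))), dt.time(8, 0)
        ) + dt.timedelta(minutes=int(rng.integers(0, 600)))
        records.append(
            CallRecord(caller_id, group_id, ts, float(xy[0]), float(xy[1]), f"s{k}")
        )
    return records


# ---------------------------------------------------------------------------
# weights


def simulate_weights(
    individual_ids: Sequence[str],
    rng: np.random.Generator,
    baseline_gain: float = 2.0,
    calling_effect: float = 0.0,
    noise_sd: float = 1.0,
    start: dt.date = dt.date(2010, 10, 1),
) -> list[WeightSession]:
    """One heavy-calling / quiet session pair per individual, 2-11 days apart.

    Session mass change = baseline_gain + calling_effect * [calling day]
    + Normal(0, noise_sd) grams; bout counts on calling days are >= 6.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sessions: list[WeightSession] = []
    for k, ind in enumerate(individual_ids):
        call_date = start + dt.timedelta(days=int(rng.integers(0, 120)))
        gap = int(rng.integers(2, 12))
        quiet_date = call_date + dt.timedelta(days=gap if rng.random() < 0.5 else -gap)
        bouts = 6 + int(rng.poisson(5.5))
        for date, is_calling in ((call_date, True), (quiet_date, False)):
            mass_start = float(rng.normal(82.0, 4.0))
            change = (
                baseline_gain
                + (calling_effect if is_calling else 0.0)
                + float(rng.normal(0.0, noise_sd))
            )
            sessions.append(
                WeightSession(
                    individual_id=ind,
                    date=date,
                    mass_start=mass_start,
                    mass_end=mass_start + change,
                    n_calling_bouts=bouts if is_calling else 0,
                )
            )
    return sessions


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: SimConfig = SimConfig()) -> SimResult:
    """Generate a complete Dataset plus the landscape truth behind it."""
    rng = np.random.default_rng(config.seed)
    land = simulate_landscape(config, rng)

    fixes_xy: dict[str, np.ndarray] = {}
    fixes: list[Fix] = []
    for gid in sorted(land.centres):
        xy = simulate_movement(
            land.centres[gid],
            config.n_fixes_per_group,
            config.movement.theta,
            config.movement.sigma,
            rng,
        )
        fixes_xy[gid] = xy
        for ts, (x, y) in zip(_fix_timestamps(config.season_start, len(xy)), xy):
            fixes.append(Fix(gid, ts, float(x), float(y)))

    territories = {
        gid: estimate_territory(fixes_xy[gid], gid, season=config.season)
        for gid in fixes_xy
    }

    matrix = relatedness_matrix(land.pedigree)
    by_group: dict[str, list[Individual]] = {}
    for i in land.individuals:
        by_group.setdefault(i.group_id, []).append(i)
    ind_by_id = {i.id: i for i in land.individuals}

    profiles: dict[str, list[NeighbourProfile]] = {}
    inclusions: dict[tuple[str, str], BaseGeometry] = {}
    for caller_id, gid in sorted(land.callers.items()):
        caller = ind_by_id[caller_id]
        plist = []
        for nb in sorted(land.neighbours[gid]):
            inc = inclusion_area(
                territories[gid].isopleths[0.95],
                territories[nb].isopleths[0.95],
                config.buffer_m,
            )
            inclusions[(caller_id, nb)] = inc
            plist.append(
                profile_neighbour(caller, by_group[nb], matrix, config.reference_date)
            )
        profiles[caller_id] = plist

    calls: list[CallRecord] = []
    for caller_id, gid in sorted(land.callers.items()):
        calls.extend(
            _caller_calls(
                SimResultDraft(config, land, fixes_xy, profiles, inclusions),
                caller_id,
                rng,
            )
        )

    weighed = sorted(land.callers)[: config.n_weighed]
    extra = [
        i.id
        for i in land.individuals
        if i.rank == "subordinate" and i.id not in land.callers
    ]
    weighed += extra[: max(0, config.n_weighed - len(weighed))]
    weights = simulate_weights(
        weighed,
        rng,
        baseline_gain=config.weights.baseline_gain,
        calling_effect=config.weights.calling_effect,
        noise_sd=config.weights.noise_sd,
    )

    dataset = Dataset(
        fixes=fixes,
        calls=calls,
        individuals=land.individuals,
        pedigree=land.pedigree,
        weights=weights,
    )
    dataset.validate()
    return SimResult(
        config=config,
        dataset=dataset,
        landscape=land,
        fixes_xy=fixes_xy,
        territories=territories,
        profiles=profiles,
        inclusions=inclusions,
    )


@dataclass
class SimResultDraft:
    config: SimConfig
    landscape: Landscape
    fixes_xy: dict[str, np.ndarray]
    profiles: dict[str, list[NeighbourProfile]]
    inclusions: dict[tuple[str, str], BaseGeometry]


def _caller_calls(
    sim: "SimResult | SimResultDraft",
    caller_id: str,
    rng: np.random.Generator,
    n_calls: int | None = None,
    border_bias: float | None = None,
    partner_exponent: float | None = None,
) -> list[CallRecord]:
    cfg = sim.config
    gid = sim.landscape.callers[caller_id]
    unrelated = [p for p in sim.profiles[caller_id] if not p.related]
    polys = {
        p.neighbour_group: sim.inclusions[(caller_id, p.neighbour_group)]
        for p in unrelated
        if sim.inclusions[(caller_id, p.neighbour_group)].area
        >= cfg.min_border_ha * 10_000.0
    }
    partners = {p.neighbour_group: p.n_potential_partners for p in unrelated}
    return simulate_calls(
        caller_id,
        gid,
        sim.fixes_xy[gid],
        polys,
        partners,
        cfg.caller.n_calls if n_calls is None else n_calls,
        cfg.caller.border_bias if border_bias is None else border_bias,
        cfg.caller.partner_exponent if partner_exponent is None else partner_exponent,
        rng,
        season_start=cfg.season_start,
    )


def resample_calls(
    sim: SimResult,
    rng: np.random.Generator,
    n_calls: int | None = None,
    border_bias: float | None = None,
    partner_exponent: float | None = None,
) -> dict[str, list[CallRecord]]:
    """Redraw every caller's calls on a fixed landscape.

    Used by the power/type-I recovery experiments: the territories and group
    compositions stay fixed while call placement (the randomness under test)
    is resampled.
    """
    return {
        caller_id: _caller_calls(
            sim, caller_id, rng, n_calls, border_bias, partner_exponent
        )
        for caller_id in sorted(sim.landscape.callers)
    }
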