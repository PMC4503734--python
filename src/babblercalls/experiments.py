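"""Replicated parameter-recovery experiments on synthetic landscapes.

These experiments check that the analysis recovers what the generator
plants.  To keep replicate counts high at desk scale, each experiment draws
a small set of independent landscapes (fixes, territories, compositions)
and then resamples *call placement* — the randomness the statistical tests
address — many times per landscape:

* type-I control: with no planted border bias, the pooled three-band
  goodness-of-fit should reject at about the nominal level;
* power: with half of all calls pushed to unrelated borders, the band test
  should reject nearly always;
* direction recovery: with a strong partner preference, the max-vs-min
  potential-partner paired comparison should come out positive;
* weight-cost power: the paired mass-change design should match the
  closed-form noncentral-t power.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy import stats as sps

from .audience import band_counts, border_stat_from_inclusion, paired_border_tables
from .pipeline import _pooled_band_test
from .stats import paired_t
from .synthetic import (
    CallerParams,
    SimConfig,
    SimResult,
    WeightParams,
    resample_calls,
    simulate_dataset,
    simulate_weights,
)
from .audience import weight_cost_pairs

#: landscape used by the call-placement experiments: a 4x3 grid of groups so
#: interior territories have several neighbours, with mostly unrelated
#: neighbours and 25 calls per caller.
EXPERIMENT_CONFIG = SimConfig(
    n_groups=12,
    related_neighbour_prob=0.35,
    caller=CallerParams(n_calls=25, border_bias=0.5, partner_exponent=2.0),
)


def _landscapes(
    n_landscapes: int, seed: int, n_callers: int, base: SimConfig
) -> list[SimResult]:
    """Independent landscapes, each trimmed to exactly ``n_callers`` callers."""
    sims = []
    attempt = 0
    while len(sims) < n_landscapes:
        cfg = dataclasses.replace(base, seed=(seed + 7919 * attempt) % (2**31 - 1))
        attempt += 1
        sim = simulate_dataset(cfg)
        if len(sim.landscape.callers) < n_callers:
            continue
        keep = sorted(sim.landscape.callers)[:n_callers]
        sim.landscape.callers = {c: sim.landscape.callers[c] for c in keep}
        for terr in sim.territories.values():
            for geom in terr.isopleths.values():
                shapely.prepare(geom)
        for geom in sim.inclusions.values():
            shapely.prepare(geom)
        sims.append(sim)
    return sims


def band_rejection_rate(
    n_reps: int,
    seed: int,
    border_bias: float,
    n_landscapes: int = 5,
    n_callers: int = 10,
    n_calls: int = 25,
    alpha: float = 0.05,
    base: SimConfig = EXPERIMENT_CONFIG,
) -> float:
    """Fraction of replicates where the pooled band test rejects at alpha.

    With ``border_bias = 0`` this estimates the type-I error of the
    movement-proportional null; with a planted bias it estimates power.
    """
    sims = _landscapes(n_landscapes, seed, n_callers, base)
    rng = np.random.default_rng(seed + 1)
    reps_per = [n_reps // n_landscapes] * n_landscapes
    for k in range(n_reps - sum(reps_per)):
        reps_per[k] += 1
    rejections = 0
    for sim, reps in zip(sims, reps_per):
        for _ in range(reps):
            calls = resample_calls(
                sim, rng, n_calls=n_calls, border_bias=border_bias
            )
            per_caller = {}
            for caller, clist in calls.items():
                gid = sim.landscape.callers[caller]
                xy = np.array([(c.x, c.y) for c in clist])
                per_caller[caller] = band_counts(xy, sim.territories[gid])
            result = _pooled_band_test(per_caller)
            if result is not None and result.p < alpha:
                rejections += 1
    return rejections / n_reps


def partner_direction_rate(
    n_reps: int,
    seed: int,
    partner_exponent: float = 2.0,
    border_bias: float = 0.5,
    n_landscapes: int = 5,
    n_callers: int = 10,
    n_calls: int = 25,
    base: SimConfig = EXPERIMENT_CONFIG,
) -> float:
    """Fraction of replicates where the max-vs-min potential-partner paired
    comparison recovers the planted positive direction (more calls per
    hectare at the border with more partners)."""
    sims = _landscapes(n_landscapes, seed, n_callers, base)
    rng = np.random.default_rng(seed + 2)
    reps_per = [n_reps // n_landscapes] * n_landscapes
    for k in range(n_reps - sum(reps_per)):
        reps_per[k] += 1
    hits = 0
    for sim, reps in zip(sims, reps_per):
        min_area = sim.config.min_border_ha * 10_000.0
        profiles = {c: sim.profiles[c] for c in sim.landscape.callers}
        usable_profiles = {
            c: [
                p
                for p in profiles[c]
                if sim.inclusions[(c, p.neighbour_group)].area >= min_area
            ]
            for c in profiles
        }
        for _ in range(reps):
            calls = resample_calls(
                sim,
                rng,
                n_calls=n_calls,
                border_bias=border_bias,
                partner_exponent=partner_exponent,
            )
            stats = {}
            for caller, clist in calls.items():
                gid = sim.landscape.callers[caller]
                focal_ha = sim.territories[gid].areas_ha[0.95]
                stats[caller] = [
                    border_stat_from_inclusion(
                        clist,
                        focal_ha,
                        sim.inclusions[(caller, p.neighbour_group)],
                        p.neighbour_group,
                        focal_group=gid,
                    )
                    for p in usable_profiles[caller]
                ]
            table = paired_border_tables(usable_profiles, stats)["max_vs_min_partners"]
            diffs = (table["calls_per_ha_high"] - table["calls_per_ha_low"]).dropna()
            if len(diffs) and diffs.mean() > 0:
                hits += 1
    return hits / n_reps


def paired_t_null_rejection_rate(
    n_reps: int,
    seed: int,
    n_pairs: int = 7,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the paired t test on i.i.d. normal null pairs.

    Should sit at the nominal level (the test is exact under normality).
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.standard_normal(n_pairs)
        y = rng.standard_normal(n_pairs)
        if paired_t(x, y).p < alpha:
            rejections += 1
    return rejections / n_reps


def weight_cost_power(
    n_reps: int,
    seed: int,
    calling_effect: float = -2.0,
    noise_sd: float = 1.0,
    n_individuals: int = 8,
    baseline_gain: float = 2.0,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo power of the paired weight-change design.

    Each replicate simulates ``n_individuals`` with one heavy-calling and
    one quiet session, runs the day-pairing and the paired t test, and
    counts rejections at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    ids = [f"I{k}" for k in range(n_individuals)]
    rejections = 0
    for _ in range(n_reps):
        sessions = simulate_weights(
            ids,
            rng,
            baseline_gain=baseline_gain,
            calling_effect=calling_effect,
            noise_sd=noise_sd,
        )
        pairs = weight_cost_pairs(sessions)
        result = paired_t(pairs["change_calling_g"], pairs["change_noncalling_g"])
        if result.p < alpha:
            rejections += 1
    return rejections / n_reps


def weight_cost_power_analytic(
    calling_effect: float = -2.0,
    noise_sd: float = 1.0,
    n_individuals: int = 8,
    alpha: float = 0.05,
) -> float:
    """Closed-form power of the paired t test for the weighing design.

    The paired difference is d = calling_effect + (e1 - e2) with independent
    session noises, so sd(d) = sqrt(2) * noise_sd and the noncentrality is
    ncp = calling_effect / (sd(d) / sqrt(n)).
    """
    n = n_individuals
    sd_diff = np.sqrt(2.0) * noise_sd
    ncp = calling_effect / (sd_diff / np.sqrt(n))
    tcrit = sps.t.ppf(1 - alpha / 2, n - 1)
    return float(
        sps.nct.cdf(-tcrit, n - 1, ncp) + sps.nct.sf(tcrit, n - 1, ncp)
    )
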