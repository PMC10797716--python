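"""Markov cohort engine.

Alive cohort members occupy a single controlled-asthma state; within each
two-week cycle they may experience at most one exacerbation event (OCS burst,
emergency-department visit or hospitalization, modelled as transient
within-cycle channels rather than persistent states), die of background
causes (life-table qx), or die of asthma following a hospitalized
exacerbation.  Death is absorbing.  Competing risks within a cycle are
resolved in a fixed declared order: background death first, then at most one
event among survivors, then asthma case fatality applied to the
hospitalization channel.

The add-on strategy applies the exacerbation relative risk on the rate scale
and models adherence waning by blending two sub-cohorts: a fraction
discontinues at ``waning_cycle`` and reverts to comparator inputs (including
dropping the drug cost) from that cycle onward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import ScenarioSpec
from .lifetable import LifeTable, annual_q_to_cycle_q
from .params import DAYS_PER_YEAR, AdherenceSpec, ParameterError, ParameterSet

logger = logging.getLogger(__name__)

#: Cohort mass below which the run is truncated ("extinction").
EXTINCTION_TOL = 1e-9

_COMPARATOR_ALIASES = {"comparator", "standard", "ics+laba", "ics_laba", "soc"}
_ADD_ON_ALIASES = {"add_on", "addon", "add-on", "tiotropium", "tiotropium+ics+laba"}


def normalize_strategy(strategy: str) -> str:
    s = strategy.strip().lower()
    if s in _COMPARATOR_ALIASES:
        return "comparator"
    if s in _ADD_ON_ALIASES:
        return "add_on"
    raise ParameterError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------


def rate_to_cycle_probability(annual_rate, cycle_days: float):
    """Constant-hazard conversion: ``1 - exp(-rate * cycle_days/365.25)``."""
    rate = np.asarray(annual_rate, dtype=float)
    if np.any(rate < 0):
        raise ParameterError("annual rate must be non-negative")
    if cycle_days <= 0:
        raise ParameterError(f"cycle_days must be positive, got {cycle_days}")
    out = -np.expm1(-rate * cycle_days / DAYS_PER_YEAR)
    return float(out) if np.ndim(annual_rate) == 0 else out


def apply_relative_risk(annual_rate: float, rr: float) -> float:
    """Treatment effect applied on the rate scale, before probability conversion."""
    if annual_rate < 0:
        raise ParameterError("annual rate must be non-negative")
    if rr <= 0:
        raise ParameterError(f"relative risk must be positive, got {rr}")
    return annual_rate * rr


# ---------------------------------------------------------------------------
# Per-cycle transition structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleTransition:
    """Per-cycle probabilities for one age and treatment status."""

    p_event_ocs: float
    p_event_ed: float
    p_event_hosp: float
    p_death_background: float
    p_death_asthma: float  # conditional on a hospitalized exacerbation

    def event_probs(self) -> np.ndarray:
        return np.array([self.p_event_ocs, self.p_event_ed, self.p_event_hosp])


def _event_probabilities(params: ParameterSet, on_treatment: bool) -> np.ndarray:
    """Per-cycle probabilities of the three event channels (possibly normalized)."""
    rate = params.events.exacerbation_annual_rate.base
    if on_treatment:
        rate = apply_relative_risk(rate, params.effect.rr_exacerbation.base)
    splits = np.array([params.events.split_ocs, params.events.split_ed,
                       params.events.split_hosp])
    p = rate_to_cycle_probability(splits * rate, params.econ.cycle_days)
    total = p.sum()
    if total > 1.0:
        logger.warning("event-channel probabilities sum to %.4f > 1; normalizing", total)
        p = p / total
        if p.sum() > 1.0 + 1e-12:
            raise ParameterError("event probabilities exceed 1 after normalization")
    return p


def build_cycle_transition(
    params: ParameterSet,
    on_treatment: bool,
    age: float,
    life_table: LifeTable,
    female_fraction: float = 0.5,
) -> CycleTransition:
    """Transition structure at one age: events, background and asthma death."""
    if not (life_table.start_age <= age <= life_table.terminal_age + 1):
        raise ParameterError(f"age {age} outside life-table range")
    qx = life_table.blended_qx(female_fraction)
    age_idx = min(int(math.floor(age)), life_table.terminal_age)
    p_events = _event_probabilities(params, on_treatment)
    return CycleTransition(
        p_event_ocs=float(p_events[0]),
        p_event_ed=float(p_events[1]),
        p_event_hosp=float(p_events[2]),
        p_death_background=annual_q_to_cycle_q(float(qx.loc[age_idx]), params.econ.cycle_days),
        p_death_asthma=params.events.asthma_case_fatality_hosp,
    )


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of one strategy's cohort.

    Row ``k`` holds the state occupancy at the *start* of cycle ``k`` and the
    event incidence (proportion of the original cohort) occurring *during*
    cycle ``k``; the final row is the terminal occupancy with zero incidence.
    ``frac_on_treatment`` is the on-drug fraction of the alive mass.
    """

    strategy: str
    cycle: np.ndarray
    age: np.ndarray
    alive: np.ndarray
    dead: np.ndarray
    inc_ocs: np.ndarray
    inc_ed: np.ndarray
    inc_hosp: np.ndarray
    frac_on_treatment: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.cycle)
        for name in ("age", "alive", "dead", "inc_ocs", "inc_ed", "inc_hosp",
                     "frac_on_treatment"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace column {name!r} has wrong length")

    @property
    def n_cycles(self) -> int:
        """Number of full cycles spanned (rows minus the terminal record)."""
        return len(self.cycle) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": self.cycle, "age": self.age, "alive": self.alive,
            "dead": self.dead, "inc_ocs": self.inc_ocs, "inc_ed": self.inc_ed,
            "inc_hosp": self.inc_hosp, "frac_on_treatment": self.frac_on_treatment,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Vectorized propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EngineContext:
    """Inputs shared by every evaluation of one (scenario, life table) pair."""

    p_bg: np.ndarray   # background death probability per cycle, length k_max
    ages: np.ndarray   # start-of-cycle ages, length k_max + 1
    k_max: int
    cycle_days: float
    waning_cycle: int


def prepare_context(
    params: ParameterSet, scenario: ScenarioSpec, life_table: LifeTable
) -> EngineContext:
    """Precompute the per-cycle background-mortality stream and age grid."""
    scenario.validate_against(life_table)
    cycle_days = params.econ.cycle_days
    cycles_per_year = DAYS_PER_YEAR / cycle_days
    k_terminal = int(math.ceil((life_table.terminal_age + 1 - scenario.start_age)
                               * cycles_per_year))
    k_max = k_terminal
    if scenario.horizon != "lifetime":
        k_max = min(k_max, int(scenario.horizon))
    ages = scenario.start_age + np.arange(k_max + 1) * (cycle_days / DAYS_PER_YEAR)
    qx = life_table.blended_qx(scenario.female_fraction)
    age_idx = np.minimum(np.floor(ages[:-1]).astype(int), life_table.terminal_age)
    annual_q = qx.reindex(age_idx).to_numpy()
    p_bg = annual_q_to_cycle_q(annual_q, cycle_days)
    return EngineContext(p_bg=p_bg, ages=ages, k_max=k_max,
                         cycle_days=cycle_days,
                         waning_cycle=params.adherence.waning_cycle)


def _propagate(p_events: np.ndarray, p_bg: np.ndarray, case_fatality: float):
    """Run one homogeneous sub-cohort.

    ``p_events`` is (3,) or (K, 3).  Returns (alive[K+1], inc[K, 3]) as
    proportions of the starting cohort.
    """
    K = len(p_bg)
    pe = np.broadcast_to(np.asarray(p_events, dtype=float), (K, 3))
    surv_factor = (1.0 - p_bg) * (1.0 - pe[:, 2] * case_fatality)
    alive = np.empty(K + 1)
    alive[0] = 1.0
    np.cumprod(surv_factor, out=alive[1:])
    at_risk = alive[:K] * (1.0 - p_bg)
    inc = at_risk[:, None] * pe
    return alive, inc


def _pad_terminal(arr: np.ndarray, n: int, fill: float | None = None) -> np.ndarray:
    if len(arr) >= n:
        return arr
    pad_value = arr[-1] if fill is None else fill
    return np.concatenate([arr, np.full(n - len(arr), pad_value)])


def blend_adherence(
    adherent: CohortTrace, reverted: CohortTrace, adherence: AdherenceSpec
) -> CohortTrace:
    """Occupancy-weighted mixture of the adherent and reverted sub-cohorts.

    A fraction ``f`` of the add-on cohort reverts to comparator inputs at the
    waning cycle; the blend is computed as ``adherent + f*(reverted -
    adherent)`` so identical sub-cohorts blend to themselves bit-for-bit.
    """
    f = adherence.discontinuation_fraction.base
    if not (0.0 <= f <= 1.0):
        raise ParameterError(f"discontinuation fraction must be in [0, 1], got {f}")
    n = max(len(adherent.cycle), len(reverted.cycle))

    def col(trace: CohortTrace, name: str, fill=None) -> np.ndarray:
        return _pad_terminal(getattr(trace, name), n, fill)

    blended: dict[str, np.ndarray] = {}
    for name in ("alive", "dead"):
        a, r = col(adherent, name), col(reverted, name)
        blended[name] = a + f * (r - a)
    for name in ("inc_ocs", "inc_ed", "inc_hosp"):
        a, r = col(adherent, name, 0.0), col(reverted, name, 0.0)
        blended[name] = a + f * (r - a)

    cycles = np.arange(n)
    alive_a = col(adherent, "alive")
    alive_r = col(reverted, "alive")
    on_mass = (1.0 - f) * alive_a * col(adherent, "frac_on_treatment") \
        + f * alive_r * col(reverted, "frac_on_treatment")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_on = np.where(blended["alive"] > 0.0, on_mass / blended["alive"], 0.0)
    ages = _pad_terminal(adherent.age, n) if len(adherent.age) >= len(reverted.age) \
        else _pad_terminal(reverted.age, n)
    return CohortTrace(
        strategy=adherent.strategy, cycle=cycles, age=ages,
        frac_on_treatment=frac_on, **blended,
    )


def _extinction_cycle(alive: np.ndarray) -> int:
    below = np.nonzero(alive < EXTINCTION_TOL)[0]
    return int(below[0]) if len(below) else len(alive) - 1


def _make_trace(strategy, ctx, alive, inc, frac_on) -> CohortTrace:
    k_end = max(_extinction_cycle(alive), 1)
    rows = k_end + 1
    inc_full = np.zeros((rows, 3))
    inc_full[:k_end] = inc[:k_end]
    return CohortTrace(
        strategy=strategy,
        cycle=np.arange(rows),
        age=ctx.ages[:rows],
        alive=alive[:rows],
        dead=1.0 - alive[:rows],
        inc_ocs=inc_full[:, 0],
        inc_ed=inc_full[:, 1],
        inc_hosp=inc_full[:, 2],
        frac_on_treatment=frac_on[:rows],
    )


def run_cohort(
    params: ParameterSet,
    strategy: str,
    scenario: ScenarioSpec,
    life_table: LifeTable,
    ctx: EngineContext | None = None,
) -> CohortTrace:
    """Propagate the cohort over the horizon and record the trace.

    The run stops at the terminal life-table age, the scenario horizon, or
    when the alive mass drops below :data:`EXTINCTION_TOL`, whichever comes
    first.
    """
    strategy = normalize_strategy(strategy)
    if ctx is None:
        ctx = prepare_context(params, scenario, life_table)
    cf = params.events.asthma_case_fatality_hosp
    p_off = _event_probabilities(params, on_treatment=False)

    if strategy == "comparator":
        alive, inc = _propagate(p_off, ctx.p_bg, cf)
        frac_on = np.zeros(ctx.k_max + 1)
        return _make_trace(strategy, ctx, alive, inc, frac_on)

    p_on = _event_probabilities(params, on_treatment=True)
    wc = min(ctx.waning_cycle, ctx.k_max)
    f = params.adherence.discontinuation_fraction.base
    if not (0.0 <= f <= 1.0):
        raise ParameterError(f"discontinuation fraction must be in [0, 1], got {f}")

    alive_a, inc_a = _propagate(p_on, ctx.p_bg, cf)
    p_rev = np.where(np.arange(ctx.k_max)[:, None] < wc, p_on, p_off)
    alive_r, inc_r = _propagate(p_rev, ctx.p_bg, cf)

    alive = alive_a + f * (alive_r - alive_a)
    inc = inc_a + f * (inc_r - inc_a)
    on_treated = np.ones(ctx.k_max + 1)
    on_reverted = (np.arange(ctx.k_max + 1) < wc).astype(float)
    on_mass = (1.0 - f) * alive_a * on_treated + f * alive_r * on_reverted
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_on = np.where(alive > 0.0, on_mass / alive, 0.0)
    return _make_trace(strategy, ctx, alive, inc, frac_on)


# ---------------------------------------------------------------------------
# Individual-level test oracle
# ---------------------------------------------------------------------------


def oracle_simulate(
    params: ParameterSet,
    strategy: str,
    scenario: ScenarioSpec,
    life_table: LifeTable,
    n_individuals: int,
    rng: np.random.Generator,
) -> CohortTrace:
    """Stochastic individual-level counterpart of :func:`run_cohort`.

    Simulates ``n_individuals`` exchangeable patients event-by-event with the
    same per-cycle probabilities (aggregated as exact binomial/multinomial
    counts) and returns the empirical trace.  Test oracle only, not a
    production engine.
    """
    strategy = normalize_strategy(strategy)
    if n_individuals < 1:
        raise ParameterError("need at least one simulated individual")
    ctx = prepare_context(params, scenario, life_table)
    cf = params.events.asthma_case_fatality_hosp
    p_off = _event_probabilities(params, on_treatment=False)
    p_on = _event_probabilities(params, on_treatment=True)
    wc = min(ctx.waning_cycle, ctx.k_max)
    f = params.adherence.discontinuation_fraction.base

    if strategy == "comparator":
        groups = [(n_individuals, None)]  # (count, None) => comparator probs always
    else:
        n_adherent = int(rng.binomial(n_individuals, 1.0 - f))
        groups = [(n_adherent, "adherent"), (n_individuals - n_adherent, "reverted")]

    K = ctx.k_max
    alive_counts = np.zeros((K + 1,), dtype=np.int64)
    on_counts = np.zeros((K + 1,), dtype=np.int64)
    inc_counts = np.zeros((K, 3), dtype=np.int64)

    for count, role in groups:
        alive = count
        for k in range(K + 1):
            on_drug = role == "adherent" or (role == "reverted" and k < wc)
            alive_counts[k] += alive
            if on_drug:
                on_counts[k] += alive
            if k == K or alive == 0:
                continue
            p = p_on if on_drug else p_off
            deaths_bg = rng.binomial(alive, ctx.p_bg[k])
            survivors = alive - deaths_bg
            channel_p = np.append(p, 1.0 - p.sum())
            events = rng.multinomial(survivors, channel_p)
            inc_counts[k] += events[:3]
            deaths_asthma = rng.binomial(events[2], cf)
            alive = survivors - deaths_asthma

    n = float(n_individuals)
    alive_prop = alive_counts / n
    inc_full = np.zeros((K + 1, 3))
    inc_full[:K] = inc_counts / n
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_on = np.where(alive_counts > 0, on_counts / np.maximum(alive_counts, 1), 0.0)
    return CohortTrace(
        strategy=strategy,
        cycle=np.arange(K + 1),
        age=ctx.ages,
        alive=alive_prop,
        dead=1.0 - alive_prop,
        inc_ocs=inc_full[:, 0],
        inc_ed=inc_full[:, 1],
        inc_hosp=inc_full[:, 2],
        frac_on_treatment=frac_on,
    )
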