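"""Discounted lifetime costs and QALYs, ICER and net monetary benefit.

Per-cycle rewards are read off the cohort trace: the annual controlled-state
cost and utility are prorated by cycle length, event costs attach to the
cycle's incidence, utility decrements apply for one cycle's person-time per
event, and the drug cost (priced per 4-week pack) is prorated to the model
cycle for the on-treatment fraction.  Totals apply a half-cycle correction as
trapezoidal end-weights (1/2, 1, ..., 1, 1/2) together with per-cycle
discounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace
from .params import DAYS_PER_YEAR, ParameterError, ParameterSet

logger = logging.getLogger(__name__)

#: Pricing period of the drug cost row ("per 4-week cycle").
DRUG_PRICE_DAYS = 28.0


def discount_factor(cycle, annual_rate: float, cycle_days: float):
    """``(1 + rate)**(-cycle * cycle_days/365.25)``; cycle 0 maps to 1."""
    if annual_rate < 0:
        raise ParameterError(f"discount rate must be non-negative, got {annual_rate}")
    k = np.asarray(cycle, dtype=float)
    out = (1.0 + annual_rate) ** (-k * cycle_days / DAYS_PER_YEAR)
    return float(out) if np.ndim(cycle) == 0 else out


def half_cycle_weights(n_rows: int) -> np.ndarray:
    """Trapezoidal end-weights: 1/2 on the first and last record, 1 elsewhere."""
    if n_rows < 1:
        raise ParameterError("need at least one trace record")
    w = np.ones(n_rows)
    w[0] = 0.5
    w[-1] = 0.5
    return w


def reward_streams(trace: CohortTrace, params: ParameterSet):
    """Undiscounted per-record (cost, qaly) streams for a trace.

    Negative per-cycle QALYs (possible only with extreme sampled decrements)
    are clamped to zero with a warning.
    """
    c, u, econ = params.costs, params.utilities, params.econ
    f_year = econ.cycle_days / DAYS_PER_YEAR
    cost = (
        trace.alive * c.controlled_state_annual.base * f_year
        + trace.inc_ocs * c.ocs_burst_per_episode.base
        + trace.inc_ed * c.ed_visit_per_episode.base
        + trace.inc_hosp * c.hospitalization_per_episode.base
        + trace.frac_on_treatment * trace.alive
        * c.drug_per_4wk.base * (econ.cycle_days / DRUG_PRICE_DAYS)
    )
    qaly = (
        trace.alive * u.controlled.base
        - trace.inc_ocs * u.decrement_ocs.base
        - trace.inc_ed * u.decrement_ed.base
        - trace.inc_hosp * u.decrement_hosp.base
    ) * f_year
    if np.any(qaly < 0.0):
        logger.warning("negative per-cycle QALY clamped to 0 (extreme decrements)")
        qaly = np.maximum(qaly, 0.0)
    return cost, qaly


def cycle_rewards(record, params: ParameterSet, strategy: str | None = None):
    """(cost, qaly) for a single trace record (mapping with the trace fields)."""
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    one = np.array([1.0])
    mini = CohortTrace(
        strategy=strategy or "comparator",
        cycle=np.array([int(get("cycle"))]) if _has(record, "cycle") else np.array([0]),
        age=np.array([float(get("age"))]) if _has(record, "age") else np.array([0.0]),
        alive=np.array([float(get("alive"))]),
        dead=one - np.array([float(get("alive"))]),
        inc_ocs=np.array([float(get("inc_ocs"))]),
        inc_ed=np.array([float(get("inc_ed"))]),
        inc_hosp=np.array([float(get("inc_hosp"))]),
        frac_on_treatment=np.array([float(get("frac_on_treatment"))]),
    )
    cost, qaly = reward_streams(mini, params)
    return float(cost[0]), float(qaly[0])


def _has(record, key) -> bool:
    try:
        if hasattr(record, "get"):
            return record.get(key) is not None
        return hasattr(record, key)
    except Exception:
        return False


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime totals for one strategy (one base case or one PSA draw)."""

    strategy: str
    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    cost_stream: np.ndarray
    qaly_stream: np.ndarray


def accumulate_strategy(
    trace: CohortTrace, params: ParameterSet, strategy: str | None = None
) -> StrategyResult:
    """Half-cycle-corrected, discounted lifetime totals for one trace."""
    cost, qaly = reward_streams(trace, params)
    w = half_cycle_weights(len(cost))
    df = discount_factor(trace.cycle, params.econ.annual_discount_rate.base,
                         params.econ.cycle_days)
    return StrategyResult(
        strategy=strategy or trace.strategy,
        discounted_cost=float(np.sum(w * df * cost)),
        discounted_qaly=float(np.sum(w * df * qaly)),
        undiscounted_cost=float(np.sum(w * cost)),
        undiscounted_qaly=float(np.sum(w * qaly)),
        cost_stream=cost,
        qaly_stream=qaly,
    )


# ---------------------------------------------------------------------------
# Decision statistics
# ---------------------------------------------------------------------------

LABEL_RATIO = "ratio"
LABEL_EQUIVALENT = "equivalent"
LABEL_COST_ONLY = "undefined (cost-only difference)"


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return "equivalent"
    if delta_qaly >= 0.0 and delta_cost <= 0.0:
        return "dominant (cheaper, more effective)"
    if delta_qaly <= 0.0 and delta_cost >= 0.0:
        return "dominated (costlier, less effective)"
    if delta_qaly > 0.0:
        return "trade-off (costlier, more effective)"
    return "trade-off (cheaper, less effective)"


@dataclass(frozen=True)
class IcerEstimate:
    """ICER value (when defined) with its dominance label and CE-plane quadrant."""

    value: float | None
    label: str
    quadrant: str

    def __str__(self) -> str:
        if self.value is None:
            return f"{self.label} [{self.quadrant}]"
        return f"{self.value:,.2f} US$/QALY [{self.quadrant}]"


def icer(delta_cost: float, delta_qaly: float) -> IcerEstimate:
    """Incremental cost-effectiveness ratio with dominance handling.

    A zero QALY difference yields a label instead of a ratio; the CE-plane
    quadrant (dominant / dominated / trade-off) is always reported.
    """
    quadrant = _quadrant(delta_cost, delta_qaly)
    if delta_qaly == 0.0:
        if delta_cost == 0.0:
            return IcerEstimate(None, LABEL_EQUIVALENT, quadrant)
        return IcerEstimate(None, LABEL_COST_ONLY, quadrant)
    return IcerEstimate(delta_cost / delta_qaly, LABEL_RATIO, quadrant)


def nmb(qaly: float, cost: float, wtp: float) -> float:
    """Net monetary benefit: ``qaly * wtp - cost``."""
    if wtp <= 0:
        raise ParameterError(f"willingness-to-pay must be positive, got {wtp}")
    return qaly * wtp - cost


def net_benefit_effects_scale(qaly: float, cost: float, wtp: float) -> float:
    """Net benefit expressed in QALYs: ``nmb / wtp``."""
    return nmb(qaly, cost, wtp) / wtp


@dataclass(frozen=True)
class IncrementalResult:
    """Add-on versus comparator decision statistics at one willingness-to-pay."""

    delta_cost: float
    delta_qaly: float
    icer: IcerEstimate
    wtp: float
    nmb_comparator: float
    nmb_add_on: float
    incremental_nmb: float
    nb_effects_comparator: float
    nb_effects_add_on: float

    @classmethod
    def from_strategies(
        cls, comparator: StrategyResult, add_on: StrategyResult, wtp: float
    ) -> "IncrementalResult":
        dc = add_on.discounted_cost - comparator.discounted_cost
        de = add_on.discounted_qaly - comparator.discounted_qaly
        nmb_c = nmb(comparator.discounted_qaly, comparator.discounted_cost, wtp)
        nmb_a = nmb(add_on.discounted_qaly, add_on.discounted_cost, wtp)
        return cls(
            delta_cost=dc, delta_qaly=de, icer=icer(dc, de), wtp=wtp,
            nmb_comparator=nmb_c, nmb_add_on=nmb_a, incremental_nmb=nmb_a - nmb_c,
            nb_effects_comparator=nmb_c / wtp, nb_effects_add_on=nmb_a / wtp,
        )
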