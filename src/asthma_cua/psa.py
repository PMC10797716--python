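"""Probabilistic and deterministic sensitivity analysis.

The PSA is a second-order Monte Carlo: each replication samples one parameter
set (common random parameters) and evaluates *both* strategies under it, so
incremental statistics are within-replication differences.  Summaries follow
the usual decision-analytic conventions: the ICER of mean increments,
empirical 2.5/97.5 centiles with linear interpolation, decision
probabilities, the cost-effectiveness acceptability curve, and a one-way
tornado over every ranged parameter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import EngineContext, prepare_context, run_cohort
from .fixtures import ScenarioSpec
from .lifetable import LifeTable
from .outcomes import (
    IcerEstimate,
    IncrementalResult,
    StrategyResult,
    accumulate_strategy,
    icer,
)
from .params import (
    ParameterError,
    ParameterSet,
    ParameterValidationError,
    build_sampling_plan,
    sample_parameter_set,
    validate_parameter_set,
)

logger = logging.getLogger(__name__)

#: Default λ grid: 0 to 3x the base willingness-to-pay in 101 points.
CEAC_GRID_POINTS = 101
CEAC_GRID_MAX_MULTIPLE = 3.0

#: Parameters varied one at a time in the tornado analysis.
DSA_PARAMETERS = (
    "costs.drug_per_4wk",
    "costs.controlled_state_annual",
    "costs.ocs_burst_per_episode",
    "costs.ed_visit_per_episode",
    "costs.hospitalization_per_episode",
    "utilities.controlled",
    "utilities.decrement_ocs",
    "utilities.decrement_ed",
    "utilities.decrement_hosp",
    "effect.rr_exacerbation",
    "events.exacerbation_annual_rate",
    "adherence.discontinuation_fraction",
    "econ.annual_discount_rate",
)


def parameter_digest(params: ParameterSet) -> str:
    """Stable sha256 digest of the full parameter set (for run manifests)."""
    canonical = json.dumps(params.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def evaluate_strategies(
    params: ParameterSet,
    scenario: ScenarioSpec,
    life_table: LifeTable,
    ctx: EngineContext | None = None,
) -> tuple[StrategyResult, StrategyResult]:
    """Deterministic (comparator, add-on) lifetime results for one parameter set."""
    if ctx is None:
        ctx = prepare_context(params, scenario, life_table)
    comp = accumulate_strategy(
        run_cohort(params, "comparator", scenario, life_table, ctx=ctx), params,
        strategy=scenario.label_comparator,
    )
    addon = accumulate_strategy(
        run_cohort(params, "add_on", scenario, life_table, ctx=ctx), params,
        strategy=scenario.label_add_on,
    )
    return comp, addon


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

_DRAW_COLUMNS = (
    "draw", "cost_comparator", "qaly_comparator", "cost_addon", "qaly_addon",
    "dc", "de", "nmb_inc",
)


@dataclass(frozen=True)
class PsaResult:
    """The raw draws of one PSA run plus everything needed to reproduce it."""

    draws: pd.DataFrame
    seed: int | None
    n_runs: int
    wtp: float
    params_digest: str

    def summary(self, wtp: float | None = None) -> "PsaSummary":
        return summarize_psa(self.draws, wtp if wtp is not None else self.wtp)

    def ceac(self, grid: np.ndarray | None = None, wtp: float | None = None) -> "CeacCurve":
        wtp = wtp if wtp is not None else self.wtp
        if grid is None:
            grid = np.linspace(0.0, CEAC_GRID_MAX_MULTIPLE * wtp, CEAC_GRID_POINTS)
        return ceac(self.draws, grid)

    def ce_plane(self) -> pd.DataFrame:
        """CE-plane scatter data: one (dE, dC) pair per draw."""
        return self.draws[["de", "dc"]].copy()

    def write_csv(self, path) -> None:
        self.draws[list(_DRAW_COLUMNS)].to_csv(path, index=False)


def run_psa(
    params: ParameterSet,
    scenario: ScenarioSpec,
    life_table: LifeTable,
    n_runs: int = 10_000,
    seed: int | None = None,
    wtp: float | None = None,
) -> PsaResult:
    """Second-order Monte Carlo over the parameter distributions.

    Every replication applies one sampled parameter set to both strategies.
    Fully reproducible from ``seed``; infeasible distributions surface before
    the first draw.
    """
    if n_runs < 1:
        raise ParameterError(f"n_runs must be >= 1, got {n_runs}")
    violations = validate_parameter_set(params)
    if violations:
        raise ParameterValidationError(violations)
    wtp = wtp if wtp is not None else params.econ.wtp_per_qaly
    plan = build_sampling_plan(params)  # raises on infeasible fits
    ctx = prepare_context(params, scenario, life_table)
    rng = np.random.default_rng(seed)

    records = np.empty((n_runs, 7))
    sampled = np.empty((n_runs, len(plan)))
    for i in range(n_runs):
        draw = sample_parameter_set(params, rng, plan=plan)
        sampled[i] = [draw.point(item.path).base if "." in item.path else np.nan
                      for item in plan]
        comp, addon = evaluate_strategies(draw, scenario, life_table, ctx=ctx)
        dc = addon.discounted_cost - comp.discounted_cost
        de = addon.discounted_qaly - comp.discounted_qaly
        records[i] = (comp.discounted_cost, comp.discounted_qaly,
                      addon.discounted_cost, addon.discounted_qaly,
                      dc, de, de * wtp - dc)

    draws = pd.DataFrame(records, columns=[
        "cost_comparator", "qaly_comparator", "cost_addon", "qaly_addon",
        "dc", "de", "nmb_inc"])
    draws.insert(0, "draw", np.arange(n_runs))
    for j, item in enumerate(plan):
        draws[f"par_{item.path.replace('.', '_')}"] = sampled[:, j]
    if not np.isfinite(records).all():
        raise ParameterError("non-finite PSA results; check parameter ranges")
    return PsaResult(draws=draws, seed=seed, n_runs=n_runs, wtp=wtp,
                     params_digest=parameter_digest(params))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaSummary:
    """Incremental and absolute PSA statistics at one willingness-to-pay."""

    n_runs: int
    wtp: float
    mean_delta_cost: float
    mean_delta_qaly: float
    icer_of_means: IcerEstimate
    ci_delta_cost: tuple[float, float]
    ci_delta_qaly: tuple[float, float]
    p_cost_saving: float
    p_more_effective: float
    p_cost_effective: float
    mean_cost: dict[str, float]
    mean_qaly: dict[str, float]
    expected_nmb: dict[str, float]
    ci_nmb: dict[str, tuple[float, float]]
    nb_effects: dict[str, float]
    ci_nb_effects: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        d = {
            "n_runs": self.n_runs,
            "wtp": self.wtp,
            "mean_delta_cost": self.mean_delta_cost,
            "mean_delta_qaly": self.mean_delta_qaly,
            "icer_of_means": None if self.icer_of_means.value is None
            else self.icer_of_means.value,
            "icer_label": self.icer_of_means.label,
            "icer_quadrant": self.icer_of_means.quadrant,
            "ci_delta_cost": list(self.ci_delta_cost),
            "ci_delta_qaly": list(self.ci_delta_qaly),
            "p_cost_saving": self.p_cost_saving,
            "p_more_effective": self.p_more_effective,
            "p_cost_effective": self.p_cost_effective,
        }
        for name in ("mean_cost", "mean_qaly", "expected_nmb", "nb_effects"):
            d[name] = dict(getattr(self, name))
        d["ci_nmb"] = {k: list(v) for k, v in self.ci_nmb.items()}
        d["ci_nb_effects"] = {k: list(v) for k, v in self.ci_nb_effects.items()}
        return d


def _quantiles(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.quantile(x, [0.025, 0.975], method="linear")
    return float(lo), float(hi)


def summarize_psa(draws, wtp: float) -> PsaSummary:
    """Decision statistics from the raw draws at a willingness-to-pay λ.

    ``P(cost-effective)`` is the fraction of draws with incremental net
    monetary benefit ``de*λ - dc > 0``, the same functional the CEAC uses,
    so the two agree exactly at λ.
    """
    if isinstance(draws, PsaResult):
        draws = draws.draws
    if len(draws) < 2:
        raise ParameterError("need at least two draws for centile reporting")
    dc = draws["dc"].to_numpy()
    de = draws["de"].to_numpy()
    nmb_inc = de * wtp - dc
    comp_cost = draws["cost_comparator"].to_numpy()
    comp_qaly = draws["qaly_comparator"].to_numpy()
    addon_cost = draws["cost_addon"].to_numpy()
    addon_qaly = draws["qaly_addon"].to_numpy()
    names = ("comparator", "add_on")
    costs = {"comparator": comp_cost, "add_on": addon_cost}
    qalys = {"comparator": comp_qaly, "add_on": addon_qaly}
    mean_cost = {k: float(np.mean(v)) for k, v in costs.items()}
    mean_qaly = {k: float(np.mean(v)) for k, v in qalys.items()}
    expected_nmb = {k: mean_qaly[k] * wtp - mean_cost[k] for k in names}
    nmb_draws = {k: qalys[k] * wtp - costs[k] for k in names}
    return PsaSummary(
        n_runs=len(draws),
        wtp=float(wtp),
        mean_delta_cost=float(np.mean(dc)),
        mean_delta_qaly=float(np.mean(de)),
        icer_of_means=icer(float(np.mean(dc)), float(np.mean(de))),
        ci_delta_cost=_quantiles(dc),
        ci_delta_qaly=_quantiles(de),
        p_cost_saving=float(np.mean(dc < 0.0)),
        p_more_effective=float(np.mean(de > 0.0)),
        p_cost_effective=float(np.mean(nmb_inc > 0.0)),
        mean_cost=mean_cost,
        mean_qaly=mean_qaly,
        expected_nmb=expected_nmb,
        ci_nmb={k: _quantiles(nmb_draws[k]) for k in names},
        nb_effects={k: expected_nmb[k] / wtp for k in names},
        ci_nb_effects={k: _quantiles(nmb_draws[k] / wtp) for k in names},
    )


@dataclass(frozen=True)
class CeacCurve:
    """Probability the add-on strategy is cost-effective across λ."""

    lam: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        idx = np.nonzero(np.isclose(self.lam, wtp))[0]
        if not len(idx):
            raise ParameterError(f"λ={wtp} not on the CEAC grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lam, "probability": self.probability})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ceac(draws, grid) -> CeacCurve:
    """Acceptability curve: ``P(de*λ - dc > 0)`` at each grid value.

    At λ=0 this is ``P(dC < 0)``; as λ grows it tends to ``P(dE > 0)``.
    """
    if isinstance(draws, PsaResult):
        draws = draws.draws
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ParameterError("λ grid values must be non-negative")
    dc = draws["dc"].to_numpy()
    de = draws["de"].to_numpy()
    prob = np.array([float(np.mean(de * lam - dc > 0.0)) for lam in grid])
    return CeacCurve(lam=grid, probability=prob)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DsaResult:
    """Tornado table plus the base-case incremental result it perturbs."""

    table: pd.DataFrame
    base: IncrementalResult
    wtp: float

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def one_way_dsa(
    params: ParameterSet,
    scenario: ScenarioSpec,
    life_table: LifeTable,
    wtp: float | None = None,
    parameters: tuple[str, ...] = DSA_PARAMETERS,
) -> DsaResult:
    """Vary each ranged parameter to its lower and upper bound in turn.

    All other parameters stay at base; both strategies are re-run
    deterministically and the incremental net monetary benefit (and ICER) at
    each endpoint is recorded.  Rows are ordered by tornado bar width,
    ``|NMB(high) - NMB(low)|``, descending.
    """
    wtp = wtp if wtp is not None else params.econ.wtp_per_qaly
    base_comp, base_addon = evaluate_strategies(params, scenario, life_table)
    base = IncrementalResult.from_strategies(base_comp, base_addon, wtp)

    rows = []
    for path in parameters:
        pr = params.point(path)
        endpoint_nmb = {}
        endpoint_icer = {}
        for side, value in (("low", pr.lower), ("high", pr.upper)):
            varied = params.replace_base(path, value)
            comp, addon = evaluate_strategies(varied, scenario, life_table)
            inc = IncrementalResult.from_strategies(comp, addon, wtp)
            endpoint_nmb[side] = inc.incremental_nmb
            endpoint_icer[side] = inc.icer.value
        rows.append({
            "parameter": path,
            "low_value": pr.lower,
            "high_value": pr.upper,
            "nmb_low": endpoint_nmb["low"],
            "nmb_high": endpoint_nmb["high"],
            "icer_low": endpoint_icer["low"],
            "icer_high": endpoint_icer["high"],
            "width": abs(endpoint_nmb["high"] - endpoint_nmb["low"]),
        })
    table = pd.DataFrame(rows).sort_values("width", ascending=False, ignore_index=True)
    return DsaResult(table=table, base=base, wtp=wtp)
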