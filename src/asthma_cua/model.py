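"""Model/results facade for the cost-utility analysis.

:class:`CostUtilityModel` bundles a parameter set, a life table and a
scenario; ``run()`` evaluates the deterministic base case, ``run_psa()`` the
probabilistic sensitivity analysis and ``one_way_dsa()`` the tornado.  Each
returns a results object with a ``summary()`` suitable for the console.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .engine import CohortTrace, prepare_context, run_cohort
from .fixtures import ScenarioSpec, default_scenario, table1_fixture
from .lifetable import LifeTable, synthetic_life_table
from .outcomes import IncrementalResult, StrategyResult
from .params import ParameterSet, load_parameter_set
from .psa import DsaResult, PsaResult, evaluate_strategies, one_way_dsa, run_psa


@dataclass(frozen=True)
class BaseCaseResult:
    """Deterministic lifetime results for both strategies."""

    comparator: StrategyResult
    add_on: StrategyResult
    incremental: IncrementalResult
    traces: dict[str, CohortTrace]

    def summary(self) -> str:
        inc = self.incremental
        lines = [
            "Base-case cost-utility results (discounted, lifetime horizon)",
            "=" * 62,
            f"{'':32s}{'cost (US$)':>14s}{'QALYs':>14s}",
            f"{self.comparator.strategy:32s}{self.comparator.discounted_cost:14.2f}"
            f"{self.comparator.discounted_qaly:14.4f}",
            f"{self.add_on.strategy:32s}{self.add_on.discounted_cost:14.2f}"
            f"{self.add_on.discounted_qaly:14.4f}",
            "-" * 62,
            f"Incremental cost (US$):        {inc.delta_cost:14.2f}",
            f"Incremental QALYs:             {inc.delta_qaly:14.4f}",
            f"ICER:                          {inc.icer}",
            f"NMB at US${inc.wtp:g}/QALY:    comparator {inc.nmb_comparator:.2f}, "
            f"add-on {inc.nmb_add_on:.2f}",
            f"Incremental NMB:               {inc.incremental_nmb:14.2f}",
        ]
        return "\n".join(lines)


class CostUtilityModel:
    """Markov cohort cost-utility model of add-on therapy versus standard care.

    Parameters default to the packaged base-case inputs, the life table to
    the synthetic Gompertz–Makeham table and the scenario to an adult cohort
    entering at age 18 over a lifetime horizon.

    Examples
    --------
    >>> model = CostUtilityModel()
    >>> print(model.run().summary())          # doctest: +SKIP
    >>> psa = model.run_psa(n_runs=1000, seed=7)
    >>> psa.summary().p_cost_effective        # doctest: +SKIP
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        life_table: LifeTable | None = None,
        scenario: ScenarioSpec | None = None,
    ):
        self.params = params if params is not None else table1_fixture()
        self.life_table = life_table if life_table is not None else synthetic_life_table()
        self.scenario = scenario if scenario is not None else default_scenario()
        self.scenario.validate_against(self.life_table)

    @classmethod
    def from_config(cls, source: str | Path | Mapping[str, Any]) -> "CostUtilityModel":
        """Build from a YAML document with optional ``scenario`` / ``life_table`` sections.

        Every other top-level section is treated as a parameter override and
        merged onto the packaged defaults.
        """
        if isinstance(source, (str, Path)):
            doc = yaml.safe_load(Path(source).read_text()) or {}
        else:
            doc = dict(source)
        scenario_doc = doc.pop("scenario", {})
        life_table_doc = doc.pop("life_table", {})
        params = load_parameter_set(doc or None)
        scenario = ScenarioSpec(**scenario_doc) if scenario_doc else default_scenario()
        if isinstance(life_table_doc, (str, Path)) and life_table_doc:
            life_table = LifeTable.read_csv(life_table_doc)
        elif life_table_doc:
            life_table = synthetic_life_table(**life_table_doc)
        else:
            life_table = synthetic_life_table()
        return cls(params=params, life_table=life_table, scenario=scenario)

    # -- analyses ----------------------------------------------------------

    def run(self) -> BaseCaseResult:
        """Deterministic base case: both cohorts, discounted lifetime totals."""
        ctx = prepare_context(self.params, self.scenario, self.life_table)
        traces = {
            "comparator": run_cohort(self.params, "comparator", self.scenario,
                                     self.life_table, ctx=ctx),
            "add_on": run_cohort(self.params, "add_on", self.scenario,
                                 self.life_table, ctx=ctx),
        }
        comp, addon = evaluate_strategies(self.params, self.scenario,
                                          self.life_table, ctx=ctx)
        inc = IncrementalResult.from_strategies(comp, addon,
                                                self.params.econ.wtp_per_qaly)
        return BaseCaseResult(comparator=comp, add_on=addon, incremental=inc,
                              traces=traces)

    def run_psa(
        self, n_runs: int = 10_000, seed: int | None = None, wtp: float | None = None
    ) -> PsaResult:
        return run_psa(self.params, self.scenario, self.life_table,
                       n_runs=n_runs, seed=seed, wtp=wtp)

    def one_way_dsa(self, wtp: float | None = None) -> DsaResult:
        return one_way_dsa(self.params, self.scenario, self.life_table, wtp=wtp)
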