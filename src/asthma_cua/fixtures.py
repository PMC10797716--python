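"""Packaged fixtures: the base-case parameter set and the default scenario.

Everything the analysis needs ships with the package so no external data is
required: :func:`table1_fixture` returns the frozen base-case inputs and
:func:`asthma_cua.lifetable.synthetic_life_table` stands in for the national
life tables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lifetable import LifeTable
from .params import ParameterError, ParameterSet, load_parameter_set

STRATEGY_COMPARATOR = "ICS+LABA"
STRATEGY_ADD_ON = "tiotropium+ICS+LABA"


@dataclass(frozen=True)
class ScenarioSpec:
    """Cohort composition and horizon for one model run.

    The modelled population is adults (> 18 years) with severe asthma; the
    source does not state an age distribution or sex mix, so the cohort
    enters at age 18 with a 50/50 sex mix by declared default.  ``horizon``
    is a cycle count or ``"lifetime"`` (run to the terminal life-table age or
    cohort extinction).
    """

    start_age: float = 18.0
    female_fraction: float = 0.5
    horizon: int | str = "lifetime"
    label_comparator: str = STRATEGY_COMPARATOR
    label_add_on: str = STRATEGY_ADD_ON

    def __post_init__(self) -> None:
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ParameterError(f"female fraction must be in [0, 1], got {self.female_fraction}")
        if isinstance(self.horizon, str):
            if self.horizon != "lifetime":
                raise ParameterError(f"horizon must be 'lifetime' or a cycle count, got {self.horizon!r}")
        elif self.horizon < 1:
            raise ParameterError(f"horizon must be >= 1 cycle, got {self.horizon}")

    def validate_against(self, life_table: LifeTable) -> None:
        if not (life_table.start_age <= self.start_age <= life_table.terminal_age):
            raise ParameterError(
                f"start age {self.start_age} outside life-table range "
                f"[{life_table.start_age}, {life_table.terminal_age}]"
            )


def table1_fixture() -> ParameterSet:
    """The frozen base-case parameter encoding shipped with the package."""
    return load_parameter_set(None)


def default_scenario() -> ScenarioSpec:
    return ScenarioSpec()
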