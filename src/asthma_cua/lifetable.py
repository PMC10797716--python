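"""Life tables: annual all-cause mortality by age and sex.

The published analysis uses national age- and sex-specific life tables that
are external data; :func:`synthetic_life_table` generates a plausible adult
stand-in from a Gompertz–Makeham hazard so the model never needs a download.
The cohort engine consumes a single annual-probability stream; sex-specific
tables are blended by the scenario's female fraction at each age.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import DAYS_PER_YEAR, ParameterError

logger = logging.getLogger(__name__)

SEXES = ("female", "male", "combined")

#: Relative all-cause hazard by sex around the combined-sex baseline.
SEX_HAZARD_FACTORS = {"combined": 1.0, "female": 0.80, "male": 1.25}


class LifeTableError(ValueError):
    """Malformed life table."""


def annual_q_to_cycle_q(qx, cycle_days: float):
    """Convert an annual death probability to the per-cycle probability.

    ``1 - (1 - qx)**(cycle_days/365.25)``: constant-hazard splitting of the
    year, so recompounding 365.25/cycle_days cycles recovers the annual value.
    Accepts scalars or arrays; 0 maps to 0 and 1 to 1.
    """
    if cycle_days <= 0:
        raise ParameterError(f"cycle_days must be positive, got {cycle_days}")
    q = np.asarray(qx, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ParameterError("annual death probability must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.expm1(np.log1p(-q) * (cycle_days / DAYS_PER_YEAR))
    out = np.where(q >= 1.0, 1.0, out)
    return float(out) if np.isscalar(qx) or np.ndim(qx) == 0 else out


@dataclass(frozen=True)
class LifeTable:
    """Rows of (age, sex, qx): annual probability of death.

    Ages must be contiguous per sex and the terminal-age qx must be 1 so any
    cohort is extinguished at the table's end.  Non-monotone qx is allowed
    (real tables wobble).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"age", "sex", "qx"}
        if not required.issubset(self.table.columns):
            raise LifeTableError(f"life table needs columns {sorted(required)}")
        df = self.table
        if df.empty:
            raise LifeTableError("life table is empty")
        bad = df[(df.qx < 0) | (df.qx > 1)]
        if len(bad):
            raise LifeTableError(f"qx outside [0, 1] at ages {bad.age.tolist()[:5]}")
        unknown = set(df.sex.unique()) - set(SEXES)
        if unknown:
            raise LifeTableError(f"unknown sex label(s): {sorted(unknown)}")
        for sex, grp in df.groupby("sex"):
            ages = grp.age.to_numpy()
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise LifeTableError(f"ages not contiguous for sex={sex!r}")
            if grp.qx.iloc[-1] != 1.0:
                raise LifeTableError(f"terminal qx must be 1 for sex={sex!r}")

    @property
    def start_age(self) -> int:
        return int(self.table.age.min())

    @property
    def terminal_age(self) -> int:
        return int(self.table.age.max())

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted(self.table.sex.unique()))

    def qx(self, sex: str = "combined") -> pd.Series:
        """Annual death probabilities for one sex, indexed by age."""
        grp = self.table[self.table.sex == sex]
        if grp.empty:
            raise LifeTableError(f"no rows for sex={sex!r}; table has {self.sexes}")
        return grp.set_index("age").qx

    def blended_qx(self, female_fraction: float = 0.5) -> pd.Series:
        """Single qx stream: sex-specific tables mixed at each age.

        Uses the combined-sex rows when present; otherwise blends female and
        male rows with the given female fraction.
        """
        if "combined" in self.sexes:
            return self.qx("combined")
        if not (0.0 <= female_fraction <= 1.0):
            raise ParameterError(f"female fraction must be in [0, 1], got {female_fraction}")
        qf, qm = self.qx("female"), self.qx("male")
        if not qf.index.equals(qm.index):
            raise LifeTableError("female and male tables cover different ages")
        return female_fraction * qf + (1.0 - female_fraction) * qm

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        df["age"] = df["age"].astype(int)
        df["qx"] = df["qx"].astype(float)
        return cls(df.sort_values(["sex", "age"]).reset_index(drop=True))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def synthetic_life_table(
    a: float = 5e-4,
    b: float = 3e-5,
    c: float = 0.09,
    start_age: int = 0,
    terminal_age: int = 100,
    sexes: tuple[str, ...] = ("combined",),
) -> LifeTable:
    """Gompertz–Makeham stand-in for a national adult life table.

    The annual hazard is ``a + b*exp(c*age)`` (scaled per sex by
    :data:`SEX_HAZARD_FACTORS`), so ``qx = 1 - exp(-(a + b*exp(c*age)))``,
    clipped to [0, 1] with a warning if the hazard explodes before the
    terminal age, whose qx is forced to 1.  Deterministic.
    """
    if a < 0 or b < 0 or c < 0:
        raise ParameterError("Makeham parameters must be non-negative")
    if terminal_age <= start_age:
        raise ParameterError("terminal age must exceed start age")
    ages = np.arange(start_age, terminal_age + 1)
    frames = []
    for sex in sexes:
        factor = SEX_HAZARD_FACTORS[sex]
        hazard = factor * (a + b * np.exp(c * ages.astype(float)))
        qx = -np.expm1(-hazard)
        if np.any(qx[:-1] >= 1.0):
            logger.warning("synthetic life table hazard saturates qx=1 before terminal age")
        qx = np.clip(qx, 0.0, 1.0)
        qx[-1] = 1.0
        frames.append(pd.DataFrame({"age": ages, "sex": sex, "qx": qx}))
    return LifeTable(pd.concat(frames, ignore_index=True))
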