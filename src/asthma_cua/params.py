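"""Model parameters: point values, sensitivity ranges and PSA distributions.

Every quantity of the cost-utility model carries a base-case value plus the
lower/upper range used in sensitivity analysis (a :class:`PointRange`).  The
probabilistic sensitivity analysis samples relative risk, utilities, utility
decrements, event probabilities and the discontinuation fraction from beta
distributions and costs from gamma distributions, each fitted by the method of
moments so that the distribution mean equals the base-case value and the
standard deviation equals (upper - lower)/3.92, i.e. the range is read as a
central 95% interval.

The annual exacerbation rate exceeds 1 and therefore cannot be beta-sampled on
its natural scale; it is sampled through its per-cycle probability parent,
``1 - exp(-rate * cycle_days/365.25)``, which lives in (0, 1), and
back-transformed to a rate.  A relative risk with an upper range >= 1 falls
back to a moment-matched log-normal with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, is_dataclass, replace
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

#: Width of a central 95% normal interval in standard deviations.
RANGE_Z = 3.92

#: Days per year used for all rate/discount/person-time conversions.
DAYS_PER_YEAR = 365.25


class ParameterError(ValueError):
    """Invalid parameter value or range."""


class InfeasibleDistributionError(ParameterError):
    """The requested mean/sd pair cannot be represented by the family."""


class ParameterValidationError(ParameterError):
    """A loaded parameter document violates one or more invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        msg = "; ".join(f"{v.field}: {v.rule} (got {v.value!r})" for v in violations)
        super().__init__(f"invalid parameter set: {msg}")


# ---------------------------------------------------------------------------
# Core value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointRange:
    """A base-case value with the lower/upper bounds used in one-way DSA.

    The ordering invariant ``lower <= base <= upper`` is enforced by
    :func:`validate_parameter_set` and at load time rather than at
    construction, because PSA draws replace ``base`` with sampled values that
    may legitimately fall outside the deterministic range (e.g. gamma tails).
    """

    base: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        for name in ("base", "lower", "upper"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"PointRange.{name} must be finite, got {v!r}")

    @classmethod
    def of(cls, value: Any) -> "PointRange":
        """Coerce a mapping/triple/scalar into a PointRange (scalar -> degenerate)."""
        if isinstance(value, PointRange):
            return value
        if isinstance(value, Mapping):
            extra = set(value) - {"base", "lower", "upper"}
            if extra or "base" not in value:
                raise ParameterError(
                    f"range mapping needs keys base/lower/upper, got {sorted(value)}"
                )
            base = float(value["base"])
            return cls(base, float(value.get("lower", base)), float(value.get("upper", base)))
        if isinstance(value, (tuple, list)):
            if len(value) != 3:
                raise ParameterError(f"range triple must have 3 items, got {value!r}")
            return cls(*(float(v) for v in value))
        v = float(value)
        return cls(v, v, v)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def degenerate(self) -> bool:
        return self.width == 0.0

    def with_base(self, base: float) -> "PointRange":
        """Copy with the point value replaced and the range untouched."""
        return replace(self, base=float(base))


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution: family plus its shape parameters.

    Families: ``beta(alpha, beta)``, ``gamma(shape, scale)``,
    ``lognormal(mu_log, sigma_log)``, ``fixed(value,)``.
    """

    family: str
    args: tuple[float, ...]

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.args
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.args
            return shape * scale
        if self.family == "lognormal":
            mu, sigma = self.args
            return math.exp(mu + sigma**2 / 2)
        return self.args[0]

    def sd(self) -> float:
        if self.family == "beta":
            a, b = self.args
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            shape, scale = self.args
            return math.sqrt(shape) * scale
        if self.family == "lognormal":
            mu, sigma = self.args
            return math.exp(mu + sigma**2 / 2) * math.sqrt(math.expm1(sigma**2))
        return 0.0

    def frozen(self):
        """The matching frozen scipy distribution (fixed -> point mass via norm(scale=0))."""
        if self.family == "beta":
            return stats.beta(*self.args)
        if self.family == "gamma":
            shape, scale = self.args
            return stats.gamma(shape, scale=scale)
        if self.family == "lognormal":
            mu, sigma = self.args
            return stats.lognorm(sigma, scale=math.exp(mu))
        raise ParameterError(f"no scipy counterpart for fixed value {self.args[0]!r}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(*self.args, size=size)
        if self.family == "gamma":
            shape, scale = self.args
            return rng.gamma(shape, scale, size=size)
        if self.family == "lognormal":
            return rng.lognormal(*self.args, size=size)
        value = self.args[0]
        return value if size is None else np.full(size, value)


# ---------------------------------------------------------------------------
# Method-of-moments fits
# ---------------------------------------------------------------------------


def _range_sd(lower: float, upper: float) -> float:
    return (upper - lower) / RANGE_Z


def beta_from_mean_range(mean: float, lower: float, upper: float) -> DistributionSpec:
    """Beta distribution with the given mean and sd = (upper-lower)/3.92.

    A degenerate range yields a fixed-value spec.  Raises
    :class:`InfeasibleDistributionError` when the implied variance reaches
    ``mean*(1-mean)``, which no beta distribution can attain.
    """
    if lower > upper:
        raise ParameterError(f"lower {lower} > upper {upper}")
    if not (lower <= mean <= upper):
        raise ParameterError(f"mean {mean} outside [{lower}, {upper}]")
    if lower == upper:
        return DistributionSpec("fixed", (float(mean),))
    if not (0.0 < mean < 1.0) or lower < 0.0 or upper > 1.0:
        raise ParameterError(
            f"beta requires 0 <= lower <= mean <= upper <= 1 with mean interior, "
            f"got ({mean}, {lower}, {upper})"
        )
    var = _range_sd(lower, upper) ** 2
    if var >= mean * (1.0 - mean):
        raise InfeasibleDistributionError(
            f"implied variance {var:.6g} >= mean(1-mean) = {mean * (1 - mean):.6g}"
        )
    k = mean * (1.0 - mean) / var - 1.0
    return DistributionSpec("beta", (mean * k, (1.0 - mean) * k))


def gamma_from_mean_range(mean: float, lower: float, upper: float) -> DistributionSpec:
    """Gamma distribution with the given mean and sd = (upper-lower)/3.92."""
    if lower > upper:
        raise ParameterError(f"lower {lower} > upper {upper}")
    if not (lower <= mean <= upper):
        raise ParameterError(f"mean {mean} outside [{lower}, {upper}]")
    if mean <= 0.0:
        raise ParameterError(f"gamma mean must be positive, got {mean}")
    if lower == upper:
        return DistributionSpec("fixed", (float(mean),))
    sd = _range_sd(lower, upper)
    return DistributionSpec("gamma", ((mean / sd) ** 2, sd**2 / mean))


def lognormal_from_mean_range(mean: float, lower: float, upper: float) -> DistributionSpec:
    """Moment-matched log-normal fallback for positive quantities not in (0,1)."""
    if mean <= 0.0:
        raise ParameterError(f"lognormal mean must be positive, got {mean}")
    if lower == upper:
        return DistributionSpec("fixed", (float(mean),))
    sd = _range_sd(lower, upper)
    sigma2 = math.log1p((sd / mean) ** 2)
    return DistributionSpec("lognormal", (math.log(mean) - sigma2 / 2, math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# Parameter groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostSet:
    """Unit costs in 2023 US$ (COP converted at 4000 COP/US$)."""

    drug_per_4wk: PointRange
    controlled_state_annual: PointRange
    ocs_burst_per_episode: PointRange
    ed_visit_per_episode: PointRange
    hospitalization_per_episode: PointRange


@dataclass(frozen=True)
class UtilitySet:
    """Controlled-state utility and per-event utility decrements."""

    controlled: PointRange
    decrement_ocs: PointRange
    decrement_ed: PointRange
    decrement_hosp: PointRange


@dataclass(frozen=True)
class TreatmentEffect:
    """Relative risk of exacerbation under add-on therapy (rate scale)."""

    rr_exacerbation: PointRange


@dataclass(frozen=True)
class EventRates:
    """Exacerbation incidence and its split across severity channels.

    ``split_*`` apportion the annual exacerbation rate between OCS-burst,
    emergency-department and hospitalization episodes and must sum to 1.
    ``asthma_case_fatality_hosp`` is the probability of asthma death per
    hospitalized exacerbation (declared model assumption, not a published
    input).
    """

    exacerbation_annual_rate: PointRange
    split_ocs: float
    split_ed: float
    split_hosp: float
    asthma_case_fatality_hosp: float


@dataclass(frozen=True)
class AdherenceSpec:
    """Treatment waning: a fraction discontinues after ``waning_cycle`` cycles."""

    discontinuation_fraction: PointRange
    waning_cycle: int


@dataclass(frozen=True)
class EconomicConfig:
    """Discounting, willingness-to-pay and the cycle/currency conventions."""

    annual_discount_rate: PointRange
    wtp_per_qaly: float
    cycle_days: float
    currency_cop_per_usd: float


@dataclass(frozen=True)
class ParameterSet:
    """Everything the cohort model needs for one evaluation."""

    costs: CostSet
    utilities: UtilitySet
    effect: TreatmentEffect
    events: EventRates
    adherence: AdherenceSpec
    econ: EconomicConfig

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, PointRange):
                return {"base": obj.base, "lower": obj.lower, "upper": obj.upper}
            if is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name)) for f in fields(obj)}
            return obj

        return conv(self)

    def replace_base(self, path: str, base: float) -> "ParameterSet":
        """Copy with the point value at ``section.field`` replaced."""
        section, name = path.split(".")
        group = getattr(self, section)
        value = getattr(group, name)
        if isinstance(value, PointRange):
            value = value.with_base(base)
        else:
            value = float(base)
        return replace(self, **{section: replace(group, **{name: value})})

    def point(self, path: str) -> PointRange:
        section, name = path.split(".")
        return getattr(getattr(self, section), name)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the field path, the rule, the offending value."""

    field: str
    rule: str
    value: float

    def to_dict(self) -> dict:
        return {"field": self.field, "rule": self.rule, "value": self.value}


def _check_range(out: list[Violation], path: str, pr: PointRange) -> None:
    if not (pr.lower <= pr.base <= pr.upper):
        out.append(Violation(path, "lower <= base <= upper", pr.base))


def validate_parameter_set(params: ParameterSet) -> list[Violation]:
    """Return every invariant violation (empty list when the set is valid)."""
    v: list[Violation] = []
    c, u, e = params.costs, params.utilities, params.events
    for name in ("drug_per_4wk", "controlled_state_annual", "ocs_burst_per_episode",
                 "ed_visit_per_episode", "hospitalization_per_episode"):
        pr = getattr(c, name)
        _check_range(v, f"costs.{name}", pr)
        if min(pr.base, pr.lower) < 0:
            v.append(Violation(f"costs.{name}", "cost >= 0", min(pr.base, pr.lower)))

    _check_range(v, "utilities.controlled", u.controlled)
    if not (0.0 <= u.controlled.base <= 1.0):
        v.append(Violation("utilities.controlled", "utility in [0, 1]", u.controlled.base))
    for name in ("decrement_ocs", "decrement_ed", "decrement_hosp"):
        pr = getattr(u, name)
        _check_range(v, f"utilities.{name}", pr)
        if pr.base < 0:
            v.append(Violation(f"utilities.{name}", "decrement >= 0", pr.base))
    max_dec = max(u.decrement_ocs.base, u.decrement_ed.base, u.decrement_hosp.base)
    if u.controlled.base - max_dec < -1.0:
        v.append(Violation("utilities", "controlled - max decrement >= -1",
                           u.controlled.base - max_dec))

    rr = params.effect.rr_exacerbation
    _check_range(v, "effect.rr_exacerbation", rr)
    if min(rr.base, rr.lower) <= 0:
        v.append(Violation("effect.rr_exacerbation", "relative risk > 0", rr.base))

    _check_range(v, "events.exacerbation_annual_rate", e.exacerbation_annual_rate)
    if e.exacerbation_annual_rate.base < 0:
        v.append(Violation("events.exacerbation_annual_rate", "rate >= 0",
                           e.exacerbation_annual_rate.base))
    splits = (e.split_ocs, e.split_ed, e.split_hosp)
    for name, s in zip(("split_ocs", "split_ed", "split_hosp"), splits):
        if not (0.0 <= s <= 1.0):
            v.append(Violation(f"events.{name}", "proportion in [0, 1]", s))
    if abs(sum(splits) - 1.0) > 1e-9:
        v.append(Violation("events.split_ocs+split_ed+split_hosp", "sum to 1", sum(splits)))
    if not (0.0 <= e.asthma_case_fatality_hosp <= 1.0):
        v.append(Violation("events.asthma_case_fatality_hosp", "probability in [0, 1]",
                           e.asthma_case_fatality_hosp))

    a = params.adherence
    _check_range(v, "adherence.discontinuation_fraction", a.discontinuation_fraction)
    if not (0.0 <= a.discontinuation_fraction.base <= 1.0):
        v.append(Violation("adherence.discontinuation_fraction", "proportion in [0, 1]",
                           a.discontinuation_fraction.base))
    if a.waning_cycle < 1:
        v.append(Violation("adherence.waning_cycle", "waning cycle >= 1", a.waning_cycle))

    ec = params.econ
    _check_range(v, "econ.annual_discount_rate", ec.annual_discount_rate)
    if not (0.0 <= ec.annual_discount_rate.base <= 1.0):
        v.append(Violation("econ.annual_discount_rate", "discount in [0, 1]",
                           ec.annual_discount_rate.base))
    if ec.wtp_per_qaly <= 0:
        v.append(Violation("econ.wtp_per_qaly", "willingness-to-pay > 0", ec.wtp_per_qaly))
    if ec.cycle_days <= 0:
        v.append(Violation("econ.cycle_days", "cycle length > 0", ec.cycle_days))
    return v


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_GROUPS = {
    "costs": CostSet,
    "utilities": UtilitySet,
    "effect": TreatmentEffect,
    "events": EventRates,
    "adherence": AdherenceSpec,
    "econ": EconomicConfig,
}

_SCALAR_FIELDS = {
    ("events", "split_ocs"), ("events", "split_ed"), ("events", "split_hosp"),
    ("events", "asthma_case_fatality_hosp"),
    ("adherence", "waning_cycle"),
    ("econ", "wtp_per_qaly"), ("econ", "cycle_days"), ("econ", "currency_cop_per_usd"),
}


def _packaged_defaults() -> dict:
    from importlib.resources import files

    text = files("asthma_cua").joinpath("data/table1_parameters.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _from_document(doc: Mapping) -> ParameterSet:
    unknown = set(doc) - set(_GROUPS)
    if unknown:
        raise ParameterError(f"unknown parameter section(s): {sorted(unknown)}")
    groups = {}
    for section, cls in _GROUPS.items():
        if section not in doc:
            raise ParameterError(f"missing parameter section: {section}")
        section_doc = dict(doc[section])
        unknown = set(section_doc) - {f.name for f in fields(cls)}
        if unknown:
            raise ParameterError(f"unknown field(s) in {section}: {sorted(unknown)}")
        kwargs = {}
        for f in fields(cls):
            if f.name not in section_doc:
                raise ParameterError(f"missing field: {section}.{f.name}")
            raw = section_doc[f.name]
            if (section, f.name) in _SCALAR_FIELDS:
                kwargs[f.name] = int(raw) if f.name == "waning_cycle" else float(raw)
            else:
                kwargs[f.name] = PointRange.of(raw)
        groups[section] = cls(**kwargs)
    return ParameterSet(**groups)


def load_parameter_set(source: Any = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a config document.

    ``source`` may be None (packaged base-case defaults), a mapping of
    overrides merged onto the defaults, or a path to a YAML file of such
    overrides.  Any invariant violation raises
    :class:`ParameterValidationError` naming the offending fields.
    """
    doc = _packaged_defaults()
    if source is not None:
        if isinstance(source, (str, Path)):
            loaded = yaml.safe_load(Path(source).read_text())
            source = loaded if loaded is not None else {}
        if not isinstance(source, Mapping):
            raise ParameterError(f"parameter document must be a mapping, got {type(source)}")
        doc = _deep_merge(doc, source)
    params = _from_document(doc)
    violations = validate_parameter_set(params)
    if violations:
        raise ParameterValidationError(violations)
    return params


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampledParameter:
    """One PSA-sampled quantity: target path, distribution, draw transform."""

    path: str
    dist: DistributionSpec
    from_draw: Callable[[float], float]


def _identity(x: float) -> float:
    return x


def build_sampling_plan(params: ParameterSet) -> list[SampledParameter]:
    """Distributions for every PSA-sampled parameter, in the fixed draw order.

    Relative risk, utilities, decrements, the per-cycle exacerbation
    probability and the discontinuation fraction are beta; the five costs are
    gamma; discounting, willingness-to-pay, the event split and the case
    fatality are structural and held fixed.  Infeasible fits raise here,
    before any draw is taken.
    """
    plan: list[SampledParameter] = []

    rr = params.effect.rr_exacerbation
    if rr.upper < 1.0 and rr.base < 1.0:
        rr_dist = beta_from_mean_range(rr.base, rr.lower, rr.upper)
    else:
        logger.warning(
            "relative risk range [%g, %g] not inside (0, 1); "
            "falling back to a log-normal fit", rr.lower, rr.upper,
        )
        rr_dist = lognormal_from_mean_range(rr.base, rr.lower, rr.upper)
    plan.append(SampledParameter("effect.rr_exacerbation", rr_dist, _identity))

    u = params.utilities
    for name in ("controlled", "decrement_ocs", "decrement_ed", "decrement_hosp"):
        pr = getattr(u, name)
        plan.append(SampledParameter(
            f"utilities.{name}", beta_from_mean_range(pr.base, pr.lower, pr.upper), _identity,
        ))

    # Annual exacerbation rate via its beta-distributed per-cycle probability.
    rate = params.events.exacerbation_annual_rate
    f_cycle = params.econ.cycle_days / DAYS_PER_YEAR

    def p_of_rate(x: float) -> float:
        return -math.expm1(-x * f_cycle)

    def rate_of_p(p: float) -> float:
        return -math.log1p(-p) / f_cycle

    plan.append(SampledParameter(
        "events.exacerbation_annual_rate",
        beta_from_mean_range(p_of_rate(rate.base), p_of_rate(rate.lower), p_of_rate(rate.upper)),
        rate_of_p,
    ))

    d = params.adherence.discontinuation_fraction
    plan.append(SampledParameter(
        "adherence.discontinuation_fraction",
        beta_from_mean_range(d.base, d.lower, d.upper), _identity,
    ))

    for name in ("drug_per_4wk", "controlled_state_annual", "ocs_burst_per_episode",
                 "ed_visit_per_episode", "hospitalization_per_episode"):
        pr = getattr(params.costs, name)
        plan.append(SampledParameter(
            f"costs.{name}", gamma_from_mean_range(pr.base, pr.lower, pr.upper), _identity,
        ))
    return plan


def sample_parameter_set(
    params: ParameterSet,
    rng: np.random.Generator,
    plan: list[SampledParameter] | None = None,
) -> ParameterSet:
    """One second-order Monte Carlo draw: point values replaced, ranges untouched."""
    if plan is None:
        plan = build_sampling_plan(params)
    out = params
    for item in plan:
        out = out.replace_base(item.path, item.from_draw(float(item.dist.sample(rng))))
    return out
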