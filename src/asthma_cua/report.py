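"""Report assembly: the CE-statistics and net-benefit tables plus a run manifest.

Reports are data-first: the JSON document is the source of truth and the
plain-text table is a view of it.  Internal consistency is enforced before
anything is rendered — the per-strategy expected net benefit must equal
``mean QALYs * λ - mean cost``, the summary and base-case blocks must share
one willingness-to-pay, and, when an acceptability curve is supplied, its
value at λ must equal the summary's P(cost-effective) exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version

from .outcomes import IncrementalResult
from .params import ParameterSet
from .psa import CeacCurve, PsaSummary, parameter_digest

_CONSISTENCY_TOL = 1e-9


def _package_version() -> str:
    try:
        return version("asthma-cua")
    except PackageNotFoundError:
        return "unknown"


class ReportConsistencyError(RuntimeError):
    """The report inputs contradict each other; nothing is rendered."""


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit (given the seed)."""

    package_version: str
    seed: int | None
    n_runs: int
    params_digest: str
    assumptions: dict

    def to_dict(self) -> dict:
        return asdict(self)


def build_manifest(
    params: ParameterSet, seed: int | None, n_runs: int
) -> RunManifest:
    """Record the seed, parameter digest and every declared default in force."""
    e, a = params.events, params.adherence
    return RunManifest(
        package_version=_package_version(),
        seed=seed,
        n_runs=n_runs,
        params_digest=parameter_digest(params),
        assumptions={
            "event_split": [e.split_ocs, e.split_ed, e.split_hosp],
            "asthma_case_fatality_hosp": e.asthma_case_fatality_hosp,
            "discontinuation_fraction": a.discontinuation_fraction.base,
            "waning_cycle": a.waning_cycle,
            "adherence_interpretation":
                "28% discontinue after 16 weeks; published adherence row used as DSA range",
            "half_cycle_correction": "trapezoidal end-weights (1/2, 1, ..., 1, 1/2)",
            "quantile_convention": "empirical, linear interpolation",
            "range_to_sd": "ranges read as central 95% intervals, sd = width/3.92",
        },
    )


def render_report(
    summary: PsaSummary,
    base: IncrementalResult,
    manifest: RunManifest,
    ceac: CeacCurve | None = None,
) -> dict:
    """Assemble the two-table report dict after verifying internal consistency."""
    if summary.wtp != base.wtp:
        raise ReportConsistencyError(
            f"willingness-to-pay mismatch: summary {summary.wtp} vs base case {base.wtp}"
        )
    for name in ("comparator", "add_on"):
        recomputed = summary.mean_qaly[name] * summary.wtp - summary.mean_cost[name]
        if abs(recomputed - summary.expected_nmb[name]) > _CONSISTENCY_TOL:
            raise ReportConsistencyError(
                f"expected NMB for {name} inconsistent with mean cost/QALY: "
                f"{summary.expected_nmb[name]} vs {recomputed}"
            )
    if ceac is not None:
        p_at_wtp = ceac.at(summary.wtp)
        if p_at_wtp != summary.p_cost_effective:
            raise ReportConsistencyError(
                f"CEAC at λ={summary.wtp} is {p_at_wtp} but summary reports "
                f"P(cost-effective)={summary.p_cost_effective}"
            )

    ce_statistics = {
        "Threshold (US$ per QALY)": summary.wtp,
        "Number of PSA runs": summary.n_runs,
        "Mean incremental effect per person (QALY)": summary.mean_delta_qaly,
        "Mean incremental cost per person (US$)": summary.mean_delta_cost,
        "ICER estimate (US$ per QALY)": summary.icer_of_means.value,
        "ICER quadrant": summary.icer_of_means.quadrant,
        "2.5th centile for inc. effects (QALY)": summary.ci_delta_qaly[0],
        "97.5th centile for inc. effects (QALY)": summary.ci_delta_qaly[1],
        "2.5th centile for inc. costs (US$)": summary.ci_delta_cost[0],
        "97.5th centile for inc. costs (US$)": summary.ci_delta_cost[1],
        "Probability intervention is cost saving": summary.p_cost_saving,
        "Probability intervention provides more benefit": summary.p_more_effective,
        "Probability that intervention is cost-effective against comparator":
            summary.p_cost_effective,
    }
    net_benefit = {}
    for key, label in (("comparator", "comparator"), ("add_on", "add-on")):
        net_benefit[label] = {
            "Mean discounted lifetime QALYs": summary.mean_qaly[key],
            "Mean discounted lifetime costs (US$)": summary.mean_cost[key],
            f"Expected net benefit at US$ {summary.wtp:g} per QALY":
                summary.expected_nmb[key],
            "95% lower CI (on costs scale)": summary.ci_nmb[key][0],
            "95% upper CI (on costs scale)": summary.ci_nmb[key][1],
            "Expected net benefit on effects scale": summary.nb_effects[key],
            "95% lower CI (on effects scale)": summary.ci_nb_effects[key][0],
            "95% upper CI (on effects scale)": summary.ci_nb_effects[key][1],
        }
    base_case = {
        "Incremental cost (US$)": base.delta_cost,
        "Incremental QALYs": base.delta_qaly,
        "ICER (US$ per QALY)": base.icer.value,
        "ICER quadrant": base.icer.quadrant,
        "Incremental NMB (US$)": base.incremental_nmb,
    }
    return {
        "ce_statistics": ce_statistics,
        "net_benefit": net_benefit,
        "base_case": base_case,
        "manifest": manifest.to_dict(),
    }


def report_text(report: dict) -> str:
    """Human-readable view of :func:`render_report`'s document."""
    lines = ["CE data / statistics", "=" * 60]
    for label, value in report["ce_statistics"].items():
        lines.append(f"{label:58s} {_fmt(value)}")
    lines += ["", "Absolute net benefit statistics", "=" * 60]
    for strategy, rows in report["net_benefit"].items():
        lines.append(f"-- {strategy}")
        for label, value in rows.items():
            lines.append(f"  {label:56s} {_fmt(value)}")
    lines += ["", "Deterministic base case", "=" * 60]
    for label, value in report["base_case"].items():
        lines.append(f"{label:58s} {_fmt(value)}")
    return "\n".join(lines)


def _fmt(value) -> str:
    if value is None:
        return "n/a"
    if isinstance(value, float):
        return f"{value:.4f}" if abs(value) < 10 else f"{value:,.2f}"
    return str(value)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
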