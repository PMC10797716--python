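"""Convenience figures: CE plane, acceptability curve, tornado.

Plots are views over the exported data, never the source of truth.
"""

from __future__ import annotations

import numpy as np

from .psa import CeacCurve, DsaResult, PsaResult


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_ce_plane(psa: PsaResult, ax=None):
    """Incremental cost vs incremental effect scatter with the WTP ray."""
    ax = _get_ax(ax)
    plane = psa.ce_plane()
    ax.scatter(plane["de"], plane["dc"], s=4, alpha=0.3, linewidths=0)
    lim = max(abs(plane["de"].min()), abs(plane["de"].max())) or 1.0
    de = np.linspace(-lim, lim, 2)
    ax.plot(de, de * psa.wtp, "k--", lw=1, label=f"λ = {psa.wtp:g} US$/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (US$)")
    ax.legend(frameon=False)
    return ax


def plot_ceac(curve: CeacCurve, wtp: float | None = None, ax=None):
    ax = _get_ax(ax)
    ax.plot(curve.lam, curve.probability)
    if wtp is not None:
        ax.axvline(wtp, color="grey", ls="--", lw=1)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness-to-pay (US$ per QALY)")
    ax.set_ylabel("P(add-on cost-effective)")
    return ax


def plot_tornado(dsa: DsaResult, ax=None):
    """Horizontal bars of incremental NMB at each parameter's range endpoints."""
    ax = _get_ax(ax)
    table = dsa.table.iloc[::-1]
    y = np.arange(len(table))
    base = dsa.base.incremental_nmb
    for yi, (_, row) in zip(y, table.iterrows()):
        lo, hi = sorted((row.nmb_low, row.nmb_high))
        ax.barh(yi, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.axvline(base, color="k", lw=1, label="base case")
    ax.set_yticks(y, table.parameter)
    ax.set_xlabel(f"Incremental NMB at λ = {dsa.wtp:g} (US$)")
    ax.legend(frameon=False)
    return ax
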