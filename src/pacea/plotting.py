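"""Optional plots: cost-effectiveness plane and acceptability curves.

The canonical outputs are the CSV tables; these helpers render them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def ce_plane(psa_table, path=None, wtp: float = 20_000.0,
             cost: str = "d_cost_total"):
    """Scatter of (dQALYs, dCost) draws per scenario, with the WTP ray."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for label, grp in psa_table.groupby("scenario"):
        ax.scatter(grp["d_qalys"], grp[cost], s=12, alpha=0.6, label=label)
    lim = max(abs(psa_table["d_qalys"]).max(), 1e-9)
    xs = [-lim, lim]
    ax.plot(xs, [wtp * x for x in xs], "k--", lw=1,
            label=f"WTP €{wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental costs (€)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def ceac_plot(curve, path=None):
    """CEAC: probability most cost-effective vs willingness-to-pay."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in curve.groupby("scenario"):
        ax.plot(grp["wtp"], grp["probability"], marker="o", ms=3,
                label=label)
    ax.set_xlabel("willingness to pay (€/QALY)")
    ax.set_ylabel("P(most cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
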