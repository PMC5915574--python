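"""Optional DSE plot (requires matplotlib)."""

from __future__ import annotations

from .core import DSETimeSeries


def dse_plot(dse: DSETimeSeries, result=None, path=None, ax=None):
    """Plot the A/D/S/E curves with flagged scan pairs striped.

    Gray stripes mark statistically significant pairs, orange ones pairs
    that are also practically significant.  Returns the matplotlib axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))

    if result is not None:
        tab = result.table
        for _, row in tab[tab.get("flag_statistical", False)].iterrows():
            color = "orange" if row.get("flag_practical", False) else "0.8"
            ax.axvspan(row.t, row.t + 1, color=color, alpha=0.6, lw=0)

    ax.plot(dse.abscissa("A"), dse.A, color="green", label="A (total)")
    ax.plot(dse.abscissa("D"), dse.D, color="tab:blue", label="D (fast)")
    ax.plot(dse.abscissa("S"), dse.S, color="gold", label="S (slow)")
    mask = dse.E > 0
    ax.plot(dse.abscissa("E")[mask], dse.E[mask], "o", color="purple", label="E (edge)")

    avg_a = dse.averages()["A"]
    if avg_a > 0:
        sec = ax.secondary_yaxis(
            "right",
            functions=(lambda v: 100.0 * v / avg_a, lambda v: v * avg_a / 100.0),
        )
        sec.set_ylabel("% of A-var")
    ax.set_xlabel("scan")
    ax.set_ylabel("mean square")
    ax.legend(loc="upper right", ncol=4, fontsize="small")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
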