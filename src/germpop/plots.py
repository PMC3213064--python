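"""Small per-stage figures: membership bars, ordination scatter, LD decay."""

from __future__ import annotations

import numpy as np

from .ld import DecayFit, LDTable
from .structure import MembershipMatrix, OrdinationResult


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_membership(members: MembershipMatrix, ax=None):
    """Stacked membership-probability bars, lines sorted by first column."""
    ax = _axes(ax)
    P = members.probabilities
    order = np.argsort(-P[:, 0])
    bottom = np.zeros(P.shape[0])
    x = np.arange(P.shape[0])
    for k in range(members.K):
        ax.bar(x, P[order, k], bottom=bottom, width=1.0, label=f"G{k + 1}")
    ax.set_xlabel("line")
    ax.set_ylabel("membership probability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small")
    return ax


def plot_ordination(result: OrdinationResult, labels=None, ax=None):
    """First two ordination axes, optionally coloured by group label."""
    ax = _axes(ax)
    xy = result.coordinates[:, :2]
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=8)
    else:
        lab = np.asarray(list(labels))
        for g in np.unique(lab):
            sel = lab == g
            ax.scatter(xy[sel, 0], xy[sel, 1], s=8, label=str(g))
        ax.legend(fontsize="small")
    ve = result.variance_explained
    ax.set_xlabel(f"{result.method} 1 ({ve[0] * 100:.1f}%)")
    if len(ve) > 1:
        ax.set_ylabel(f"{result.method} 2 ({ve[1] * 100:.1f}%)")
    return ax


def plot_ld_decay(table: LDTable, fit: DecayFit | None = None, ax=None):
    """Linked r^2 against cM distance with the fitted curve and threshold."""
    ax = _axes(ax)
    linked = table.linked
    ax.scatter(linked["distance_cm"], linked["r2"], s=4, alpha=0.3, color="grey")
    if fit is not None:
        d = np.linspace(0.01, max(float(linked["distance_cm"].max()), 1.0), 200)
        ax.plot(d, fit.expected(d), color="red", label=f"Hill-Weir fit (Ne={fit.ne:.0f})")
        if fit.threshold is not None:
            ax.axhline(fit.threshold, linestyle="--", color="black",
                       label=f"unlinked Q95 = {fit.threshold:.3f}")
        ax.legend(fontsize="small")
    ax.set_xlabel("map distance (cM)")
    ax.set_ylabel(r"$r^2$")
    ax.set_ylim(0, 1)
    return ax
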