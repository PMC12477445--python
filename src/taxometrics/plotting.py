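"""Figure output: curve panels and CCFI profile plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_curves(curves: dict, path=None, title: str | None = None):
    """One panel per procedure's empirical panel-mean curve."""
    fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3.2), squeeze=False)
    for ax, (name, curve) in zip(axes[0], sorted(curves.items())):
        ax.plot(curve.x, curve.y, lw=1.5)
        ax.set_title(name.upper())
        xlabel = "factor score" if curve.procedure == "LMODE" else "case rank"
        ylabel = {
            "MAMBAC": "mean above - below",
            "MAXEIG": "largest eigenvalue",
            "LMODE": "density",
        }.get(curve.procedure, "y")
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_profile(profile, path=None, title: str | None = None):
    """CCFI vs assumed base rate per procedure, dashed reference at 0.50."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, proc in enumerate(profile.procedures_):
        ax.plot(profile.base_rates_, profile.ccfi_matrix_[i], marker="o", ms=3, label=proc.upper())
    with np.errstate(all="ignore"):
        ax.plot(profile.base_rates_, profile.profile_, color="k", lw=2, label="mean")
    ax.axhline(0.5, ls="--", color="grey")
    ax.set_ylim(0, 1)
    ax.set_xlabel("assumed taxon base rate")
    ax.set_ylabel("CCFI")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
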