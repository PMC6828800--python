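"""Quick-look figures: cost-benefit curves and efficiency-gain trends."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from matplotlib import pyplot as plt

from .efficiency import CostBenefitCurve

_STYLE = {"min_cost": "-", "min_area": "--", "crank": ":"}


def plot_curves(curves: Mapping[str, CostBenefitCurve], path=None, ax=None):
    """Cost fraction (x) against occupancy target (y), one line per
    method; only feasible prefixes are drawn."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    for name, curve in curves.items():
        t, x = curve.feasible_prefix()
        ax.plot(np.concatenate([[0.0], x]), np.concatenate([[0.0], t]),
                _STYLE.get(name, "-"), label=name)
    ax.set_xlabel("cost (fraction of total)")
    ax.set_ylabel("occupancy target achieved")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_gain_trend(levels: Sequence[float],
                    gains_by_label: Mapping[str, Sequence[float]],
                    ylabel: str = "fractional gain in efficiency",
                    path=None, ax=None):
    """Fractional gain against the relative-CV ladder, one line per
    label (typically one per guild)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    for label, gains in gains_by_label.items():
        ax.plot(levels, gains, marker="o",
                linestyle="--" if label == "human" else "-", label=label)
    ax.set_xscale("log", base=2)
    ax.set_xticks(list(levels), [str(v) for v in levels])
    ax.set_xlabel("relative CV (benefit / cost)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
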