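"""Fit-overlay plots: observed counts and fitted time courses per panel."""

from __future__ import annotations

import numpy as np

from .kinetics import dln_timecourse, skin_timecourse
from .parameters import SkinPoolState


def plot_fit(results, site: str = "dln", ax=None, n_grid: int = 200):
    """Overlay observed counts and fitted curves for one site.

    One line per (condition, photoconversion-time) strategy; points are the
    observations. Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    frame = results.model.dataset.frame
    sub = frame[frame["site"] == site]
    params = results.params
    colors = {"alum": "tab:red", "saline": "tab:blue"}
    for (cond, t_pc), grp in sub.groupby(["condition", "t_pc"]):
        x0 = results.x0_groups[f"{cond}:tpc{t_pc:g}"]
        state = SkinPoolState(x0=x0, t_pc=float(t_pc))
        t_max = grp["t_harvest"].max()
        grid = np.linspace(float(t_pc), float(t_max), n_grid)
        fn = skin_timecourse if site == "skin" else dln_timecourse
        ax.plot(grid, np.atleast_1d(fn(grid, state, params, cond)),
                color=colors[cond], alpha=0.6, lw=1)
        ax.scatter(grp["t_harvest"], grp["count"], s=12, color=colors[cond],
                   alpha=0.6, label=None)
    ax.set_xlabel("hours post-injection")
    ax.set_ylabel(f"photoconverted cells ({site})")
    ax.set_title(results.spec.name)
    return ax
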