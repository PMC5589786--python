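"""Headless figure generation (matplotlib Agg) for pooled summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def boxplot_binned(binned: pd.DataFrame, metric: str, path=None):
    """Box plot of a delta metric per concentration bin, one panel per time.

    Boxes are rebuilt from the precomputed summary statistics (median,
    quartiles, whiskers), so the figure reflects exactly what the tables
    report.
    """
    sub = binned[binned["metric"] == metric]
    times = sorted(sub["time_min"].unique())
    fig, axes = plt.subplots(1, max(len(times), 1), figsize=(3.2 * max(len(times), 1), 3.4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, t in zip(axes, times):
        st = sub[sub["time_min"] == t].sort_values("bin_lo_ug_ml")
        stats = [
            {
                "med": r["median"],
                "q1": r["q1"],
                "q3": r["q3"],
                "whislo": r["whisker_lo"],
                "whishi": r["whisker_hi"],
                "label": f"{r['bin_lo_ug_ml']:.1f}-{r['bin_hi_ug_ml']:.1f}",
                "fliers": [],
            }
            for _, r in st.iterrows()
            if np.isfinite(r["median"])
        ]
        if stats:
            ax.bxp(stats, showfliers=False)
        ax.set_title(f"t = {t:g} min")
        ax.set_xlabel("mean exposure (ug/ml)")
        ax.tick_params(axis="x", rotation=45)
    axes[0].set_ylabel(metric.replace("_", " "))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def gradient_profile_figure(profiles: dict, path=None):
    """Normalized dye profiles along the gradient axis, one line per time."""
    fig, ax = plt.subplots(figsize=(4.5, 3.4))
    for t in sorted(profiles):
        p = profiles[t]
        ax.plot(p.positions_um, p.intensity_pct, label=f"{t:g} min")
    ax.set_xlabel("position along gradient axis (um)")
    ax.set_ylabel("normalized intensity (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
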