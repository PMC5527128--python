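"""Minimal band plots mirroring the common/differential smoother layout."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_trend_fit(trend_fit, path=None):
    """Two stacked panels: common smoother band (top) and differential
    smoother band (bottom), with the elicitation day marked when known."""
    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, summ, title in (
        (axes[0], trend_fit.common, "common trend"),
        (axes[1], trend_fit.differential, "differential (treated only)"),
    ):
        band = summ.band
        ax.fill_between(band["day"], band["lower"], band["upper"], alpha=0.3, color="tab:blue")
        ax.plot(band["day"], band["estimate"], color="tab:blue")
        ax.axhline(0.0, color="gray", lw=0.8, ls=":")
        if trend_fit.elicitation_day is not None:
            ax.axvline(trend_fit.elicitation_day, color="red", ls="--", lw=1)
        ax.set_title(f"{trend_fit.response}: {title} (e.d.f.={summ.edf:.2f}, p={summ.p_value:.3g})")
        ax.set_ylabel("link-scale effect")
    axes[1].set_xlabel("day")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
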