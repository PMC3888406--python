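"""Rendering helpers: AP panels, phase diagrams, voltage frames.

Thin matplotlib wrappers; matplotlib is an optional dependency and is
imported lazily.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_ap_trace", "plot_phase_diagram", "plot_frame",
           "plot_line_profile"]

_LABEL_COLORS = {
    "NORMAL": "#f2d43d",        # no EAD
    "EAD": "#d6453d",
    "OSCILLATORY": "#3d6bd6",   # non-repolarizing
    "FAILED": "#999999",
}


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_ap_trace(trace, path, currents=False):
    """Voltage (and optionally per-current) panel of one AP trace."""
    plt = _plt()
    n = 2 if (currents and trace.currents) else 1
    fig, axes = plt.subplots(n, 1, figsize=(7, 3 * n), sharex=True,
                             squeeze=False)
    ax = axes[0, 0]
    ax.plot(trace.t / 1000.0, trace.V, lw=1.0, color="k")
    ax.set_ylabel("V [mV]")
    if n == 2:
        ax2 = axes[1, 0]
        for name, series in trace.currents.items():
            if name == "i_ion":
                continue
            ax2.plot(trace.t / 1000.0, series, lw=0.8, label=name)
        ax2.legend(fontsize=6, ncol=4)
        ax2.set_ylabel("I [pA/pF]")
    axes[-1, 0].set_xlabel("t [s]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_diagram(pd, path):
    """AP-class map over the swept multiplier grid."""
    plt = _plt()
    order = ["NORMAL", "EAD", "OSCILLATORY", "FAILED"]
    idx = np.vectorize(order.index)(pd.labels.astype(str))
    from matplotlib.colors import ListedColormap
    cmap = ListedColormap([_LABEL_COLORS[k] for k in order])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(idx.T, origin="lower", aspect="auto", cmap=cmap, vmin=0,
              vmax=len(order) - 1,
              extent=(pd.x_mults[0], pd.x_mults[-1],
                      pd.y_mults[0], pd.y_mults[-1]))
    ax.set_xlabel("G_CaL multiplier")
    ax.set_ylabel(f"G_{pd.y_channel} multiplier")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_frame(frames, index, path, channel="V"):
    """Gray-scale plot of one 2D frame (V or a gate product)."""
    plt = _plt()
    data = {"V": frames.V, "na": frames.na, "ca": frames.ca}[channel]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(data[index], origin="lower", cmap="gray")
    fig.colorbar(im, ax=ax, label=channel)
    ax.set_title(f"t = {frames.times[index]:.0f} ms")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_line_profile(matrix, times, dx, path):
    """Space-time image of V along a row/column (wavebreak panels)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(matrix, origin="lower", aspect="auto", cmap="gray",
                   extent=(0, matrix.shape[1] * dx, times[0] / 1000.0,
                           times[-1] / 1000.0))
    ax.set_xlabel("position [mm]")
    ax.set_ylabel("t [s]")
    fig.colorbar(im, ax=ax, label="V [mV]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
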