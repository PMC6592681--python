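"""Figure helpers: angular histograms, polarity rose plots, H:W scatter."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .division import angular_histogram  # noqa: E402

__all__ = ["angular_histogram_plot", "rose_plot", "hw_vs_angle_plot"]


def angular_histogram_plot(angles, path, bin_width: float = 10.0, title: str = ""):
    """Quarter-circle polar histogram of division angles on [0°, 90°]."""
    counts, edges = angular_histogram(np.asarray(angles), bin_width=bin_width)
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.set_thetamin(0)
    ax.set_thetamax(90)
    centers = np.radians((edges[:-1] + edges[1:]) / 2)
    ax.bar(centers, counts, width=np.radians(bin_width) * 0.95, alpha=0.8)
    ax.set_title(title or "division angles")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def rose_plot(weights, bin_width_deg, path, title: str = "", mean_axis_deg=None, mean_magnitude=None):
    """Axial (mod-180°) rose plot of per-cell polarity, mirrored to 360°.

    The red radial line marks the average magnitude and direction of
    polarity (scaled to the plot radius).
    """
    weights = np.asarray(weights, dtype=float)
    edges = np.arange(0.0, 180.0 + bin_width_deg / 2, bin_width_deg)
    centers = np.radians((edges[:-1] + edges[1:]) / 2)
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    width = np.radians(bin_width_deg) * 0.95
    ax.bar(centers, weights, width=width, alpha=0.8)
    ax.bar(centers + np.pi, weights, width=width, alpha=0.8, color="C0")
    if mean_axis_deg is not None and mean_magnitude is not None and weights.max() > 0:
        r = mean_magnitude * weights.max()
        for off in (0.0, np.pi):
            ax.plot([np.radians(mean_axis_deg) + off] * 2, [0, r], color="red", lw=2)
    ax.set_title(title or "polarity")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def hw_vs_angle_plot(per_event, path, title: str = ""):
    """Scatter of interphase H:W ratio against division angle, by category."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    colors = {"planar": "C0", "oblique": "m", "perpendicular": "g"}
    for cat, g in per_event.groupby("category"):
        ax.scatter(g["angle_deg"], g["hw_ratio"], s=14, label=cat, color=colors.get(cat))
    ax.set_xlabel("division angle (deg)")
    ax.set_ylabel("interphase height:width")
    ax.legend(fontsize=8)
    ax.set_title(title or "H:W vs division angle")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
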