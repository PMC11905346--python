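"""Minimal figure helpers (centered maps, distance profiles, quartiles)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_centered_map", "plot_distance_profile", "plot_quartile_means"]


def plot_centered_map(cmap, ax=None):
    """Heat map of influenced-neurons-per-target around the centered target."""
    if ax is None:
        _, ax = plt.subplots()
    e = cmap.extent
    im = ax.imshow(cmap.grid.T, origin="lower", extent=(-e, e, -e, e),
                   cmap="magma")
    ax.set_xlabel("offset from target (µm)")
    ax.set_ylabel("offset from target (µm)")
    ax.set_title(f"{cmap.sign} influence, {cmap.cell_type}")
    plt.colorbar(im, ax=ax, label="neurons / target")
    return ax


def plot_distance_profile(profile, ax=None, fit=None):
    """Mean influence vs distance, optionally with a DoG fit overlay."""
    if ax is None:
        _, ax = plt.subplots()
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(profile.bin_centers, profile.mean_influence, "o-",
            label=profile.cell_type)
    if fit is not None and fit.converged:
        import numpy as np
        d = np.linspace(profile.bin_centers[0], profile.bin_centers[-1], 200)
        ax.plot(d, fit.predict(d), "--", label="DoG fit")
    ax.set_xlabel("distance to target (µm)")
    ax.set_ylabel("mean influence")
    ax.legend()
    return ax


def plot_quartile_means(summary, value="mean", ax=None):
    """Per-quartile means (influence or activity) per cell type."""
    if ax is None:
        _, ax = plt.subplots()
    for ct, grp in summary.groupby("neuron_type"):
        ax.plot(grp["quartile"], grp[value], "o-", label=ct)
    ax.set_xlabel("running-speed quartile")
    ax.set_ylabel(value)
    ax.set_xticks([1, 2, 3, 4])
    ax.legend()
    return ax
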