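"""Basic diagnostic plots for localization tables and density maps."""

from __future__ import annotations

import numpy as np

from npcroute.radial import RadialDensityMap


def plot_density_map(density: RadialDensityMap, ax=None):
    """Bar plot of the recovered radial density with the projection overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = density.bin_centers
    width = density.bin_edges[1] - density.bin_edges[0]
    ax.bar(centers, density.rho, width=width * 0.9, label=r"recovered $\rho(r)$")
    ax2 = ax.twinx()
    ax2.step(centers, density.A, where="mid", color="C1", label="projected counts")
    ax.set_xlabel("radius (nm)")
    ax.set_ylabel(r"density (counts/nm$^2$)")
    ax2.set_ylabel("counts per |x| bin")
    ax.legend(loc="upper left")
    ax2.legend(loc="upper right")
    return ax


def plot_localizations(table, ax=None, sample: int | None = 2000, seed: int = 0):
    """Scatter of projected localizations in the pore-centered frame."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if sample is not None and len(table) > sample:
        table = table.sample(sample, random_state=np.random.default_rng(seed).integers(2**31))
    ax.scatter(table["x_nm"], table["y_nm"], s=4, alpha=0.4)
    ax.axhline(20.0, color="grey", lw=0.8, ls="--")
    ax.axhline(-20.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.set_aspect("equal")
    return ax
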