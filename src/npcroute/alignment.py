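"""NPC centroid estimation and re-centering of localization tables.

The pore center is found in two stages: a coarse 2D-Gaussian fit of a
pore-marker image when one is available, then a histogram refinement on the
single-molecule data itself.  Because the pore is rotationally symmetric,
the x-histogram of a ring-shaped route is either unimodal (wide or central
routes) or a mirrored pair of peaks (peripheral routes); the refinement
fits both a single Gaussian and a mirrored two-Gaussian model sharing a
symmetry axis and keeps whichever fits better.  The y-histogram is fitted
with a single Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from npcroute.localization import fit_spot

__all__ = ["CenterEstimate", "estimate_npc_center"]


@dataclass(frozen=True)
class CenterEstimate:
    x0: float  # nm
    y0: float  # nm
    method: str  # "marker_fit" or "histogram_refine"
    uncertainty: float  # nm, 1-sigma on the refined center

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


def _single_gauss(x, amp, c, s):
    return amp * np.exp(-((x - c) ** 2) / (2.0 * s * s))


def _mirrored_pair(x, amp, c, d, s):
    # two equal Gaussians at c +/- d: symmetric about the axis x = c
    return amp * (
        np.exp(-((x - c - d) ** 2) / (2.0 * s * s))
        + np.exp(-((x - c + d) ** 2) / (2.0 * s * s))
    )


def _fit_axis_center(values: np.ndarray, bin_width: float) -> tuple[float, float, bool]:
    """Fit the histogram of one axis; return (center, 1-sigma error, bimodal?).

    Tries the single-Gaussian and mirrored-pair models and keeps the one
    with the lower residual sum of squares.
    """
    lo, hi = values.min(), values.max()
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    amp0 = counts.max()
    c0 = float(np.average(centers, weights=np.maximum(counts, 1e-12)))
    spread = float(values.std()) or bin_width

    candidates = []
    try:
        p, cov = curve_fit(
            _single_gauss, centers, counts, p0=(amp0, c0, spread), maxfev=5000
        )
        rss = float(np.sum((counts - _single_gauss(centers, *p)) ** 2))
        candidates.append(("unimodal", p[1], float(np.sqrt(max(cov[1, 1], 0.0))), rss))
    except RuntimeError:
        pass
    try:
        p, cov = curve_fit(
            _mirrored_pair,
            centers,
            counts,
            p0=(amp0, c0, spread, spread / 2.0),
            maxfev=5000,
        )
        rss = float(np.sum((counts - _mirrored_pair(centers, *p)) ** 2))
        candidates.append(("bimodal", p[1], float(np.sqrt(max(cov[1, 1], 0.0))), rss))
    except RuntimeError:
        pass
    if not candidates:
        raise RuntimeError("center refinement fit did not converge on any model")
    mode, center, err, _ = min(candidates, key=lambda t: t[3])
    return center, err, mode == "bimodal"


def estimate_npc_center(
    localizations: pd.DataFrame,
    marker_image: np.ndarray | None = None,
    pixel_size_nm: float = 240.0,
    bin_width: float = 5.0,
    min_locs: int = 100,
) -> tuple[CenterEstimate, pd.DataFrame]:
    """Estimate the pore center and return the table in the centered frame.

    When a marker image is given, its 2D-Gaussian centroid provides a coarse
    center that is subtracted before histogram refinement.  The returned
    table has the full estimate subtracted from ``x_nm``/``y_nm``.
    """
    if len(localizations) < min_locs:
        raise ValueError(
            f"histogram refinement needs at least {min_locs} localizations, "
            f"got {len(localizations)}"
        )
    coarse_x = coarse_y = 0.0
    method = "histogram_refine"
    if marker_image is not None:
        marker = fit_spot(marker_image, pixel_size_nm=pixel_size_nm)
        coarse_x, coarse_y = marker.x, marker.y
        method = "marker_fit"

    x = localizations["x_nm"].to_numpy() - coarse_x
    y = localizations["y_nm"].to_numpy() - coarse_y
    x0, x_err, _ = _fit_axis_center(x, bin_width)
    y0, y_err, _ = _fit_axis_center(y, bin_width)

    estimate = CenterEstimate(
        x0=coarse_x + x0,
        y0=coarse_y + y0,
        method=method,
        uncertainty=float(np.hypot(x_err, y_err)),
    )
    centered = localizations.copy()
    centered["x_nm"] = localizations["x_nm"] - estimate.x0
    centered["y_nm"] = localizations["y_nm"] - estimate.y0
    return estimate, centered
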