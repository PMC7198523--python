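"""Dual-channel co-tracking: pairing, separation statistics, error budget.

A molecule tagged at both termini with spectrally distinct fluorophores is
recorded simultaneously in two channels; pairing the per-frame
localizations across channels yields the projected distance between the two
tags.  The resolvable scale is bounded by the co-tracking error, the
quadrature sum of the two single-channel localization precisions and the
channel-registration error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["CotrackErrorInputs", "cotracking_error", "pair_channels", "summarize_pairs"]


@dataclass(frozen=True)
class CotrackErrorInputs:
    """Error budget: first/second channel precision and alignment error, nm."""

    G_p: float
    R_p: float
    A_p: float

    def __post_init__(self) -> None:
        if min(self.G_p, self.R_p, self.A_p) < 0:
            raise ValueError("error terms must be non-negative")


def cotracking_error(inputs: CotrackErrorInputs) -> float:
    """Quadrature co-tracking error sqrt(G_p^2 + R_p^2 + A_p^2), nm."""
    return float(np.sqrt(inputs.G_p**2 + inputs.R_p**2 + inputs.A_p**2))


def pair_channels(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    max_separation: float = 60.0,
    max_frame_gap: int = 0,
) -> pd.DataFrame:
    """Greedy one-to-one nearest-neighbor pairing of two channels per frame.

    Both tables must be in the same (centered) coordinate frame.  Candidate
    pairs are localizations whose frames differ by at most ``max_frame_gap``
    and whose projected distance is below ``max_separation``; pairs are
    accepted in ascending distance order, each localization used at most
    once.  Returns one row per pair with the two row indices, the frame and
    the separation (nm); an empty result is valid.
    """
    if max_separation < 0:
        raise ValueError("max_separation must be non-negative")
    rows = []
    used_b: set[int] = set()
    frames_b = table_b.groupby("frame").groups
    for frame, grp_a in table_a.groupby("frame"):
        cand_idx = []
        for f in range(int(frame) - max_frame_gap, int(frame) + max_frame_gap + 1):
            cand_idx.extend(frames_b.get(f, []))
        cand_idx = [i for i in cand_idx if i not in used_b]
        if not cand_idx:
            continue
        grp_b = table_b.loc[cand_idx]
        dists = cdist(grp_a[["x_nm", "y_nm"]], grp_b[["x_nm", "y_nm"]])
        order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
        taken_a: set[int] = set()
        taken_b: set[int] = set()
        for ia, ib in order:
            if dists[ia, ib] > max_separation:
                break
            if ia in taken_a or ib in taken_b:
                continue
            taken_a.add(int(ia))
            taken_b.add(int(ib))
            idx_b = grp_b.index[ib]
            used_b.add(idx_b)
            rows.append(
                {
                    "frame": int(frame),
                    "index_a": grp_a.index[ia],
                    "index_b": idx_b,
                    "separation_nm": float(dists[ia, ib]),
                }
            )
    return pd.DataFrame(rows, columns=["frame", "index_a", "index_b", "separation_nm"])


def summarize_pairs(pairs: pd.DataFrame, bin_width: float = 2.0) -> dict:
    """Summary statistics of pair separations (mean, median, histogram)."""
    sep = pairs["separation_nm"].to_numpy()
    if sep.size == 0:
        return {"n": 0, "mean_nm": None, "median_nm": None, "histogram": []}
    edges = np.arange(0.0, sep.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(sep, bins=edges)
    return {
        "n": int(sep.size),
        "mean_nm": float(sep.mean()),
        "median_nm": float(np.median(sep)),
        "histogram": [
            {"lo": float(lo), "hi": float(hi), "count": int(c)}
            for lo, hi, c in zip(edges[:-1], edges[1:], counts)
        ],
    }
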