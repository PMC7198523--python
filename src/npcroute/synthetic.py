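"""Seeded synthetic data with the statistical structure the pipeline assumes.

Every generator takes an explicit integer seed and returns plain pandas /
numpy containers; there is no global random state.  Observed localization
tables retain the generating ground truth in ``true_x``/``true_y``/``true_z``
columns, so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from npcroute.geometry import NPCGeometry, PhotonModel, RouteModel
from npcroute.localization import precision_moving

__all__ = [
    "TrajectorySet",
    "simulate_route_localizations",
    "simulate_trajectories",
    "simulate_dual_channel",
    "simulate_membrane_populations",
    "render_spot_stack",
]

# Default metadata for simulated emitters: bright, in-focus spots that pass
# the >2000-photon / 0.5-1.0 px quality filter unless a caller overrides.
_DEFAULT_PHOTONS = 5000.0
_DEFAULT_WIDTH_PX = 0.7
_DEFAULT_BG = 2.0


def _noise_sd(noise: PhotonModel | float) -> float:
    """Per-axis localization error sd (nm) from a PhotonModel or a fixed sd."""
    if isinstance(noise, PhotonModel):
        return precision_moving(noise).sigma
    sd = float(noise)
    if sd < 0:
        raise ValueError("localization noise sd must be non-negative")
    return sd


def _sample_radii(
    rng: np.random.Generator, route: RouteModel, size: int
) -> np.ndarray:
    if route.radial_sd == 0:
        return np.full(size, route.mean_radius)
    # truncated at zero so radii stay physical
    a = (0.0 - route.mean_radius) / route.radial_sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=route.mean_radius, scale=route.radial_sd,
        size=size, random_state=rng,
    )


def simulate_route_localizations(
    routes: Sequence[RouteModel],
    n: int,
    noise: PhotonModel | float,
    seed: int,
) -> pd.DataFrame:
    """Simulate projected localizations from a mixture of ring-shaped routes.

    3D points are drawn per route with uniform azimuth, radius ~
    Normal(mean_radius, radial_sd) truncated at zero, and y uniform on the
    route's axial extent.  The observation is the (x, y) projection plus
    isotropic Gaussian localization error.

    Returns a localization table with ground-truth columns ``true_x``,
    ``true_y``, ``true_z``; ``route`` records the generating component.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not routes:
        raise ValueError("route list must not be empty")
    weights = np.array([r.weight for r in routes], dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("route weights must sum to 1")

    rng = np.random.default_rng(seed)
    sd = _noise_sd(noise)
    component = rng.choice(len(routes), size=n, p=weights)

    radius = np.empty(n)
    y_true = np.empty(n)
    for k, route in enumerate(routes):
        mask = component == k
        m = int(mask.sum())
        if m == 0:
            continue
        radius[mask] = _sample_radii(rng, route, m)
        y_true[mask] = rng.uniform(route.y_low, route.y_high, size=m)

    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    x_true = radius * np.cos(theta)
    z_true = radius * np.sin(theta)
    err = rng.normal(0.0, sd, size=(2, n)) if sd > 0 else np.zeros((2, n))

    photons = _DEFAULT_PHOTONS if not isinstance(noise, PhotonModel) else noise.N
    bg = _DEFAULT_BG if not isinstance(noise, PhotonModel) else noise.b
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "x_nm": x_true + err[0],
            "y_nm": y_true + err[1],
            "photons": photons,
            "width_px": _DEFAULT_WIDTH_PX,
            "bg": bg,
            "channel": 0,
            "track_id": np.arange(n),
            "true_x": x_true,
            "true_y": y_true,
            "true_z": z_true,
            "route": component,
        }
    )


@dataclass(frozen=True)
class TrajectorySet:
    """A set of 2D single-particle tracks sharing one frame interval.

    ``data`` holds one row per localization with columns ``track_id``,
    ``frame``, ``x_nm``, ``y_nm``; ``dt`` is the frame interval in seconds.
    """

    data: pd.DataFrame
    dt: float

    def track_lengths(self) -> pd.Series:
        return self.data.groupby("track_id").size()

    def displacements(self, track_ids: Sequence[int] | None = None) -> np.ndarray:
        """Consecutive-frame jump distances (nm), optionally per track subset."""
        df = self.data
        if track_ids is not None:
            df = df[df["track_id"].isin(track_ids)]
        out = []
        for _, grp in df.groupby("track_id"):
            dx = np.diff(grp["x_nm"].to_numpy())
            dy = np.diff(grp["y_nm"].to_numpy())
            out.append(np.hypot(dx, dy))
        return np.concatenate(out) if out else np.empty(0)


def _draw_lengths(
    rng: np.random.Generator,
    spec: int | tuple,
    n_tracks: int,
) -> np.ndarray:
    """Track lengths (frames) from a distribution spec.

    Accepts a fixed integer length >= 2, or ``("uniform", lo, hi)`` for
    lengths uniform on the integers lo..hi (inclusive, lo >= 2).
    """
    if isinstance(spec, (int, np.integer)):
        if spec < 2:
            raise ValueError("track length must be at least 2 frames")
        return np.full(n_tracks, int(spec))
    if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "uniform":
        lo, hi = int(spec[1]), int(spec[2])
        if lo < 2 or hi < lo:
            raise ValueError("uniform length spec requires 2 <= lo <= hi")
        return rng.integers(lo, hi + 1, size=n_tracks)
    raise ValueError(f"invalid track length distribution spec: {spec!r}")


def simulate_trajectories(
    D: float,
    dt: float,
    n_tracks: int,
    length_distribution: int | tuple = 10,
    seed: int = 0,
) -> TrajectorySet:
    """Simulate 2D Brownian tracks at diffusion coefficient D (um^2/s).

    Per-axis steps are Normal(0, sqrt(2*D*dt)); positions are reported in nm.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_tracks < 1:
        raise ValueError("n_tracks must be at least 1")
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(rng, length_distribution, n_tracks)
    step_sd_nm = math.sqrt(2.0 * D * dt) * 1.0e3  # um -> nm

    rows = []
    for tid, length in enumerate(lengths):
        steps = rng.normal(0.0, step_sd_nm, size=(int(length) - 1, 2))
        pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": np.arange(length),
                    "x_nm": pos[:, 0],
                    "y_nm": pos[:, 1],
                }
            )
        )
    return TrajectorySet(data=pd.concat(rows, ignore_index=True), dt=dt)


def simulate_dual_channel(
    r_first: float,
    r_second: float,
    n_pairs: int,
    noise_first: float = 0.0,
    noise_second: float = 0.0,
    misalignment: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate co-tracked emitter pairs on two rings sharing azimuth and y.

    Emulates a doubly tagged molecule whose two termini ride different
    radial routes: both channels see the same azimuth and axial position,
    each with its own localization error.  Channel-2 coordinates are offset
    by a fixed misalignment vector of the given magnitude (random direction,
    constant within one call) standing in for imperfect channel registration.
    """
    if r_first < 0 or r_second < 0:
        raise ValueError("radii must be non-negative")
    if noise_first < 0 or noise_second < 0:
        raise ValueError("localization noise must be non-negative")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_pairs)
    y = rng.uniform(-40.0, 40.0, size=n_pairs)
    phi = rng.uniform(0.0, 2.0 * np.pi)  # registration offset direction
    offset = misalignment * np.array([np.cos(phi), np.sin(phi)])

    def observe(radius, noise_sd, channel, shift):
        x = radius * np.cos(theta) + shift[0]
        yy = y + shift[1]
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=n_pairs)
            yy = yy + rng.normal(0.0, noise_sd, size=n_pairs)
        return pd.DataFrame(
            {
                "frame": np.arange(n_pairs),
                "x_nm": x,
                "y_nm": yy,
                "photons": _DEFAULT_PHOTONS,
                "width_px": _DEFAULT_WIDTH_PX,
                "bg": _DEFAULT_BG,
                "channel": channel,
                "track_id": np.arange(n_pairs),
                "true_x": radius * np.cos(theta),
                "true_y": y,
                "true_z": radius * np.sin(theta),
            }
        )

    first = observe(r_first, noise_first, 0, np.zeros(2))
    second = observe(r_second, noise_second, 1, offset)
    return first, second


def simulate_membrane_populations(
    ratio_inm_onm: float,
    n: int,
    peak_sd: float,
    geometry: NPCGeometry | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate localizations on the two nuclear membranes.

    y-coordinates follow a two-Gaussian mixture centered on the INM and ONM
    planes with mixing ratio ``ratio_inm_onm : 1``; x is uninformative and
    drawn broadly around the pore.
    """
    if ratio_inm_onm <= 0:
        raise ValueError("ratio must be positive")
    if peak_sd <= 0:
        raise ValueError("peak_sd must be positive")
    geometry = geometry or NPCGeometry()
    rng = np.random.default_rng(seed)
    p_inm = ratio_inm_onm / (1.0 + ratio_inm_onm)
    on_inm = rng.random(n) < p_inm
    centers = np.where(on_inm, geometry.inm_y, geometry.onm_y)
    y = rng.normal(centers, peak_sd)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "x_nm": rng.normal(0.0, 50.0, size=n),
            "y_nm": y,
            "photons": _DEFAULT_PHOTONS,
            "width_px": _DEFAULT_WIDTH_PX,
            "bg": _DEFAULT_BG,
            "channel": 0,
            "track_id": np.arange(n),
            "true_x": np.nan,
            "true_y": centers,
            "true_z": np.nan,
            "membrane": np.where(on_inm, "INM", "ONM"),
        }
    )


def render_spot_stack(
    true_positions: Sequence[tuple[float, float]],
    model: PhotonModel,
    frame_size: int = 16,
    seed: int = 0,
    shot_noise: bool = True,
) -> np.ndarray:
    """Render one diffraction-limited spot per frame onto a pixel grid.

    Positions are in nm within the frame; pixel ``i`` spans
    ``[i*a, (i+1)*a)`` nm.  Each frame integrates a 2D Gaussian PSF of sd
    ``model.s_eff`` carrying ``model.N`` photons over the pixel areas (exact
    erf integration, so photons are conserved up to edge clipping), plus
    zero-mean Gaussian background of sd ``model.b`` per pixel.  With
    ``shot_noise`` each signal pixel additionally fluctuates with variance
    ``F`` times its mean, the Gaussian limit of photon counting on a
    detector with excess-noise factor F.
    """
    a = model.a
    extent = frame_size * a
    positions = np.asarray(true_positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("true_positions must be a list of (x, y) pairs in nm")
    if np.any(positions < 0) or np.any(positions >= extent):
        raise ValueError("emitter position outside the frame")

    rng = np.random.default_rng(seed)
    s = model.s_eff
    edges = np.arange(frame_size + 1) * a
    stack = np.empty((len(positions), frame_size, frame_size))
    sqrt2 = math.sqrt(2.0)
    for k, (x0, y0) in enumerate(positions):
        from scipy.special import erf

        cx = 0.5 * (erf((edges[1:] - x0) / (sqrt2 * s))
                    - erf((edges[:-1] - x0) / (sqrt2 * s)))
        cy = 0.5 * (erf((edges[1:] - y0) / (sqrt2 * s))
                    - erf((edges[:-1] - y0) / (sqrt2 * s)))
        frame = model.N * np.outer(cy, cx)  # rows are y
        if shot_noise:
            frame = frame + rng.normal(0.0, np.sqrt(model.F * frame))
        if model.b > 0:
            frame = frame + rng.normal(0.0, model.b, size=frame.shape)
        stack[k] = frame
    return stack
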