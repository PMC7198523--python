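"""Diffusion, membrane distribution, FRAP recovery and translocation rate.

The translocation rate (TR) of an inner-nuclear-membrane protein — how many
molecules cross from the outer to the inner nuclear membrane per minute per
NPC — is derived from single-molecule FRAP observables.  Writing the
measured INM:ONM concentration ratio as a1:a2 (a3 = a1 + a2), with mobile
fractions F_mi / F_mo and diffusion coefficients D_i / D_o on the two
membranes, the fluorescence recovering in a bleached region splits into a
fraction A arriving from the ONM and a fraction B redistributing within the
INM:

    a1*F_mi = A*(a2*F_mo) + B*(a1*F_mi)
    A/B     = (a2*F_mo*D_o) / (a1*F_mi*D_i)

which has the closed-form solution (u = a2*F_mo, v = a1*F_mi)

    A = u*v*D_o / (u^2*D_o + v^2*D_i),   B = v^2*D_i / (u^2*D_o + v^2*D_i)

and the rate per pore follows from the recovery half-time tau_half, the
total copy number N_T and the number of pores per cell:

    R = N_T * a2 * A / (a3 * 2*tau_half * n_NPC)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from npcroute.geometry import NPCGeometry
from npcroute.radial import FWHM_FACTOR
from npcroute.synthetic import TrajectorySet

__all__ = [
    "DiffusionEstimate",
    "TransportRateInputs",
    "TransportRateResult",
    "FrapFit",
    "UnresolvedPeaksError",
    "estimate_diffusion",
    "membrane_ratio",
    "frap_halftime",
    "correct_ratio",
    "transport_rate",
    "compare_rates",
]

NM2_TO_UM2 = 1.0e-6
# tracks longer than this many frames go to the MSD estimator, shorter
# tracks (>= 2 frames) to the jump-distance estimator
MSD_MIN_FRAMES = 7


class UnresolvedPeaksError(ValueError):
    """Raised when the two membrane peaks cannot be separated."""


@dataclass(frozen=True)
class DiffusionEstimate:
    D: float  # um^2/s
    method: str  # "msd", "jump" or "combined"
    n: int  # tracks (msd) or jumps (jump)
    stderr: float  # um^2/s

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")


def _msd_estimate(tracks: TrajectorySet, max_lag: int = 4) -> DiffusionEstimate:
    lengths = tracks.track_lengths()
    eligible = lengths[lengths >= MSD_MIN_FRAMES].index
    if len(eligible) == 0:
        raise ValueError("no tracks long enough for the MSD estimator")
    df = tracks.data[tracks.data["track_id"].isin(eligible)]

    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    per_track = []
    for _, grp in df.groupby("track_id"):
        xy = grp[["x_nm", "y_nm"]].to_numpy()
        for lag in range(1, max_lag + 1):
            if len(xy) > lag:
                d2 = np.sum((xy[lag:] - xy[:-lag]) ** 2, axis=1)
                sums[lag - 1] += d2.sum()
                counts[lag - 1] += d2.size
        step2 = np.sum(np.diff(xy, axis=0) ** 2, axis=1)
        per_track.append(step2.mean() / (4.0 * tracks.dt))
    msd = sums / counts  # nm^2 per lag
    lags_t = np.arange(1, max_lag + 1) * tracks.dt
    # weighted linear fit with free intercept (absorbs localization error);
    # weights follow the number of displacement pairs per lag
    w = counts.astype(float)
    W = np.diag(w)
    X = np.column_stack([lags_t, np.ones(max_lag)])
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ msd)
    D = max(beta[0] / 4.0 * NM2_TO_UM2, 0.0)
    # MSD values across lags reuse the same displacements and are strongly
    # correlated, so the regression covariance understates the error; use
    # the between-track spread of per-track estimates instead
    per_track = np.asarray(per_track) * NM2_TO_UM2
    if len(per_track) > 1:
        stderr = float(per_track.std(ddof=1) / math.sqrt(len(per_track)))
    else:
        stderr = D / math.sqrt(max(counts[0], 1))
    return DiffusionEstimate(
        D=D, method="msd", n=int(len(eligible)), stderr=stderr
    )


def _jump_estimate(tracks: TrajectorySet) -> DiffusionEstimate:
    lengths = tracks.track_lengths()
    eligible = lengths[(lengths >= 2) & (lengths < MSD_MIN_FRAMES)].index
    if len(eligible) == 0:
        raise ValueError("no short tracks for the jump-distance estimator")
    jumps = tracks.displacements(eligible)
    n = jumps.size
    # 2D Brownian jumps are Rayleigh-distributed; the maximum-likelihood
    # estimate of D is the mean squared jump over 4*dt
    D = float(np.sum(jumps**2)) / (4.0 * n * tracks.dt) * NM2_TO_UM2
    return DiffusionEstimate(D=D, method="jump", n=n, stderr=D / math.sqrt(n))


def estimate_diffusion(tracks: TrajectorySet, method: str = "combined") -> DiffusionEstimate:
    """Estimate the diffusion coefficient from single-particle tracks.

    Long trajectories (> 6 frames) are analyzed by a weighted linear fit of
    MSD(lag) = 4*D*lag*dt + c over lags 1-4; short trajectories (2-6 frames)
    by the closed-form maximum-likelihood jump-distance estimator.
    ``"combined"`` averages the two, as both estimators target the same D.
    """
    if method == "msd":
        return _msd_estimate(tracks)
    if method == "jump":
        return _jump_estimate(tracks)
    if method == "combined":
        msd = _msd_estimate(tracks)
        jump = _jump_estimate(tracks)
        return DiffusionEstimate(
            D=0.5 * (msd.D + jump.D),
            method="combined",
            n=msd.n + jump.n,
            stderr=0.5 * math.hypot(msd.stderr, jump.stderr),
        )
    raise ValueError(f"unknown diffusion method {method!r}")


def _two_gauss(y, a1, c1, s1, a2, c2, s2):
    return a1 * np.exp(-((y - c1) ** 2) / (2 * s1 * s1)) + a2 * np.exp(
        -((y - c2) ** 2) / (2 * s2 * s2)
    )


def membrane_ratio(
    table: pd.DataFrame,
    geometry: NPCGeometry | None = None,
    bin_width: float = 2.0,
) -> tuple[float, dict]:
    """INM:ONM population ratio from the axial (y) localization histogram.

    Fits a two-Gaussian model with centers near the two membrane planes;
    each membrane's population is counted within the FWHM window of its
    peak.  Raises :class:`UnresolvedPeaksError` when the fitted peak
    separation does not exceed the sum of the half-FWHMs.
    """
    geometry = geometry or NPCGeometry()
    y = table["y_nm"].to_numpy()
    edges = np.arange(y.min() - bin_width, y.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(y, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    amp0 = counts.max()
    p0 = (amp0, geometry.inm_y, 8.0, amp0, geometry.onm_y, 8.0)
    try:
        popt, _ = curve_fit(_two_gauss, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"membrane peak fit did not converge: {exc}") from exc
    a1, c1, s1, a2, c2, s2 = popt
    s1, s2 = abs(s1), abs(s2)
    if c1 > c2:  # order as (INM, ONM)
        a1, c1, s1, a2, c2, s2 = a2, c2, s2, a1, c1, s1
    fwhm1, fwhm2 = FWHM_FACTOR * s1, FWHM_FACTOR * s2
    if (c2 - c1) <= 0.5 * (fwhm1 + fwhm2):
        raise UnresolvedPeaksError(
            "membrane peaks closer than the sum of their half-FWHMs"
        )
    n_inm = int(np.sum((y >= c1 - fwhm1 / 2) & (y <= c1 + fwhm1 / 2)))
    n_onm = int(np.sum((y >= c2 - fwhm2 / 2) & (y <= c2 + fwhm2 / 2)))
    if n_onm == 0:
        raise ValueError("no localizations within the ONM peak window")
    report = {
        "inm_center": float(c1),
        "onm_center": float(c2),
        "inm_fwhm": float(fwhm1),
        "onm_fwhm": float(fwhm2),
        "n_inm": n_inm,
        "n_onm": n_onm,
    }
    return n_inm / n_onm, report


@dataclass(frozen=True)
class FrapFit:
    """Single-exponential FRAP recovery fit."""

    tau_half: float  # in the units of the time axis
    mobile_fraction: float
    k: float  # recovery rate constant
    i0: float  # post-bleach intensity
    i_inf: float  # plateau intensity


def frap_halftime(
    time: np.ndarray, intensity: np.ndarray, pre_bleach: float
) -> FrapFit:
    """Fit I(t) = I0 + (Iinf - I0)*(1 - exp(-k*t)) to a recovery curve.

    ``tau_half = ln(2)/k`` carries the units of the time axis; the mobile
    fraction is the recovered plateau relative to the pre-bleach baseline,
    (Iinf - I0)/(I_pre - I0).
    """
    time = np.asarray(time, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if time.size < 6:
        raise ValueError("need at least 6 post-bleach points")

    def model(t, i0, i_inf, k):
        return i0 + (i_inf - i0) * (1.0 - np.exp(-k * t))

    i0_guess = float(intensity[0])
    iinf_guess = float(intensity[-1])
    span = time[-1] - time[0] or 1.0
    try:
        popt, _ = curve_fit(
            model, time, intensity,
            p0=(i0_guess, iinf_guess, 1.0 / span), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"FRAP fit did not converge: {exc}") from exc
    i0, i_inf, k = popt
    if k <= 0 or i_inf <= i0:
        raise ValueError("curve does not recover (k <= 0 or no intensity gain)")
    if pre_bleach <= i0:
        raise ValueError("pre-bleach baseline must exceed post-bleach intensity")
    return FrapFit(
        tau_half=math.log(2.0) / k,
        mobile_fraction=(i_inf - i0) / (pre_bleach - i0),
        k=float(k),
        i0=float(i0),
        i_inf=float(i_inf),
    )


def correct_ratio(corrected_mobile_ratio: float, F_mi: float, F_mo: float) -> float:
    """Scale a mobile-pool INM:ONM ratio back to total pools.

    The FRAP-derived ratio reflects only mobile molecules; dividing by the
    INM mobile fraction and multiplying by the ONM mobile fraction restores
    the total-concentration ratio: final = ratio * F_mo / F_mi.  Rounding to
    two significant figures is a reporting decision left to the caller.
    """
    if not (0.0 < F_mi <= 1.0 and 0.0 < F_mo <= 1.0):
        raise ValueError("mobile fractions must lie in (0, 1]")
    if corrected_mobile_ratio <= 0:
        raise ValueError("ratio must be positive")
    return corrected_mobile_ratio * F_mo / F_mi


@dataclass(frozen=True)
class TransportRateInputs:
    """Observables feeding the translocation-rate model (one construct)."""

    a1: float  # INM part of the INM:ONM ratio
    a2: float  # ONM part
    a3: float  # a1 + a2
    F_mi: float  # INM mobile fraction
    F_mo: float  # ONM mobile fraction
    D_i: float  # um^2/s on the INM
    D_o: float  # um^2/s on the ONM
    N_T: float = 150_000.0  # total molecules per cell
    n_NPC: float = 2_000.0  # pores per cell
    tau_half: float = 1.0  # FRAP recovery half-time, minutes

    def __post_init__(self) -> None:
        if not math.isclose(self.a3, self.a1 + self.a2, rel_tol=1e-9):
            raise ValueError("a3 must equal a1 + a2")
        if not (0.0 < self.F_mi <= 1.0 and 0.0 < self.F_mo <= 1.0):
            raise ValueError("mobile fractions must lie in (0, 1]")
        if min(self.a1, self.a2, self.D_i, self.D_o, self.N_T,
               self.n_NPC, self.tau_half) <= 0:
            raise ValueError("all inputs must be positive")


@dataclass(frozen=True)
class TransportRateResult:
    A: float  # fraction of recovery arriving from the ONM
    B: float  # fraction redistributing within the INM
    R: float  # molecules per minute per NPC
    residual_balance: float  # recovery-partition equation residual
    residual_ratio: float  # flux-ratio equation residual


def transport_rate(inputs: TransportRateInputs, tol: float = 1e-10) -> TransportRateResult:
    """Solve the recovery-partition system and return the per-pore rate.

    Closed form with u = a2*F_mo, v = a1*F_mi:
    A = u*v*D_o/(u^2*D_o + v^2*D_i), B = v^2*D_i/(u^2*D_o + v^2*D_i);
    R = N_T*a2*A / (a3 * 2*tau_half * n_NPC).  Both defining equations are
    re-checked to ``tol`` after the solve.
    """
    u = inputs.a2 * inputs.F_mo
    v = inputs.a1 * inputs.F_mi
    denom = u * u * inputs.D_o + v * v * inputs.D_i
    if denom <= 0:
        raise ValueError("degenerate denominator in the A/B solution")
    A = u * v * inputs.D_o / denom
    B = v * v * inputs.D_i / denom
    res_balance = abs(v - (A * u + B * v))
    res_ratio = abs(A / B - (u * inputs.D_o) / (v * inputs.D_i))
    if res_balance > tol * max(v, 1.0):
        raise AssertionError(f"recovery-partition residual {res_balance:g} > tol")
    R = inputs.N_T * inputs.a2 * A / (inputs.a3 * 2.0 * inputs.tau_half * inputs.n_NPC)
    return TransportRateResult(
        A=A, B=B, R=R, residual_balance=res_balance, residual_ratio=res_ratio
    )


def compare_rates(R_ref: float, R_alt: float) -> float:
    """Percent decrease of R_alt relative to R_ref, 100*(1 - R_alt/R_ref).

    Negative values indicate an increase.  Round to the nearest integer
    percent at reporting.
    """
    if R_ref <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (1.0 - R_alt / R_ref)
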