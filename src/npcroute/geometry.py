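"""Domain types shared across the pipeline.

Coordinate conventions
----------------------
All positions are in nanometres.  The pore-centered frame puts the origin on
the NPC's central axis: ``x`` is the transverse (in-plane) axis, ``y`` the
nucleocytoplasmic axis with the outer nuclear membrane (ONM) at +20 nm and
the inner nuclear membrane (INM) at -20 nm, and ``z`` the unobserved depth
axis.  Microscopy records the (x, y) projection only.  Diffusion
coefficients are in um^2/s (1 um^2 = 1e6 nm^2); times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

UM2_TO_NM2 = 1.0e6


@dataclass(frozen=True)
class NPCGeometry:
    """Nominal NPC dimensions (nm), matching cryo-EM and live-cell estimates.

    The central channel has a ~25 nm radius at its narrowest point, the
    peripheral channels sit at ~41 nm radial distance, and the nuclear
    envelope lumen extends to ~68 nm.  The two nuclear membranes are modeled
    as planes at y = +/-20 nm; ``scaffold_span`` is the ~20 nm radial
    thickness of the structural scaffold separating central from peripheral
    channels.
    """

    central_radius: float = 25.0
    peripheral_radius: float = 41.0
    lumen_radius: float = 68.0
    onm_y: float = 20.0
    inm_y: float = -20.0
    scaffold_span: float = 20.0

    def __post_init__(self) -> None:
        if min(self.central_radius, self.peripheral_radius, self.lumen_radius) <= 0:
            raise ValueError("all radii must be positive")
        if not (self.central_radius < self.peripheral_radius < self.lumen_radius):
            raise ValueError(
                "radii must be ordered central < peripheral < lumen"
            )
        if self.onm_y <= self.inm_y:
            raise ValueError("onm_y must exceed inm_y")


@dataclass(frozen=True)
class RouteModel:
    """Generative model of one transport route: a ring of given mean radius.

    Points are drawn with uniform azimuth, radius ~ Normal(mean_radius,
    radial_sd) truncated at zero, and y uniform on [y_low, y_high].
    ``weight`` is the mixture fraction when several routes are combined.
    """

    mean_radius: float
    radial_sd: float = 0.0
    y_low: float = -40.0
    y_high: float = 40.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_radius < 0:
            raise ValueError("mean_radius must be non-negative")
        if self.radial_sd < 0:
            raise ValueError("radial_sd must be non-negative")
        if self.y_low >= self.y_high:
            raise ValueError("y_low must be below y_high")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass(frozen=True)
class PhotonModel:
    """Imaging model for a moving emitter.

    Parameters
    ----------
    N : float
        Collected signal photons per frame.
    F : float
        Excess-noise factor of the detector (2 for EM-CCD).
    a : float
        Effective pixel size at the sample, nm.
    b : float
        Standard deviation of the background, photons per pixel.
    s0 : float
        PSF standard deviation in the focal plane, nm.
    D : float
        Diffusion coefficient of the emitter, um^2/s; motion during the
        exposure blurs the PSF.
    dt : float
        Frame acquisition time, seconds.
    """

    N: float
    F: float = 2.0
    a: float = 240.0
    b: float = 2.0
    s0: float = 150.0
    D: float = 0.0
    dt: float = 4.0e-4

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("photon count N must be positive")
        if self.a <= 0 or self.s0 <= 0 or self.dt <= 0:
            raise ValueError("a, s0 and dt must be positive")
        if self.D < 0 or self.b < 0:
            raise ValueError("D and b must be non-negative")

    @property
    def s_eff(self) -> float:
        """Motion-blurred PSF sd (nm): sqrt(s0^2 + D*dt/3), D in nm^2/s."""
        return math.sqrt(self.s0**2 + self.D * UM2_TO_NM2 * self.dt / 3.0)
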