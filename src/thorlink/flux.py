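"""Particle export fluxes from 234Th/238U disequilibrium.

234Th (half-life 24.1 d) is produced at a known rate by the decay of
conservative 238U, whose activity in seawater is a linear function of
salinity.  Because 234Th is highly particle-reactive it is stripped from the
upper water column by sinking particles, leaving an activity deficit relative
to its parent.  Under a one-dimensional scavenging model at steady state with
negligible advective and diffusive transport, the downward export flux of
234Th across an integration depth ``z_int`` is

    F = lambda_234 * integral_0^z_int (A_U(z) - A_Th(z)) dz

in dpm m^-2 d^-1, with activities in dpm L^-1 converted by 1000 L m^-3.
``z_int`` is the shallowest depth at which daughter and parent have returned
to secular equilibrium (activity ratio = 1 within a configurable tolerance,
persisting at all deeper measurements).  The depth integral uses the
trapezoidal rule on the measured depths, extending the shallowest measured
deficit to the surface as a constant.

Counting uncertainties (1 sigma) propagate in quadrature through the
trapezoid weights; uncertainty in the U-salinity regression coefficients can
optionally be included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .model import RadionuclideProfile, ValidationError

#: 234Th half-life, days.
HALF_LIFE_TH234_D = 24.1


@dataclass(frozen=True)
class DecayConstants:
    """234Th decay constants; lambda = ln(2) / half-life."""

    half_life_th234: float = HALF_LIFE_TH234_D  # d

    @property
    def lambda_th234(self) -> float:
        """Decay constant, d^-1 (~0.028761 for the 24.1 d half-life)."""
        return math.log(2.0) / self.half_life_th234


@dataclass(frozen=True)
class UraniumModel:
    """Linear 238U-activity vs salinity model: A_U = slope * S + intercept.

    The default coefficients (0.0786, -0.315 dpm L^-1) are the widely used
    open-ocean regression; both are configurable, optionally with 1-sigma
    coefficient uncertainties.
    """

    slope: float = 0.0786  # dpm L^-1 per salinity unit
    intercept: float = -0.315  # dpm L^-1
    valid_salinity_range: tuple[float, float] = (30.0, 38.0)
    slope_sigma: float = 0.0
    intercept_sigma: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.valid_salinity_range
        if lo >= hi:
            raise ValidationError("valid_salinity_range must be (low, high)")
        if self.slope * lo + self.intercept <= 0 or self.slope * hi + self.intercept <= 0:
            raise ValidationError(
                "uranium model yields non-positive activity inside its valid range"
            )


def uranium_from_salinity(
    salinity: float | np.ndarray, model: UraniumModel = UraniumModel()
) -> np.ndarray | float:
    """238U activity (dpm L^-1) from salinity via the linear model.

    Raises :class:`ValidationError` when salinity falls outside the model's
    valid range.
    """
    s = np.asarray(salinity, dtype=float)
    lo, hi = model.valid_salinity_range
    if np.any((s < lo) | (s > hi)):
        raise ValidationError(
            f"salinity {salinity!r} outside the model's valid range [{lo}, {hi}]"
        )
    out = model.slope * s + model.intercept
    return float(out) if np.isscalar(salinity) else out


def uranium_sigma(
    salinity: float | np.ndarray, model: UraniumModel
) -> np.ndarray | float:
    """1-sigma of the modelled 238U activity from coefficient uncertainties."""
    s = np.asarray(salinity, dtype=float)
    out = np.sqrt((s * model.slope_sigma) ** 2 + model.intercept_sigma**2)
    return float(out) if np.isscalar(salinity) else out


class EquilibriumDepth(NamedTuple):
    """Secular-equilibrium depth search result."""

    depth: float  # m
    index: int  # index into the profile's depth array
    reached: bool  # False -> never equilibrated; depth is the deepest sample


def equilibrium_depth(
    profile: RadionuclideProfile,
    u_model: UraniumModel = UraniumModel(),
    tolerance: float = 0.05,
) -> EquilibriumDepth:
    """Shallowest measured depth of persistent 234Th/238U secular equilibrium.

    The activity ratio must be within ``tolerance`` of 1 at the identified
    depth, and no deeper measurement may fall back into deficit (ratio below
    ``1 - tolerance``): a transient crossing followed by a renewed deficit
    does not qualify.  Deeper excursions *above* ``1 + tolerance`` indicate
    excess 234Th, not renewed scavenging, and do not restart the search —
    a two-sided persistence rule would let ordinary counting noise on
    already-equilibrated deep samples drag the integration depth (and the
    excess region's negative deficits) into the flux.  If equilibrium is
    never reached the deepest measured depth is returned flagged
    (``reached=False``) so the resulting flux can be reported as a lower
    bound.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be > 0")
    a_u = np.asarray(uranium_from_salinity(profile.salinity, u_model))
    ratio = profile.th234 / a_u
    within = np.abs(ratio - 1.0) <= tolerance
    no_deficit = ratio >= 1.0 - tolerance
    # deficit_free[i]: no depth from i downward returns to a deficit
    deficit_free = np.logical_and.accumulate(no_deficit[::-1])[::-1]
    idx = np.flatnonzero(within & deficit_free)
    if idx.size:
        i = int(idx[0])
        return EquilibriumDepth(float(profile.depths[i]), i, True)
    i = profile.depths.size - 1
    return EquilibriumDepth(float(profile.depths[i]), i, False)


def _trapezoid_weights(depths: np.ndarray, z_int: float) -> np.ndarray:
    """Trapezoid quadrature weights over [0, z_int] for values at ``depths``.

    The surface boundary uses constant extrapolation of the shallowest
    measurement, which adds its depth to the first weight.  ``z_int`` must be
    one of the measured depths (callers integrate to a measured depth).
    """
    used = depths[depths <= z_int + 1e-9]
    n = used.size
    w = np.zeros(n)
    if n == 0:
        return w
    if n == 1:
        w[0] = z_int
        return w
    dz = np.diff(used)
    w[0] = used[0] + dz[0] / 2.0  # surface extension + first half-interval
    w[1:-1] = (used[2:] - used[:-2]) / 2.0
    w[-1] = dz[-1] / 2.0
    return w


def integrate_deficit(
    profile: RadionuclideProfile,
    u_model: UraniumModel = UraniumModel(),
    z_int: float | None = None,
    include_u_sigma: bool = False,
) -> tuple[float, float]:
    """Trapezoid-integrated 234Th deficit over [0, z_int], in dpm m^-2.

    Returns ``(deficit, sigma)``; the 1-sigma combines the per-depth activity
    counting errors (and optionally the U-model coefficient errors) in
    quadrature through the trapezoid weights.  Activities are dpm L^-1, so
    the integral is scaled by 1000 L m^-3.
    """
    if z_int is None:
        z_int = float(profile.depths[-1])
    if z_int > profile.depths[-1] + 1e-9:
        raise ValidationError(
            f"z_int={z_int} m exceeds the deepest measurement "
            f"({profile.depths[-1]} m)"
        )
    if z_int < profile.depths[0] - 1e-9:
        raise ValidationError(
            f"z_int={z_int} m is above the shallowest measurement "
            f"({profile.depths[0]} m); no surface rule applies"
        )
    a_u = np.asarray(uranium_from_salinity(profile.salinity, u_model))
    deficit = a_u - profile.th234
    w = _trapezoid_weights(profile.depths, z_int)
    n = w.size
    integral = float(np.dot(w, deficit[:n])) * 1000.0
    var = np.dot(w**2, profile.th234_sigma[:n] ** 2)
    if include_u_sigma:
        su = np.asarray(uranium_sigma(profile.salinity, u_model))
        var += np.dot(w**2, su[:n] ** 2)
    sigma = float(np.sqrt(var)) * 1000.0
    return integral, sigma


@dataclass(frozen=True)
class FluxEstimate:
    """Steady-state 234Th export flux for one station."""

    station: str
    integration_depth: float  # m
    integrated_deficit: float  # dpm m^-2
    flux: float  # dpm m^-2 d^-1
    flux_sigma: float  # dpm m^-2 d^-1
    flags: tuple[str, ...] = field(default=())


def steady_state_flux(
    profile: RadionuclideProfile,
    u_model: UraniumModel = UraniumModel(),
    constants: DecayConstants = DecayConstants(),
    tolerance: float = 0.05,
    include_u_sigma: bool = False,
) -> FluxEstimate:
    """Steady-state 1D scavenging-model export flux for one profile.

    Integrates the deficit down to the secular-equilibrium depth and scales
    by the 234Th decay constant.  Estimates are flagged ``lower_bound`` when
    equilibrium was never reached (integration stops at the deepest sample)
    and ``negative_deficit`` when the water column holds a net 234Th excess
    (the flux is reported negative, not clipped).
    """
    eq = equilibrium_depth(profile, u_model, tolerance)
    deficit, sigma = integrate_deficit(
        profile, u_model, z_int=eq.depth, include_u_sigma=include_u_sigma
    )
    lam = constants.lambda_th234
    flags = []
    if not eq.reached:
        flags.append("lower_bound")
    if deficit < 0:
        flags.append("negative_deficit")
    return FluxEstimate(
        station=profile.station,
        integration_depth=eq.depth,
        integrated_deficit=deficit,
        flux=lam * deficit,
        flux_sigma=lam * sigma,
        flags=tuple(flags),
    )
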