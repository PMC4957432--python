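"""Single-source diffusion kernel with pump decay, and what follows from it.

The calcium released by a point source on one membrane spreads by free 2-D
diffusion while the envelope pumps take it back up at a linear rate.  The
concentration a time ``tau`` after a release, a great-circle distance
``delta_r`` away, is

    K(delta_r, tau) = exp(-delta_r**2 / (4 D tau) - k_s tau) / (4 pi D tau)

in units of 1/um^2; multiplying by the released amount (uM*.um^2) gives a
surface concentration in uM*.  The curved surface is handled by feeding the
great-circle metric into the planar kernel; no wrap-around image terms are
added (for the distances and decay rates of interest the planar solution is
an excellent approximation, see docs/methods.md).

From this kernel follow the two analyses that shape the model's behaviour:
whether a single release can trigger a neighbour at distance ``delta_r``
(the propagation condition, in both bracketed-numeric and closed form), and
how long a channel stays refractory when its re-arming is tied to the decay
of its own released calcium.

Units: concentrations are in uM* — molar over an implicit 1 um deep layer —
so an amount in mol converts to uM*.um^2 by a factor 1e21 (1 um^3 = 1e-15 L).
This is the unique convention under which the compartment refractory period
of 2.86 s follows from sigma = 2e-20 mol, D = 5 um^2/s, k_s = 1/s,
alpha = 0.15 and c_th = 0.0425 uM*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import ConfigurationError, InvalidInputError, NumericalError
from .geometry import SphereGeometry, SphericalPoint, great_circle_distance

__all__ = [
    "MOL_TO_CONC_AREA",
    "Surface",
    "ReleaseAmount",
    "FiringThreshold",
    "TruncationSpec",
    "greens_kernel",
    "concentration_from_events",
    "propagation_condition_numeric",
    "propagation_condition_closed_form",
    "propagation_peak_closed_form",
    "refractory_period",
]

#: mol -> uM*.um^2 under the thin-layer (1 um implicit depth) convention.
MOL_TO_CONC_AREA = 1.0e21


@dataclass(frozen=True)
class Surface:
    """One side of the nuclear envelope.

    Parameters
    ----------
    side:
        ``"inner"`` (nucleosolic) or ``"outer"`` (cytosolic).
    D:
        Diffusion constant for calcium on this surface, um^2/s.
    k_s:
        Linear pump uptake rate back into the envelope store, 1/s.
    """

    side: Literal["inner", "outer"]
    D: float
    k_s: float

    def __post_init__(self) -> None:
        if self.side not in ("inner", "outer"):
            raise InvalidInputError(f"unknown side {self.side!r}")
        if not (math.isfinite(self.D) and self.D > 0):
            raise InvalidInputError(f"diffusion constant must be > 0, got {self.D}")
        if not (math.isfinite(self.k_s) and self.k_s >= 0):
            raise InvalidInputError(f"pump rate must be >= 0, got {self.k_s}")


@dataclass(frozen=True)
class ReleaseAmount:
    """Amount of calcium released by one channel firing.

    ``sigma_mol`` is the physical amount in mol; ``sigma_conc`` the same
    amount expressed as concentration times area (uM*.um^2), which is what
    multiplies the kernel.
    """

    sigma_mol: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma_mol) and self.sigma_mol >= 0):
            raise InvalidInputError(f"release amount must be >= 0, got {self.sigma_mol}")

    @property
    def sigma_conc(self) -> float:
        return self.sigma_mol * MOL_TO_CONC_AREA

    @classmethod
    def from_conc(cls, sigma_conc: float) -> "ReleaseAmount":
        return cls(sigma_conc / MOL_TO_CONC_AREA)


@dataclass(frozen=True)
class FiringThreshold:
    """CICR firing threshold ``c_th`` (uM*) and the re-arming fraction
    ``alpha``: a channel leaves its refractory state once its own released
    calcium has decayed below ``alpha * c_th``."""

    c_th: float
    alpha: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c_th) and self.c_th > 0):
            raise InvalidInputError(f"threshold must be > 0, got {self.c_th}")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class TruncationSpec:
    """Controls for discarding and coarsening old point-source history.

    ``epsilon`` bounds the relative kernel mass ignored by the age cut-off
    ``T_cut = -ln(epsilon)/k_s``; events older than that are dropped (their
    remaining field is below ``epsilon`` of what they contributed at release,
    which also bounds any distant-source contribution, making a separate
    radial cut-off redundant).  ``merge_age_fraction`` and ``exact_window``
    govern the amplitude-conserving temporal coarsening of pore-pulse
    history used by the simulator: pulses younger than ``exact_window``
    seconds are kept per time step, older pulses are pairwise merged as long
    as the merged bin half-width stays below ``merge_age_fraction`` times
    its age (second-order accurate, see docs/methods.md).
    """

    epsilon: float = 1.0e-6
    merge_age_fraction: float = 0.1
    exact_window: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise InvalidInputError(f"epsilon must lie in (0, 1), got {self.epsilon}")
        if self.merge_age_fraction < 0 or self.exact_window < 0:
            raise InvalidInputError("truncation controls must be non-negative")

    def t_cut(self, surface: Surface, horizon: float = math.inf) -> float:
        if surface.k_s <= 0:
            return horizon
        return min(horizon, -math.log(self.epsilon) / surface.k_s)


def greens_kernel(delta_r, tau, surface: Surface):
    """Kernel value (1/um^2) at great-circle distance ``delta_r`` and age
    ``tau``; multiply by an amount in uM*.um^2 to obtain uM*.

    Accepts scalars or arrays; ``tau`` must be strictly positive (a source
    must never be evaluated at or before its own emission time).
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0.0) or not np.all(np.isfinite(tau_arr)):
        raise InvalidInputError("kernel age tau must be finite and > 0")
    dr = np.asarray(delta_r, dtype=float)
    four_dt = 4.0 * surface.D * tau_arr
    val = np.exp(-dr**2 / four_dt - surface.k_s * tau_arr) / (np.pi * four_dt)
    if np.isscalar(delta_r) and np.isscalar(tau):
        return float(val)
    return val


def concentration_from_events(
    probe: SphericalPoint,
    t: float,
    events: Iterable[tuple[SphericalPoint, float, float]],
    surface: Surface,
    geom: SphereGeometry,
    truncation: TruncationSpec | None = None,
) -> float:
    """Superpose the kernel over past point releases at one probe.

    ``events`` are ``(position, emission time, amount in uM*.um^2)`` tuples;
    amounts may be negative (pore pulses withdraw calcium).  Events older
    than the truncation age cut-off are skipped.
    """
    truncation = truncation or TruncationSpec()
    t_cut = truncation.t_cut(surface)
    total = 0.0
    for pos, t_ev, amount in events:
        age = t - t_ev
        if age <= 0.0:
            raise InvalidInputError(
                f"event at t={t_ev} not strictly before evaluation time t={t}"
            )
        if age > t_cut or amount == 0.0:
            continue
        dr = great_circle_distance(probe, pos, geom)
        total += amount * greens_kernel(dr, age, surface)
    return total


def _peak_self(t: float, delta_r: float, surface: Surface) -> float:
    return math.exp(
        -delta_r**2 / (4.0 * surface.D * t) - surface.k_s * t
    ) / (4.0 * math.pi * surface.D * t)


def propagation_condition_numeric(
    delta_r_bar: float,
    surface: Surface,
    release: ReleaseAmount,
    threshold: FiringThreshold,
) -> tuple[bool, float, float]:
    """Can one release trigger a channel ``delta_r_bar`` away?

    Maximises the released concentration over time by bracketed 1-D
    optimisation (the profile at fixed distance is unimodal in time) and
    compares the peak with the firing threshold.  Returns
    ``(satisfied, t_star, peak concentration)``.
    """
    if not (math.isfinite(delta_r_bar) and delta_r_bar > 0):
        raise InvalidInputError(f"delta_r_bar must be > 0, got {delta_r_bar}")
    t_free = delta_r_bar**2 / (4.0 * surface.D)  # maximiser when pumps are off
    if surface.k_s == 0.0:
        t_star = t_free
        peak = release.sigma_conc * _peak_self(t_star, delta_r_bar, surface)
        return (peak >= threshold.c_th, t_star, peak)
    # pumps only pull the maximiser earlier, so [tiny, t_free] brackets it
    res = minimize_scalar(
        lambda t: -_peak_self(t, delta_r_bar, surface),
        bounds=(1e-12 * max(t_free, 1.0), 1.0000001 * t_free),
        method="bounded",
        options={"xatol": 1e-13 * max(t_free, 1.0)},
    )
    if not res.success:
        raise NumericalError(f"peak bracketing failed for delta_r={delta_r_bar}")
    t_star = float(res.x)
    peak = release.sigma_conc * float(-res.fun)
    return (peak >= threshold.c_th, t_star, peak)


def propagation_peak_closed_form(
    delta_r_bar: float, surface: Surface, release: ReleaseAmount
) -> float:
    """Closed-form peak concentration reached at distance ``delta_r_bar``.

    With ``s = sqrt(1 + k_s delta_r**2 / D)`` the released concentration
    peaks at ``t* = (s - 1) / (2 k_s)`` with value

        sigma * k_s / (2 pi D (s-1)) *
            exp(- k_s delta_r**2 / (2 D (s-1)) - (s-1)/2).

    For ``k_s = 0`` this degenerates to ``sigma e^-1 / (pi delta_r**2)``.
    """
    if not (math.isfinite(delta_r_bar) and delta_r_bar > 0):
        raise InvalidInputError(f"delta_r_bar must be > 0, got {delta_r_bar}")
    D, ks = surface.D, surface.k_s
    if ks == 0.0:
        return release.sigma_conc * math.exp(-1.0) / (math.pi * delta_r_bar**2)
    s = math.sqrt(1.0 + ks * delta_r_bar**2 / D)
    return (
        release.sigma_conc
        * ks
        / (2.0 * math.pi * D * (s - 1.0))
        * math.exp(-ks * delta_r_bar**2 / (2.0 * D * (s - 1.0)) - (s - 1.0) / 2.0)
    )


def propagation_condition_closed_form(
    delta_r_bar: float,
    surface: Surface,
    release: ReleaseAmount,
    threshold: FiringThreshold,
) -> bool:
    """Closed-form version of the propagation condition (peak >= c_th)."""
    return propagation_peak_closed_form(delta_r_bar, surface, release) >= threshold.c_th


def refractory_period(
    surface: Surface,
    release: ReleaseAmount,
    threshold: FiringThreshold,
    rtol: float = 1e-9,
) -> float:
    """Time for a channel's own released calcium to fall to ``alpha*c_th``.

    "Self" concentration is evaluated at the channel's own location
    (distance zero) and includes no other sources:
    ``sigma / (4 pi D t) * exp(-k_s t)``, which decreases monotonically
    from an arbitrarily large value at small ``t``, so the downward crossing
    sought here is the largest (and only) root.  Found by bracketed
    root-finding on the decreasing tail.
    """
    level = threshold.alpha * threshold.c_th
    sigma = release.sigma_conc
    if sigma <= 0 or level <= 0:
        raise ConfigurationError(
            "refractory period needs a positive release amount and re-arming level"
        )

    def excess(t: float) -> float:
        return sigma * math.exp(-surface.k_s * t) / (4.0 * math.pi * surface.D * t) - level

    # with pumps off the root is exactly sigma/(4 pi D level); pumping only
    # brings the crossing earlier, so that value is an upper bracket
    hi = sigma / (4.0 * math.pi * surface.D * level)
    lo = hi * 1e-12
    if excess(lo) <= 0.0:
        raise ConfigurationError(
            "self-released calcium never exceeds alpha*c_th: release too weak "
            f"(sigma_conc={sigma}, level={level})"
        )
    return float(brentq(excess, lo, hi * 1.0000001, rtol=rtol, maxiter=200))
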