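"""The three canonical numerical experiments and their readouts.

* **Transmission saturation** — how much calcium a single channel firing on
  one side of the envelope delivers to a probe on the other side, as the
  density of evenly spaced pores grows; transmission saturates once the
  envelope is effectively transparent, at which point (for equal diffusion
  constants) exactly half of the released calcium ends up on each side.
* **Per-pore contribution decomposition** — with pores queued along the
  great arc between the source channel and the probe, how much each pore's
  pulses contribute (signed) to the probe concentration up to its peak.
* **Coupled oscillations** — 24 channels per side coupled by a large pore
  population; each compartment fires at its own refractory-period-limited
  rate, the low-D side driven by influx from the high-D side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigurationError, InconclusiveResultError, InvalidInputError
from .geometry import (
    SphereGeometry,
    SphericalPoint,
    arc_queue_points,
    golden_spiral_points,
    great_circle_distance,
    random_uniform_points,
    unit_vectors,
)
from .kernel import (
    FiringThreshold,
    ReleaseAmount,
    Surface,
    TruncationSpec,
    greens_kernel,
    propagation_peak_closed_form,
)
from .simulator import (
    Channel,
    EnvelopeParams,
    Pore,
    Probe,
    Scenario,
    SimulationConfig,
    SimulationRecord,
    run,
)

__all__ = [
    "TransmissionResult",
    "SaturationEstimate",
    "PoreContribution",
    "OscillationSummary",
    "transmission_experiment",
    "saturation_density",
    "intermediate_D_equivalence",
    "pore_contribution_decomposition",
    "oscillation_experiment",
    "frequency_estimate",
]


@dataclass
class TransmissionResult:
    """Peak probe concentrations across a pore-count sweep.

    ``peaks`` are maxima over time of the opposite-side probe concentration,
    expressed as a fraction of the released amount sigma (i.e. divided by
    sigma in uM*.um^2); ``ref_full``/``ref_half`` are the no-pore same-side
    peaks at sigma and sigma/2 on the same normalisation.
    """

    pore_counts: np.ndarray
    densities: np.ndarray  # pores per um^2
    peaks: np.ndarray  # fraction of sigma
    ref_full: float
    ref_half: float
    separation: float
    normalisation: str = "peak concentration divided by sigma_conc (uM*.um^2)"


@dataclass
class SaturationEstimate:
    """Smallest evaluated density reaching ``fraction`` of the plateau."""

    density: float  # pores per um^2
    grid_step: float  # local density grid resolution around the estimate
    plateau: float  # fraction-of-sigma transmission at the plateau
    fraction: float


@dataclass
class PoreContribution:
    """Signed per-pore contribution fractions to the probe peak."""

    fractions: np.ndarray  # sum to 1 by normalisation; entries may be < 0
    contributions: np.ndarray  # un-normalised, uM*
    distances_to_source: np.ndarray  # arc distance from the channel C, um
    t_peak: float  # accumulation cut-off: time of the probe maximum


@dataclass
class OscillationSummary:
    """Firing-interval and trace statistics of a two-sided oscillation run."""

    intervals: dict[str, np.ndarray]
    median_interval: dict[str, float]
    sustained: dict[str, bool]
    peak_amplitude: dict[tuple[str, str], float]  # (side, 'local'|'global')
    local_global_ratio: dict[str, float]
    tau_R: dict[str, float | None]
    record: SimulationRecord


# -- defaults shared by the experiments (the envelope the model describes) --

_DEFAULT_GEOM = SphereGeometry(radius=8.0)
_DEFAULT_RELEASE = ReleaseAmount(sigma_mol=2.0e-20)
_DEFAULT_THRESHOLD = FiringThreshold(c_th=0.0425, alpha=0.15)
_DEFAULT_ENVELOPE = EnvelopeParams(delta_m=0.01, D_P=20.0)
_PORE_DIAMETER = 0.029


def _equator_point(phi: float) -> SphericalPoint:
    return SphericalPoint(math.pi / 2.0, phi)


def _single_release_scenario(
    pores: list[Pore],
    D_outer: float,
    D_inner: float,
    k_s: float,
    separation: float,
    geom: SphereGeometry,
    release: ReleaseAmount,
    env: EnvelopeParams,
    probe_side: Literal["inner", "outer"],
    t_never: float,
) -> Scenario:
    """One channel C on the outer surface, one probe P_N ``separation`` um
    away along the equator (on ``probe_side``), and the given pores."""
    phi0 = math.pi / 4.0
    c_pos = _equator_point(phi0)
    p_pos = _equator_point(phi0 + separation / geom.radius)
    for pore in pores:
        for who, pos in (("source channel", c_pos), ("probe", p_pos)):
            if great_circle_distance(pore.position, pos, geom) < pore.diameter:
                raise ConfigurationError(
                    f"a pore coincides with the {who} (closer than one pore diameter)"
                )
    channel = Channel(
        position=c_pos,
        side="outer",
        release=release,
        threshold=_DEFAULT_THRESHOLD,
        tau_R=t_never,  # fires only once, by the forced stimulus
    )
    return Scenario(
        geometry=geom,
        outer=Surface("outer", D_outer, k_s),
        inner=Surface("inner", D_inner, k_s),
        channels=[channel],
        pores=pores,
        envelope=env,
        probes=[Probe("P_N", p_pos, probe_side)],
    )


def _single_release_config(dt: float, t_max: float, truncation: TruncationSpec,
                           stop_min_time: float) -> SimulationConfig:
    return SimulationConfig(
        dt=dt,
        t_end=t_max,
        truncation=truncation,
        initial_stimulus=("outer", 0, 0.0),
        record_stride=max(1, int(round(0.1 / dt))),
        n_global_probes=0,
        stop_probe="P_N",
        stop_drop_fraction=0.5,
        stop_min_time=stop_min_time,
    )


def _cross_peak(record: SimulationRecord, release: ReleaseAmount) -> float:
    trace = record.probe_traces["P_N"].to_numpy()
    return float(trace.max()) / release.sigma_conc


def transmission_experiment(
    pore_counts: Sequence[int],
    D_outer: float = 20.0,
    D_inner: float = 20.0,
    *,
    k_s: float = 1.0,
    geom: SphereGeometry = _DEFAULT_GEOM,
    release: ReleaseAmount = _DEFAULT_RELEASE,
    env: EnvelopeParams = _DEFAULT_ENVELOPE,
    pore_diameter: float = _PORE_DIAMETER,
    separation: float = 8.0,
    layout: Literal["golden", "random"] = "golden",
    layout_seed: int = 0,
    dt: float = 0.05,
    t_max: float = 6.0,
    truncation: TruncationSpec | None = None,
) -> TransmissionResult:
    """Sweep evenly spaced pore layouts and record cross-envelope peaks.

    For each pore count a single forced release of the outer-side channel C
    is simulated and the maximum over time of the inner-surface
    concentration at the probe P_N is recorded, as a fraction of sigma.
    The two reference values are the no-pore same-side peaks at sigma and
    sigma/2, obtained from the closed-form kernel maximum at the same
    separation (a single free release on one surface is exactly one kernel).

    The half-the-release plateau only appears when the probe sits outside
    the trans-envelope equilibration zone: the kernel peak time at the
    probe, t*(separation), must be large compared with the pore relaxation
    time 1/(2*g*rho) (g = per-pore transfer coefficient, rho = pore
    density).  For D = 20 um^2/s that means separations of roughly 8 um or
    more; at short separations the probe's own peak passes before the two
    surfaces equilibrate and the measured plateau sits below one half.
    """
    if separation <= 0:
        raise InvalidInputError("separation must be positive")
    truncation = truncation or TruncationSpec()
    peaks = []
    for n in pore_counts:
        if n == 0:
            peaks.append(0.0)
            continue
        if layout == "golden":
            pts = golden_spiral_points(n, geom)
        elif layout == "random":
            pts = random_uniform_points(n, geom, layout_seed)
        else:
            raise InvalidInputError(f"unknown layout family {layout!r}")
        scen = None
        for rot in range(20):
            # rotating the whole layout in azimuth keeps it evenly spaced
            # while deterministically stepping any pore off the source/probe
            rotated = [
                SphericalPoint(p.theta, p.phi + rot * 0.0137) for p in pts
            ]
            pores = [Pore(p, pore_diameter) for p in rotated]
            try:
                scen = _single_release_scenario(
                    pores, D_outer, D_inner, k_s, separation, geom, release,
                    env, probe_side="inner", t_never=t_max + 1.0,
                )
                break
            except ConfigurationError:
                continue
        if scen is None:
            raise ConfigurationError(
                f"could not place {n} pores clear of the source and probe"
            )
        cfg = _single_release_config(dt, t_max, truncation, stop_min_time=1.0)
        peaks.append(_cross_peak(run(cfg, scen), release))
    ref_surface = Surface("outer", D_outer, k_s)
    ref_full = propagation_peak_closed_form(separation, ref_surface, release)
    counts = np.asarray(list(pore_counts), dtype=int)
    return TransmissionResult(
        pore_counts=counts,
        densities=counts / geom.area,
        peaks=np.asarray(peaks),
        ref_full=ref_full / release.sigma_conc,
        ref_half=0.5 * ref_full / release.sigma_conc,
        separation=separation,
    )


def saturation_density(
    result: TransmissionResult,
    fraction: float = 0.95,
    geom: SphereGeometry = _DEFAULT_GEOM,
    plateau_rtol: float = 0.02,
) -> SaturationEstimate:
    """Density at which the transmission sweep reaches its plateau.

    The plateau is the mean of the two largest-density grid values, which
    must agree within ``plateau_rtol`` (otherwise the sweep has not
    plateaued and no number is fabricated).  Returns the smallest evaluated
    density whose transmission reaches ``fraction`` of the plateau,
    together with the local grid resolution.
    """
    order = np.argsort(result.densities)
    dens = result.densities[order]
    peaks = result.peaks[order]
    if len(dens) < 2:
        raise InconclusiveResultError("need at least two densities")
    top2 = peaks[-2:]
    if abs(top2[1] - top2[0]) > plateau_rtol * max(abs(top2).max(), 1e-300):
        raise InconclusiveResultError(
            f"no plateau: top-two transmissions {top2} differ by more than "
            f"{plateau_rtol:.0%}"
        )
    plateau = float(top2.mean())
    above = np.nonzero(peaks >= fraction * plateau)[0]
    if len(above) == 0:
        raise InconclusiveResultError("no grid point reaches the plateau fraction")
    i = int(above[0])
    step = dens[i] - dens[i - 1] if i > 0 else dens[i + 1] - dens[i]
    return SaturationEstimate(
        density=float(dens[i]), grid_step=float(step), plateau=plateau,
        fraction=fraction,
    )


@dataclass
class IntermediateDReport:
    """Cross-envelope transmission for (D_lo, D_hi) against a single surface
    at the mean D carrying half the release."""

    cross_peak: float  # fraction of sigma
    single_mid_half_peak: float  # fraction of sigma
    ratio: float


def intermediate_D_equivalence(
    D_lo: float,
    D_hi: float,
    *,
    n_pores: int,
    k_s: float = 1.0,
    geom: SphereGeometry = _DEFAULT_GEOM,
    release: ReleaseAmount = _DEFAULT_RELEASE,
    env: EnvelopeParams = _DEFAULT_ENVELOPE,
    pore_diameter: float = _PORE_DIAMETER,
    separation: float = 8.0,
    dt: float = 0.05,
    t_max: float = 6.0,
    truncation: TruncationSpec | None = None,
) -> IntermediateDReport:
    """Compare a transparent two-surface system with one averaged surface.

    The release happens on the ``D_hi`` (outer) surface; the probe sits on
    the ``D_lo`` (inner) surface.  ``n_pores`` should put the evenly spaced
    layout at transmission saturation.  The reference is a single surface
    at ``(D_lo+D_hi)/2`` carrying ``sigma/2``.
    """
    res = transmission_experiment(
        [n_pores], D_outer=D_hi, D_inner=D_lo, k_s=k_s, geom=geom,
        release=release, env=env, pore_diameter=pore_diameter,
        separation=separation, dt=dt, t_max=t_max, truncation=truncation,
    )
    cross = float(res.peaks[0])
    mid = Surface("outer", 0.5 * (D_lo + D_hi), k_s)
    single_half = 0.5 * propagation_peak_closed_form(separation, mid, release)
    single_half /= release.sigma_conc
    return IntermediateDReport(
        cross_peak=cross,
        single_mid_half_peak=single_half,
        ratio=cross / single_half,
    )


def pore_contribution_decomposition(
    n_pores: int,
    D_outer: float = 2.0,
    D_inner: float = 15.0,
    *,
    k_s: float = 1.0,
    geom: SphereGeometry = _DEFAULT_GEOM,
    release: ReleaseAmount = _DEFAULT_RELEASE,
    env: EnvelopeParams = _DEFAULT_ENVELOPE,
    pore_diameter: float = _PORE_DIAMETER,
    separation: float = 6.0,
    spacing: float | None = None,
    spacing_multiplier: float = 4.0,
    dt: float = 0.01,
    t_max: float = 6.0,
    truncation: TruncationSpec | None = None,
) -> PoreContribution:
    """Signed fraction each queued pore contributes to the probe peak.

    Pores sit on the great arc from the source channel C (outer surface)
    towards the probe P_N (inner surface), queued from C at a fixed spacing
    (default: ``spacing_multiplier`` pore diameters).  After a single forced
    release of C, the contribution of pore k is the sum over time steps up
    to (and excluding) the probe's maximum of the pulse it deposited on the
    inner surface times the inner kernel propagated to the probe; fractions
    are these contributions normalised by their total.
    """
    if n_pores < 1:
        raise InvalidInputError("need at least one pore")
    if spacing is None:
        spacing = spacing_multiplier * pore_diameter
    truncation = truncation or TruncationSpec()
    phi0 = math.pi / 4.0
    c_pos = _equator_point(phi0)
    p_pos = _equator_point(phi0 + separation / geom.radius)
    pts = arc_queue_points(n_pores, c_pos, p_pos, geom, spacing)
    pores = [Pore(p, pore_diameter) for p in pts]
    scen = _single_release_scenario(
        pores, D_outer, D_inner, k_s, separation, geom, release, env,
        probe_side="inner", t_never=t_max + 1.0,
    )
    cfg = _single_release_config(dt, t_max, truncation, stop_min_time=0.5)
    cfg.record_pulses = True
    record = run(cfg, scen)

    trace = record.probe_traces["P_N"].to_numpy()
    times = record.probe_traces["time"].to_numpy()
    i_peak = int(np.argmax(trace))
    if i_peak == 0 or trace[i_peak] <= 0.0:
        raise InconclusiveResultError(
            "probe concentration has no interior maximum; nothing to decompose"
        )
    t_peak = float(times[i_peak])

    inner = Surface("inner", D_inner, k_s)
    pulse_times = record.pulses.index.to_numpy()
    inner_pulses = -record.pulses.to_numpy()  # pulses applied to the inner side
    mask = pulse_times < t_peak - 1e-12
    ages = t_peak - pulse_times[mask]
    d_probe = np.array(
        [great_circle_distance(p, p_pos, geom) for p in pts]
    )
    kern = greens_kernel(d_probe[None, :], ages[:, None], inner)
    contributions = (inner_pulses[mask] * kern).sum(axis=0)
    total = contributions.sum()
    if total == 0.0:
        raise InconclusiveResultError("total pore contribution is zero")
    d_source = np.array([great_circle_distance(p, c_pos, geom) for p in pts])
    return PoreContribution(
        fractions=contributions / total,
        contributions=contributions,
        distances_to_source=d_source,
        t_peak=t_peak,
    )


def oscillation_experiment(
    scenario: Scenario,
    config: SimulationConfig,
) -> OscillationSummary:
    """Run a two-sided oscillation scenario and summarise its rhythm.

    Firing intervals are consecutive differences per channel, pooled per
    side, restricted to the window in which both sides are active (before
    the first scheduled shut-off).  A side whose last firing precedes one
    third of its active window is reported as "oscillation not sustained"
    rather than raising.
    """
    record = run(config, scenario)
    window_end = min(
        [t for t, _ in config.shutoff_schedule], default=config.t_end
    )
    intervals: dict[str, np.ndarray] = {}
    median_interval: dict[str, float] = {}
    sustained: dict[str, bool] = {}
    ev = record.events
    for side in ("outer", "inner"):
        sub = ev[(ev["side"] == side) & (ev["time"] <= window_end + 1e-9)]
        per = []
        for _, grp in sub.groupby("channel_id"):
            t = np.sort(grp["time"].to_numpy())
            if len(t) >= 2:
                per.append(np.diff(t))
        ivals = np.concatenate(per) if per else np.empty(0)
        intervals[side] = ivals
        median_interval[side] = float(np.median(ivals)) if ivals.size else math.nan
        last = sub["time"].max() if len(sub) else -math.inf
        sustained[side] = bool(last >= window_end / 3.0)

    peak_amplitude: dict[tuple[str, str], float] = {}
    ratio: dict[str, float] = {}
    tr = record.traces
    in_window = tr["time"] <= window_end + 1e-9
    for side in ("outer", "inner"):
        for kind in ("local", "global"):
            col = f"{kind}_{side}"
            vals = tr.loc[in_window, col].to_numpy()
            peak_amplitude[(side, kind)] = (
                float(np.nanmax(vals)) if len(vals) else math.nan
            )
        g = peak_amplitude[(side, "global")]
        ratio[side] = peak_amplitude[(side, "local")] / g if g else math.nan
    return OscillationSummary(
        intervals=intervals,
        median_interval=median_interval,
        sustained=sustained,
        peak_amplitude=peak_amplitude,
        local_global_ratio=ratio,
        tau_R=dict(record.tau_R),
        record=record,
    )


def frequency_estimate(
    event_times: Optional[Sequence[float]] = None,
    trace: Optional[np.ndarray] = None,
    times: Optional[np.ndarray] = None,
    peak_fraction: float = 0.5,
) -> float:
    """Median inter-event (or inter-trace-peak) interval, in seconds.

    Trace peaks are local maxima above ``peak_fraction`` of the global
    maximum.  Needs at least three events or peaks; otherwise the estimate
    is inconclusive.
    """
    if event_times is not None:
        t = np.sort(np.asarray(event_times, dtype=float))
        if len(t) < 3:
            raise InconclusiveResultError("need at least three events")
        return float(np.median(np.diff(t)))
    if trace is None or times is None:
        raise InvalidInputError("provide event_times, or trace together with times")
    trace = np.asarray(trace, dtype=float)
    tmax = trace.max()
    if not (tmax > trace.min()):
        raise InconclusiveResultError("trace is constant; no peaks to measure")
    idx, _ = find_peaks(trace, height=peak_fraction * tmax)
    if len(idx) < 3:
        raise InconclusiveResultError(f"only {len(idx)} peaks found; need >= 3")
    return float(np.median(np.diff(np.asarray(times)[idx])))
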