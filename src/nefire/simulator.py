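"""Event engine coupling the two membranes of the nuclear envelope.

Channels fire by calcium-induced calcium release the moment their local
concentration reaches the threshold (and they are armed); each open pore
deposits one flux pulse pair per time step, transferring calcium down the
local concentration gradient between the outer and inner surface.  All
concentrations are lazy superpositions of the single-source kernel over the
recorded release/pulse history — no field is ever stored on a grid.

Scheme notes (see docs/methods.md for the full account):

* The scheme is explicit: gradients driving this step's pore pulses, and
  the concentrations checked against the firing threshold, are evaluated
  from the history up to and including the previous step, so same-step
  pulses (whose kernel age would be zero) never enter an evaluation.
* A pore pulse of size ``omega`` is applied on the outer surface and
  ``-omega`` simultaneously on the inner surface, so transfer is pairwise
  conservative and directed down-gradient.
* Channels can only fire on the step grid; recorded firing times therefore
  respect the refractory period by construction, and a channel whose
  surroundings stay above threshold refires on the first step after it
  re-arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .errors import ConfigurationError, InvalidInputError
from .geometry import (
    SphereGeometry,
    SphericalPoint,
    golden_spiral_points,
    great_circle_distance_matrix,
    mollweide_project,
    points_from_unit_vectors,
    unit_vectors,
)
from .kernel import (
    FiringThreshold,
    ReleaseAmount,
    Surface,
    TruncationSpec,
    refractory_period,
)

__all__ = [
    "Channel",
    "Pore",
    "EnvelopeParams",
    "Probe",
    "Scenario",
    "SimulationConfig",
    "SimulationState",
    "SimulationRecord",
    "pore_flux",
    "initialise",
    "step",
    "run",
    "shutoff",
]

Side = Literal["inner", "outer"]


@dataclass
class Channel:
    """A calcium release channel: point source with CICR firing rule.

    ``tau_R`` may be left ``None`` to have it derived from the compartment
    kernel at setup (the compartment-characteristic refractory period), or
    set explicitly (e.g. effectively infinite for a channel that is only
    ever force-fired once).
    """

    position: SphericalPoint
    side: Side
    release: ReleaseAmount
    threshold: FiringThreshold
    tau_R: Optional[float] = None
    enabled: bool = True


@dataclass
class Pore:
    """A nuclear pore: point coupler between the two surfaces."""

    position: SphericalPoint
    diameter: float  # um
    open: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.diameter) and self.diameter > 0):
            raise InvalidInputError(f"pore diameter must be > 0, got {self.diameter}")


@dataclass(frozen=True)
class EnvelopeParams:
    """Geometry of the passage through the envelope: thickness ``delta_m``
    (um) and in-pore diffusion constant ``D_P`` (um^2/s)."""

    delta_m: float
    D_P: float

    def __post_init__(self) -> None:
        if self.delta_m <= 0 or self.D_P <= 0:
            raise InvalidInputError("envelope thickness and D_P must be positive")


@dataclass(frozen=True)
class Probe:
    """A named fixed measurement location on one surface, recorded at every
    time step."""

    name: str
    position: SphericalPoint
    side: Side


@dataclass
class Scenario:
    """A complete physical setup: geometry, the two surfaces, the channels
    and pores with their parameters, and any named probes."""

    geometry: SphereGeometry
    outer: Surface
    inner: Surface
    channels: list[Channel]
    pores: list[Pore]
    envelope: EnvelopeParams
    probes: list[Probe] = field(default_factory=list)

    def channels_on(self, side: Side) -> list[Channel]:
        return [c for c in self.channels if c.side == side]

    def surface(self, side: Side) -> Surface:
        return self.outer if side == "outer" else self.inner


@dataclass
class SimulationConfig:
    """Time stepping, stimulus, recording and truncation controls.

    ``initial_stimulus`` is ``(side, channel index, time)``: that channel is
    force-fired to ignite the dynamics.  ``shutoff_schedule`` lists
    ``(time, side)`` pairs at which all channels of a side are disabled
    (pores are unaffected).  The declarative early-stop fields let single
    -release experiments end once a probe trace has passed its peak, while
    keeping runs reproducible from the recorded configuration alone.
    """

    dt: float = 1.0e-3
    t_end: float = 1.0
    seed: int = 0
    truncation: TruncationSpec = field(default_factory=TruncationSpec)
    shutoff_schedule: tuple[tuple[float, Side], ...] = ()
    initial_stimulus: Optional[tuple[Side, int, float]] = None
    refractory_mode: Literal["compartment", "local"] = "compartment"
    record_stride: int = 1
    n_global_probes: int = 600
    local_probe_offset: float = 0.15
    local_probes_per_channel: int = 3
    snapshot_times: tuple[float, ...] = ()
    snapshot_grid: tuple[int, int] = (180, 360)
    record_pulses: bool = False
    stop_probe: Optional[str] = None
    stop_drop_fraction: float = 0.5
    stop_min_time: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidInputError(f"dt must be > 0, got {self.dt}")
        if self.t_end < 0:
            raise InvalidInputError(f"t_end must be >= 0, got {self.t_end}")
        for t_s, side in self.shutoff_schedule:
            if not 0.0 <= t_s <= self.t_end:
                raise InvalidInputError(
                    f"shut-off time {t_s} outside [0, t_end={self.t_end}]"
                )
            if side not in ("inner", "outer"):
                raise InvalidInputError(f"unknown side {side!r} in shut-off schedule")
        if self.record_stride < 1:
            raise InvalidInputError("record_stride must be >= 1")


def pore_flux(
    pore: Pore,
    c_outer_at_pore: float,
    c_inner_at_pore: float,
    env: EnvelopeParams,
    dt: float,
) -> float:
    """Flux pulse through one pore over one time step (uM*.um^2).

    Fick's law through a cylinder of the envelope's thickness:
    ``omega = -(D_P/delta_m) (c_o - c_i) pi (p_d/2)^2 dt``.  The returned
    value is applied on the outer surface; ``-omega`` goes on the inner
    surface, so the pair conserves calcium and moves it down-gradient.
    A closed pore passes nothing.
    """
    if not pore.open:
        return 0.0
    return (
        -env.D_P
        / env.delta_m
        * (c_outer_at_pore - c_inner_at_pore)
        * math.pi
        * (pore.diameter / 2.0) ** 2
        * dt
    )


class _PulseHistory:
    """Time-stamped pore-pulse history for one surface, with age cut-off and
    amplitude-conserving temporal coarsening of old entries."""

    def __init__(self, n_sources: int):
        self.n_sources = n_sources
        self.times: list[float] = []
        self.halfwidths: list[float] = []
        self.omegas: list[np.ndarray] = []

    def add(self, t: float, omega: np.ndarray, halfwidth: float) -> None:
        self.times.append(t)
        self.halfwidths.append(halfwidth)
        self.omegas.append(omega)

    def compact(self, t_now: float, trunc: TruncationSpec, t_cut: float) -> None:
        # drop entries past the age cut-off (oldest first)
        while self.times and t_now - self.times[0] > t_cut:
            self.times.pop(0)
            self.halfwidths.pop(0)
            self.omegas.pop(0)
        if trunc.merge_age_fraction <= 0:
            return
        # one pairwise merge pass per step keeps bin widths growing
        # geometrically with age
        i = 0
        while i + 1 < len(self.times):
            lo = self.times[i] - self.halfwidths[i]
            hi = self.times[i + 1] + self.halfwidths[i + 1]
            centre = 0.5 * (lo + hi)
            half = 0.5 * (hi - lo)
            age = t_now - centre
            if age > trunc.exact_window and half <= trunc.merge_age_fraction * age:
                self.times[i] = centre
                self.halfwidths[i] = half
                self.omegas[i] = self.omegas[i] + self.omegas[i + 1]
                del self.times[i + 1]
                del self.halfwidths[i + 1]
                del self.omegas[i + 1]
            i += 1

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.times:
            return np.empty(0), np.empty((0, self.n_sources))
        return np.asarray(self.times), np.stack(self.omegas)


class _SideState:
    """Mutable per-surface channel and release bookkeeping."""

    def __init__(self, side: Side, channels: list[Channel], scenario: Scenario,
                 config: SimulationConfig):
        self.side = side
        self.surface = scenario.surface(side)
        self.channels = channels
        self.n = len(channels)
        self.positions_uv = unit_vectors([c.position for c in channels])
        self.enabled = np.array([c.enabled for c in channels], dtype=bool)
        self.refractory_until = np.full(self.n, -np.inf)
        self.armed = np.ones(self.n, dtype=bool)  # local refractory mode
        self.c_th = np.array([c.threshold.c_th for c in channels])
        self.alpha_level = np.array(
            [c.threshold.alpha * c.threshold.c_th for c in channels]
        )
        self.sigma = np.array([c.release.sigma_conc for c in channels])
        if config.refractory_mode == "compartment":
            self.tau_R = np.array(
                [
                    c.tau_R
                    if c.tau_R is not None
                    else refractory_period(self.surface, c.release, c.threshold)
                    for c in channels
                ]
            )
        else:
            self.tau_R = np.full(self.n, np.nan)
        # release event log: (source column, time, amount)
        self.ev_src: list[int] = []
        self.ev_time: list[float] = []
        self.ev_amt: list[float] = []

    def add_event(self, idx: int, t: float) -> None:
        self.ev_src.append(idx)
        self.ev_time.append(t)
        self.ev_amt.append(self.sigma[idx])

    def event_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.asarray(self.ev_src, dtype=np.int64),
            np.asarray(self.ev_time),
            np.asarray(self.ev_amt),
        )


@dataclass
class SimulationRecord:
    """Everything a run produced: firing events, probe traces, per-step pore
    pulse totals, optional per-pore pulses and atlas snapshot grids."""

    events: pd.DataFrame
    traces: pd.DataFrame
    probe_traces: pd.DataFrame
    pulse_sums: pd.DataFrame
    snapshots: dict[float, pd.DataFrame]
    pulses: Optional[pd.DataFrame]
    tau_R: dict[Side, float | None]
    stopped_at: float


class SimulationState:
    """Clock plus full event/pulse history of a running simulation.

    Construct with :func:`initialise`; advance with :func:`step` or drive a
    whole run with :func:`run`.
    """

    def __init__(self, scenario: Scenario, config: SimulationConfig):
        self.scenario = scenario
        self.config = config
        self.geom = scenario.geometry
        self.t = 0.0
        self.step_index = 0

        self.outer_side = _SideState("outer", scenario.channels_on("outer"), scenario, config)
        self.inner_side = _SideState("inner", scenario.channels_on("inner"), scenario, config)

        pores = scenario.pores
        self.n_pores = len(pores)
        self.pore_uv = unit_vectors([p.position for p in pores])
        self.pore_open = np.array([p.open for p in pores], dtype=bool)
        self.pore_area = np.array(
            [math.pi * (p.diameter / 2.0) ** 2 for p in pores]
        )
        self.pulse_outer = _PulseHistory(self.n_pores)
        self.pulse_inner = _PulseHistory(self.n_pores)

        # core evaluation set: pores, outer channels, inner channels, probes
        blocks = [self.pore_uv, self.outer_side.positions_uv,
                  self.inner_side.positions_uv]
        self.probe_names = [p.name for p in scenario.probes]
        self.probe_sides = [p.side for p in scenario.probes]
        probe_uv = unit_vectors([p.position for p in scenario.probes])
        blocks.append(probe_uv)
        core_uv = np.vstack([b for b in blocks if len(b)]) if any(
            len(b) for b in blocks
        ) else np.empty((0, 3))
        n_p = self.n_pores
        n_co = self.outer_side.n
        n_ci = self.inner_side.n
        self.rows_pores = slice(0, n_p)
        self.rows_outer_ch = slice(n_p, n_p + n_co)
        self.rows_inner_ch = slice(n_p + n_co, n_p + n_co + n_ci)
        self.rows_probes = slice(n_p + n_co + n_ci, n_p + n_co + n_ci + len(probe_uv))
        self.core_d2_pores = self._d2(core_uv, self.pore_uv)
        self.core_d2_outer_ch = self._d2(core_uv, self.outer_side.positions_uv)
        self.core_d2_inner_ch = self._d2(core_uv, self.inner_side.positions_uv)

        # recording probe sets (evaluated at the recording stride only)
        self._setup_recording_probes()

        # logs
        self.event_log: list[tuple[float, Side, int]] = []
        self.trace_rows: list[tuple] = []
        self.probe_rows: list[tuple] = []
        self.pulse_sum_rows: list[tuple[float, float, float]] = []
        self.pulse_rows: list[np.ndarray] = []
        self.pulse_row_times: list[float] = []
        self.snapshots: dict[float, pd.DataFrame] = {}
        self._shutoffs_done: set[tuple[float, Side]] = set()
        self.stopped = False

        if config.initial_stimulus is not None:
            side_name, idx, t0 = config.initial_stimulus
            side = self._side(side_name)
            if not 0 <= idx < side.n:
                raise ConfigurationError(
                    f"initial stimulus names channel {idx} on the {side_name} "
                    f"side, which has only {side.n} channels"
                )
            if t0 != 0.0:
                raise ConfigurationError("the forced initial firing must be at t=0")
            side.add_event(idx, 0.0)
            if config.refractory_mode == "compartment":
                side.refractory_until[idx] = side.tau_R[idx]
            else:
                side.armed[idx] = False
            self.event_log.append((0.0, side_name, idx))

        self._record(initial=True)

    # -- helpers ---------------------------------------------------------

    def _d2(self, a_uv: np.ndarray, b_uv: np.ndarray) -> np.ndarray:
        if len(a_uv) == 0 or len(b_uv) == 0:
            return np.empty((len(a_uv), len(b_uv)))
        return great_circle_distance_matrix(a_uv, b_uv, self.geom) ** 2

    def _side(self, name: Side) -> _SideState:
        return self.outer_side if name == "outer" else self.inner_side

    def _setup_recording_probes(self) -> None:
        cfg = self.config
        self.global_uv = unit_vectors(
            golden_spiral_points(cfg.n_global_probes, self.geom)
        ) if cfg.n_global_probes > 0 else np.empty((0, 3))
        self.global_d2_pores = self._d2(self.global_uv, self.pore_uv)
        self.global_d2_ch = {
            "outer": self._d2(self.global_uv, self.outer_side.positions_uv),
            "inner": self._d2(self.global_uv, self.inner_side.positions_uv),
        }
        # channel-neighbourhood probes: a small ring at a fixed offset
        self.local_uv: dict[Side, np.ndarray] = {}
        self.local_d2_pores: dict[Side, np.ndarray] = {}
        self.local_d2_ch: dict[Side, np.ndarray] = {}
        ang = cfg.local_probe_offset / self.geom.radius
        for name in ("outer", "inner"):
            side = self._side(name)
            pts = []
            for uv in side.positions_uv:
                # deterministic tangent frame at the channel position
                ref = np.array([0.0, 0.0, 1.0])
                if abs(uv[2]) > 0.9:
                    ref = np.array([1.0, 0.0, 0.0])
                e1 = np.cross(uv, ref)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(uv, e1)
                for j in range(cfg.local_probes_per_channel):
                    a = 2.0 * math.pi * j / cfg.local_probes_per_channel
                    v = (
                        math.cos(ang) * uv
                        + math.sin(ang) * (math.cos(a) * e1 + math.sin(a) * e2)
                    )
                    pts.append(v / np.linalg.norm(v))
            arr = np.asarray(pts) if pts else np.empty((0, 3))
            self.local_uv[name] = arr
            self.local_d2_pores[name] = self._d2(arr, self.pore_uv)
            self.local_d2_ch[name] = self._d2(arr, side.positions_uv)

    def _field(
        self,
        side_name: Side,
        t: float,
        d2_pores: np.ndarray,
        d2_ch: np.ndarray,
    ) -> np.ndarray:
        """Superposed concentration of one surface at precomputed targets."""
        side = self._side(side_name)
        surf = side.surface
        trunc = self.config.truncation
        out = np.zeros(d2_pores.shape[0])
        if out.size == 0:
            return out
        ev_src, ev_time, ev_amt = side.event_arrays()
        if ev_src.size and d2_ch.shape[1]:
            _engine.add_event_field(
                out, d2_ch, ev_src, ev_amt, t - ev_time, surf.D, surf.k_s,
                trunc.t_cut(surf),
            )
        hist = self.pulse_outer if side_name == "outer" else self.pulse_inner
        times, omegas = hist.arrays()
        if times.size:
            _engine.add_pulse_field(
                out, d2_pores, omegas, t - times, surf.D, surf.k_s
            )
        return out

    def fields_at_points(
        self, points: Sequence[SphericalPoint] | np.ndarray, side_name: Side,
        t: Optional[float] = None, chunk: int = 4000,
    ) -> np.ndarray:
        """Evaluate one surface's concentration at arbitrary points at the
        current (or a past) time, chunked to bound memory."""
        t = self.t if t is None else t
        uv = points if isinstance(points, np.ndarray) else unit_vectors(points)
        side = self._side(side_name)
        out = np.empty(len(uv))
        for lo in range(0, len(uv), chunk):
            sub = uv[lo : lo + chunk]
            out[lo : lo + chunk] = self._field(
                side_name,
                t,
                self._d2(sub, self.pore_uv),
                self._d2(sub, side.positions_uv),
            )
        return out

    # -- the step --------------------------------------------------------

    def advance(self) -> None:
        """One explicit time step (see module docstring for the order)."""
        cfg = self.config
        t_new = self.t + cfg.dt
        if t_new > cfg.t_end + 1e-12:
            raise InvalidInputError("stepping past t_end")

        # (1) concentrations at every core point from history <= t
        c_out = self._field("outer", t_new, self.core_d2_pores, self.core_d2_outer_ch)
        c_in = self._field("inner", t_new, self.core_d2_pores, self.core_d2_inner_ch)

        # (2) one flux pulse pair per open pore (explicit in the gradient)
        if self.n_pores:
            env = self.scenario.envelope
            grad = c_out[self.rows_pores] - c_in[self.rows_pores]
            omega = np.where(
                self.pore_open,
                -env.D_P / env.delta_m * grad * self.pore_area * cfg.dt,
                0.0,
            )
            self.pulse_outer.add(t_new, omega, cfg.dt / 2.0)
            self.pulse_inner.add(t_new, -omega, cfg.dt / 2.0)
            self.pulse_sum_rows.append((t_new, float(omega.sum()), float(-omega.sum())))
            if cfg.record_pulses:
                self.pulse_rows.append(omega.copy())
                self.pulse_row_times.append(t_new)

        # (3)+(4) threshold test and firing, per side
        for name, rows in (("outer", self.rows_outer_ch), ("inner", self.rows_inner_ch)):
            side = self._side(name)
            if side.n == 0:
                continue
            c_here = (c_out if name == "outer" else c_in)[rows]
            if cfg.refractory_mode == "compartment":
                ready = side.enabled & (t_new >= side.refractory_until - 1e-12)
            else:
                side.armed |= c_here < side.alpha_level
                ready = side.enabled & side.armed
            fired = ready & (c_here >= side.c_th)
            for idx in np.nonzero(fired)[0]:
                side.add_event(int(idx), t_new)
                self.event_log.append((t_new, name, int(idx)))
                if cfg.refractory_mode == "compartment":
                    side.refractory_until[idx] = t_new + side.tau_R[idx]
                else:
                    side.armed[idx] = False

        # (5) scheduled shut-offs
        for t_s, side_name in cfg.shutoff_schedule:
            key = (t_s, side_name)
            if key not in self._shutoffs_done and t_new >= t_s - 1e-12:
                self._side(side_name).enabled[:] = False
                self._shutoffs_done.add(key)

        self.t = t_new
        self.step_index += 1

        # history upkeep
        horizon = cfg.t_end
        self.pulse_outer.compact(
            t_new, cfg.truncation, cfg.truncation.t_cut(self.outer_side.surface, horizon)
        )
        self.pulse_inner.compact(
            t_new, cfg.truncation, cfg.truncation.t_cut(self.inner_side.surface, horizon)
        )

        # recording
        probes_now = self._record_probes(t_new, c_out, c_in)
        if self.step_index % cfg.record_stride == 0:
            self._record()
        for t_snap in cfg.snapshot_times:
            if abs(t_new - t_snap) < cfg.dt / 2.0 and t_snap not in self.snapshots:
                self.snapshots[t_snap] = self._snapshot(t_new)

        self._maybe_stop(t_new, probes_now)

    def _record_probes(self, t_new, c_out, c_in) -> dict[str, float]:
        vals: dict[str, float] = {}
        if self.probe_names:
            block_out = c_out[self.rows_probes]
            block_in = c_in[self.rows_probes]
            for j, (name, side) in enumerate(zip(self.probe_names, self.probe_sides)):
                vals[name] = float(block_out[j] if side == "outer" else block_in[j])
            self.probe_rows.append((t_new, *[vals[n] for n in self.probe_names]))
        return vals

    def _record(self, initial: bool = False) -> None:
        t = self.t
        row = [t]
        for name in ("outer", "inner"):
            side = self._side(name)
            if side.n and self.local_uv[name].size:
                loc = self._field(
                    name, t if not initial else 0.0,
                    self.local_d2_pores[name], self.local_d2_ch[name],
                ) if not initial else np.zeros(len(self.local_uv[name]))
                row.append(float(loc.mean()))
            else:
                row.append(math.nan)
            if len(self.global_uv):
                glob = self._field(
                    name, t, self.global_d2_pores, self.global_d2_ch[name]
                ) if not initial else np.zeros(len(self.global_uv))
                row.append(float(glob.mean()))
            else:
                row.append(math.nan)
        self.trace_rows.append(tuple(row))
        if initial and self.probe_names:
            self.probe_rows.append((0.0, *[0.0] * len(self.probe_names)))

    def _maybe_stop(self, t_new: float, probes_now: dict[str, float]) -> None:
        cfg = self.config
        if cfg.stop_probe is None or t_new < cfg.stop_min_time:
            return
        if cfg.stop_probe not in self.probe_names:
            raise ConfigurationError(f"unknown stop probe {cfg.stop_probe!r}")
        col = self.probe_names.index(cfg.stop_probe)
        trace = np.array([r[1 + col] for r in self.probe_rows])
        peak = trace.max()
        if peak <= 0.0 or trace[-1] <= cfg.stop_drop_fraction * peak:
            self.stopped = True

    def _snapshot(self, t: float) -> pd.DataFrame:
        n_t, n_ph = self.config.snapshot_grid
        theta = (np.arange(n_t) + 0.5) * math.pi / n_t
        phi = np.arange(n_ph) * 2.0 * math.pi / n_ph
        tg, pg = np.meshgrid(theta, phi, indexing="ij")
        pts = [SphericalPoint(tt, pp) for tt, pp in zip(tg.ravel(), pg.ravel())]
        uv = unit_vectors(pts)
        c_i = self.fields_at_points(uv, "inner", t)
        c_o = self.fields_at_points(uv, "outer", t)
        proj = np.array([mollweide_project(p) for p in pts])
        return pd.DataFrame(
            {
                "theta": tg.ravel(),
                "phi": pg.ravel(),
                "x_mollweide": proj[:, 0],
                "y_mollweide": proj[:, 1],
                "c_inner": c_i,
                "c_outer": c_o,
            }
        )

    # -- export ----------------------------------------------------------

    def record(self) -> SimulationRecord:
        events = pd.DataFrame(self.event_log, columns=["time", "side", "channel_id"])
        traces = pd.DataFrame(
            self.trace_rows,
            columns=["time", "local_outer", "global_outer", "local_inner", "global_inner"],
        )
        probe_traces = pd.DataFrame(
            self.probe_rows, columns=["time", *self.probe_names]
        )
        pulse_sums = pd.DataFrame(
            self.pulse_sum_rows, columns=["time", "outer_total", "inner_total"]
        )
        pulses = None
        if self.config.record_pulses and self.pulse_rows:
            pulses = pd.DataFrame(
                np.stack(self.pulse_rows),
                index=pd.Index(self.pulse_row_times, name="time"),
                columns=[f"pore_{k}" for k in range(self.n_pores)],
            )
        tau_R = {}
        for name in ("outer", "inner"):
            side = self._side(name)
            tau_R[name] = (
                float(side.tau_R[0])
                if side.n and np.isfinite(side.tau_R).all()
                else None
            )
        return SimulationRecord(
            events=events,
            traces=traces,
            probe_traces=probe_traces,
            pulse_sums=pulse_sums,
            snapshots=dict(self.snapshots),
            pulses=pulses,
            tau_R=tau_R,
            stopped_at=self.t,
        )


def initialise(scenario: Scenario, config: SimulationConfig) -> SimulationState:
    """Build a ready-to-step simulation state (fires the initial stimulus)."""
    return SimulationState(scenario, config)


def step(state: SimulationState, config: SimulationConfig | None = None) -> SimulationState:
    """Advance the state by one time step and return it."""
    if config is not None and config is not state.config:
        state.config = config
    state.advance()
    return state


def shutoff(state: SimulationState, side: Side) -> SimulationState:
    """Disable all channels of a side from the current time on.  Their past
    releases keep diffusing; pores are unaffected."""
    if side not in ("inner", "outer"):
        raise InvalidInputError(f"unknown side {side!r}")
    state._side(side).enabled[:] = False
    return state


def run(config: SimulationConfig, scenario: Scenario) -> SimulationRecord:
    """Iterate the engine to ``t_end`` (or an early stop) and collect the
    record.  Deterministic for a fixed (scenario, config)."""
    state = initialise(scenario, config)
    n_steps = int(round(config.t_end / config.dt))
    for _ in range(n_steps):
        state.advance()
        if state.stopped:
            break
    return state.record()
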