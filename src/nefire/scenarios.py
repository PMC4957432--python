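"""Scenario presets, configuration (de)serialisation, validation, output.

The three presets carry the canonical parameter set of the model:
radius R = 8 um, firing threshold c_th = 0.0425 uM*, release
sigma = 2e-20 mol, re-arming fraction alpha = 0.15, pump rate k_s = 1/s,
pore diameter 0.029 um, envelope thickness 0.01 um, in-pore diffusion
constant 20 um^2/s.  Values the canonical set leaves open (probe
separations, queue spacings, time steps) get documented defaults and are
always written into the run manifest, which is sufficient to reproduce a
run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InvalidInputError
from .geometry import (
    SphereGeometry,
    SphericalPoint,
    golden_spiral_points,
    great_circle_distance,
    random_uniform_points,
)
from .kernel import (
    FiringThreshold,
    ReleaseAmount,
    Surface,
    TruncationSpec,
    propagation_condition_numeric,
    refractory_period,
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
    "MODEL_PARAMS",
    "Finding",
    "preset",
    "default_config",
    "fig4_scenario",
    "validate",
    "scenario_to_dict",
    "scenario_from_dict",
    "config_to_dict",
    "config_from_dict",
    "save_scenario",
    "load_scenario",
    "build_manifest",
    "write_outputs",
    "run_from_manifest",
]

#: The canonical model constants, by name.
MODEL_PARAMS: dict[str, float] = {
    "radius": 8.0,  # um
    "c_th": 0.0425,  # uM*
    "alpha": 0.15,
    "sigma_mol": 2.0e-20,  # mol
    "k_s": 1.0,  # 1/s
    "pore_diameter": 0.029,  # um
    "delta_m": 0.01,  # um
    "D_P": 20.0,  # um^2/s
    "n_channels_per_side": 24,
    "n_pores_fig4": 1500,
    "D_inner_fig4": 5.0,  # um^2/s
    "D_outer_fig4": 20.0,  # um^2/s
}


def _geom() -> SphereGeometry:
    return SphereGeometry(MODEL_PARAMS["radius"])


def _release() -> ReleaseAmount:
    return ReleaseAmount(MODEL_PARAMS["sigma_mol"])


def _threshold() -> FiringThreshold:
    return FiringThreshold(MODEL_PARAMS["c_th"], MODEL_PARAMS["alpha"])


def _envelope() -> EnvelopeParams:
    return EnvelopeParams(MODEL_PARAMS["delta_m"], MODEL_PARAMS["D_P"])


def fig4_scenario(
    seed: int = 0,
    n_channels: int = 24,
    n_pores: int = 1500,
    D_outer: float = 20.0,
    D_inner: float = 5.0,
    k_s: float = 1.0,
) -> Scenario:
    """Coupled-oscillation setup: seeded random channels on both sides,
    seeded uniform random pores, low-D nucleosolic surface driven by the
    high-D cytosolic one."""
    geom = _geom()
    rel, th = _release(), _threshold()
    ch_out = random_uniform_points(n_channels, geom, seed * 1000 + 1)
    ch_in = random_uniform_points(n_channels, geom, seed * 1000 + 2)
    pore_pts = random_uniform_points(n_pores, geom, seed * 1000 + 3)
    channels = [
        Channel(p, "outer", rel, th) for p in ch_out
    ] + [Channel(p, "inner", rel, th) for p in ch_in]
    pores = [Pore(p, MODEL_PARAMS["pore_diameter"]) for p in pore_pts]
    return Scenario(
        geometry=geom,
        outer=Surface("outer", D_outer, k_s),
        inner=Surface("inner", D_inner, k_s),
        channels=channels,
        pores=pores,
        envelope=_envelope(),
    )


def _fig2_scenario(n_pores: int = 512, D: float = 20.0, separation: float = 8.0) -> Scenario:
    geom = _geom()
    phi0 = math.pi / 4.0
    c_pos = SphericalPoint(math.pi / 2.0, phi0)
    p_pos = SphericalPoint(math.pi / 2.0, phi0 + separation / geom.radius)
    pores = [
        Pore(p, MODEL_PARAMS["pore_diameter"])
        for p in golden_spiral_points(n_pores, geom)
    ]
    channel = Channel(c_pos, "outer", _release(), _threshold(), tau_R=1.0e6)
    return Scenario(
        geometry=geom,
        outer=Surface("outer", D, 1.0),
        inner=Surface("inner", D, 1.0),
        channels=[channel],
        pores=pores,
        envelope=_envelope(),
        probes=[Probe("P_N", p_pos, "inner")],
    )


def _fig3_scenario(
    n_pores: int = 48,
    D_outer: float = 2.0,
    D_inner: float = 15.0,
    separation: float = 6.0,
    spacing_multiplier: float = 4.0,
) -> Scenario:
    from .geometry import arc_queue_points

    geom = _geom()
    phi0 = math.pi / 4.0
    c_pos = SphericalPoint(math.pi / 2.0, phi0)
    p_pos = SphericalPoint(math.pi / 2.0, phi0 + separation / geom.radius)
    spacing = spacing_multiplier * MODEL_PARAMS["pore_diameter"]
    pores = [
        Pore(p, MODEL_PARAMS["pore_diameter"])
        for p in arc_queue_points(n_pores, c_pos, p_pos, geom, spacing)
    ]
    channel = Channel(c_pos, "outer", _release(), _threshold(), tau_R=1.0e6)
    return Scenario(
        geometry=geom,
        outer=Surface("outer", D_outer, 1.0),
        inner=Surface("inner", D_inner, 1.0),
        channels=[channel],
        pores=pores,
        envelope=_envelope(),
        probes=[Probe("P_N", p_pos, "inner")],
    )


def preset(name: Literal["fig2", "fig3", "fig4"], seed: int = 0, **overrides: Any) -> Scenario:
    """A fully parameterised scenario for one of the three experiments.

    ``fig2``: single outer channel, inner probe, evenly spaced pores;
    ``fig3``: pores queued on the arc between channel and probe;
    ``fig4``: 24 seeded random channels per side, 1500 random pores.
    Unprinted values (separations, spacings, counts below the default) can
    be overridden by keyword and always appear in the manifest.
    """
    builders = {
        "fig2": _fig2_scenario,
        "fig3": _fig3_scenario,
        "fig4": lambda **kw: fig4_scenario(seed=seed, **kw),
    }
    if name not in builders:
        raise InvalidInputError(f"unknown preset {name!r}; choose fig2, fig3 or fig4")
    return builders[name](**overrides)


def default_config(name: Literal["fig2", "fig3", "fig4"]) -> SimulationConfig:
    """Time-stepping defaults matched to each experiment's dynamics."""
    if name == "fig2":
        return SimulationConfig(
            dt=0.05, t_end=6.0, initial_stimulus=("outer", 0, 0.0),
            n_global_probes=0, stop_probe="P_N", stop_min_time=1.0,
        )
    if name == "fig3":
        return SimulationConfig(
            dt=0.01, t_end=6.0, initial_stimulus=("outer", 0, 0.0),
            n_global_probes=0, record_pulses=True,
            stop_probe="P_N", stop_min_time=0.5,
        )
    if name == "fig4":
        return SimulationConfig(
            dt=0.1, t_end=25.0, initial_stimulus=("inner", 0, 0.0),
            shutoff_schedule=((15.0, "inner"),),
            record_stride=2, n_global_probes=600,
        )
    raise InvalidInputError(f"unknown preset {name!r}")


# -- validation ------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    level: Literal["error", "warning"]
    code: str
    message: str


def validate(scenario: Scenario, config: SimulationConfig) -> list[Finding]:
    """Static checks a run should pass before spending compute on it.

    Returns findings instead of raising, so callers can decide severity.
    """
    findings: list[Finding] = []
    geom = scenario.geometry
    # refractory feasibility per side (compartment mode derives tau_R)
    if config.refractory_mode == "compartment":
        for side in ("outer", "inner"):
            for ch in scenario.channels_on(side):
                if ch.tau_R is not None:
                    continue
                try:
                    refractory_period(scenario.surface(side), ch.release, ch.threshold)
                except ConfigurationError as exc:
                    findings.append(
                        Finding("error", "no-refractory-crossing",
                                f"{side} side: {exc}")
                    )
                break  # identical parameters per side; one check suffices
    # dt versus the fastest kernel peak between channel neighbours
    for side in ("outer", "inner"):
        chans = scenario.channels_on(side)
        if len(chans) < 2:
            continue
        dmin = min(
            great_circle_distance(a.position, b.position, geom)
            for i, a in enumerate(chans)
            for b in chans[i + 1:]
        )
        if dmin <= 0:
            findings.append(
                Finding("error", "coincident-channels",
                        f"two {side} channels share a position")
            )
            continue
        _, t_star, _ = propagation_condition_numeric(
            dmin, scenario.surface(side), chans[0].release, chans[0].threshold
        )
        if t_star < 5.0 * config.dt:
            findings.append(
                Finding(
                    "warning", "dt-too-coarse",
                    f"nearest {side} channel pair peaks at t*={t_star:.4g} s "
                    f"< 5*dt={5 * config.dt:.4g} s; consider a smaller dt",
                )
            )
    # collisions between pores and channels/probes
    targets = [("channel", c.position) for c in scenario.channels]
    targets += [("probe", p.position) for p in scenario.probes]
    for pore in scenario.pores:
        for kind, pos in targets:
            if great_circle_distance(pore.position, pos, geom) < pore.diameter:
                findings.append(
                    Finding("warning", "pore-collision",
                            f"a pore lies within one diameter of a {kind}")
                )
                break
    if config.initial_stimulus is not None:
        side, idx, _ = config.initial_stimulus
        if idx >= len(scenario.channels_on(side)):
            findings.append(
                Finding("error", "bad-stimulus",
                        f"initial stimulus channel {idx} does not exist on the "
                        f"{side} side")
            )
    return findings


# -- (de)serialisation -----------------------------------------------------


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "geometry": {"radius": s.geometry.radius},
        "outer": {"D": s.outer.D, "k_s": s.outer.k_s},
        "inner": {"D": s.inner.D, "k_s": s.inner.k_s},
        "envelope": {"delta_m": s.envelope.delta_m, "D_P": s.envelope.D_P},
        "channels": [
            {
                "theta": c.position.theta,
                "phi": c.position.phi,
                "side": c.side,
                "sigma_mol": c.release.sigma_mol,
                "c_th": c.threshold.c_th,
                "alpha": c.threshold.alpha,
                "tau_R": c.tau_R,
                "enabled": c.enabled,
            }
            for c in s.channels
        ],
        "pores": [
            {
                "theta": p.position.theta,
                "phi": p.position.phi,
                "diameter": p.diameter,
                "open": p.open,
            }
            for p in s.pores
        ],
        "probes": [
            {"name": p.name, "theta": p.position.theta, "phi": p.position.phi,
             "side": p.side}
            for p in s.probes
        ],
    }


def scenario_from_dict(d: dict) -> Scenario:
    known = {"geometry", "outer", "inner", "envelope", "channels", "pores", "probes"}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
    return Scenario(
        geometry=SphereGeometry(d["geometry"]["radius"]),
        outer=Surface("outer", d["outer"]["D"], d["outer"]["k_s"]),
        inner=Surface("inner", d["inner"]["D"], d["inner"]["k_s"]),
        envelope=EnvelopeParams(d["envelope"]["delta_m"], d["envelope"]["D_P"]),
        channels=[
            Channel(
                SphericalPoint(c["theta"], c["phi"]),
                c["side"],
                ReleaseAmount(c["sigma_mol"]),
                FiringThreshold(c["c_th"], c["alpha"]),
                tau_R=c.get("tau_R"),
                enabled=c.get("enabled", True),
            )
            for c in d["channels"]
        ],
        pores=[
            Pore(SphericalPoint(p["theta"], p["phi"]), p["diameter"],
                 p.get("open", True))
            for p in d["pores"]
        ],
        probes=[
            Probe(p["name"], SphericalPoint(p["theta"], p["phi"]), p["side"])
            for p in d.get("probes", [])
        ],
    )


def config_to_dict(c: SimulationConfig) -> dict:
    d = dataclasses.asdict(c)
    d["truncation"] = dataclasses.asdict(c.truncation)
    d["shutoff_schedule"] = [list(x) for x in c.shutoff_schedule]
    d["initial_stimulus"] = (
        list(c.initial_stimulus) if c.initial_stimulus is not None else None
    )
    d["snapshot_times"] = list(c.snapshot_times)
    d["snapshot_grid"] = list(c.snapshot_grid)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "truncation" in d:
        d["truncation"] = TruncationSpec(**d["truncation"])
    if d.get("shutoff_schedule"):
        d["shutoff_schedule"] = tuple((float(t), s) for t, s in d["shutoff_schedule"])
    else:
        d["shutoff_schedule"] = ()
    if d.get("initial_stimulus") is not None:
        side, idx, t0 = d["initial_stimulus"]
        d["initial_stimulus"] = (side, int(idx), float(t0))
    d["snapshot_times"] = tuple(d.get("snapshot_times", ()))
    if "snapshot_grid" in d:
        d["snapshot_grid"] = tuple(d["snapshot_grid"])
    return SimulationConfig(**d)


def save_scenario(s: Scenario, path: str | Path, config: SimulationConfig | None = None) -> None:
    doc: dict[str, Any] = {"scenario": scenario_to_dict(s)}
    if config is not None:
        doc["config"] = config_to_dict(config)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path: str | Path) -> tuple[Scenario, Optional[SimulationConfig]]:
    doc = yaml.safe_load(Path(path).read_text())
    unknown = set(doc) - {"scenario", "config"}
    if unknown:
        raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
    scen = scenario_from_dict(doc["scenario"])
    cfg = config_from_dict(doc["config"]) if "config" in doc else None
    return scen, cfg


# -- outputs ---------------------------------------------------------------


def build_manifest(scenario: Scenario, config: SimulationConfig) -> dict:
    """Every resolved parameter of a run; enough to reproduce it exactly."""
    return {
        "nefire_version": __version__,
        "normalisation": "concentrations in uM* (thin-layer, 1 um implicit "
        "depth); amounts in uM*.um^2 = mol * 1e21",
        "scenario": scenario_to_dict(scenario),
        "config": config_to_dict(config),
    }


def write_outputs(
    record: SimulationRecord,
    out_dir: str | Path,
    scenario: Scenario | None = None,
    config: SimulationConfig | None = None,
) -> list[Path]:
    """Write events, traces, pulse totals, snapshots and the manifest.

    Numeric formatting is full double precision so the files round-trip.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"cannot create output directory {out}: {exc}")
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        try:
            df.to_csv(path, index=False)
        except OSError as exc:
            raise ConfigurationError(f"failed writing {path}: {exc}")
        written.append(path)

    _csv(record.events, "events.csv")
    _csv(record.traces, "traces.csv")
    _csv(record.probe_traces, "probe_traces.csv")
    _csv(record.pulse_sums, "pulse_sums.csv")
    if record.pulses is not None:
        path = out / "pulses.csv"
        record.pulses.to_csv(path)
        written.append(path)
    for t_snap, grid in record.snapshots.items():
        _csv(grid, f"snapshot_t{t_snap:g}.csv")
    if scenario is not None and config is not None:
        path = out / "manifest.json"
        path.write_text(json.dumps(build_manifest(scenario, config), indent=1))
        written.append(path)
    return written


def run_from_manifest(path: str | Path) -> SimulationRecord:
    """Re-run a simulation from its manifest alone (reproducibility check)."""
    doc = json.loads(Path(path).read_text())
    scen = scenario_from_dict(doc["scenario"])
    cfg = config_from_dict(doc["config"])
    return run(cfg, scen)
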