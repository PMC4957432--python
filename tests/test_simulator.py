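"""Simulation engine: pore flux, firing, conservation, determinism."""

import math

import numpy as np
import pytest

from nefire import (
    Channel,
    EnvelopeParams,
    FiringThreshold,
    Pore,
    Probe,
    ReleaseAmount,
    Scenario,
    SimulationConfig,
    SphereGeometry,
    SphericalPoint,
    Surface,
    golden_spiral_points,
    greens_kernel,
    initialise,
    pore_flux,
    propagation_condition_numeric,
    refractory_period,
    run,
    shutoff,
    step,
)

GEOM = SphereGeometry(radius=8.0)
RELEASE = ReleaseAmount(sigma_mol=2.0e-20)
THRESHOLD = FiringThreshold(c_th=0.0425, alpha=0.15)
ENV = EnvelopeParams(delta_m=0.01, D_P=20.0)
PORE_D = 0.029


def _equator(phi: float) -> SphericalPoint:
    return SphericalPoint(math.pi / 2.0, phi)


def _scenario(channels, pores, D_outer=20.0, D_inner=5.0, probes=()):
    return Scenario(
        geometry=GEOM,
        outer=Surface("outer", D_outer, 1.0),
        inner=Surface("inner", D_inner, 1.0),
        channels=list(channels),
        pores=list(pores),
        envelope=ENV,
        probes=list(probes),
    )


def _config(**kw):
    defaults = dict(dt=0.01, t_end=1.0, n_global_probes=0,
                    initial_stimulus=("outer", 0, 0.0))
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestPoreFlux:
    def test_hand_checked_value(self):
        # Delta_c = 1 uM*, p_d = 0.029, Dm = 0.01, D_P = 20, dt = 1e-3
        # -> Omega = -(20/0.01) * 1 * pi * 0.0145^2 * 1e-3 = -1.321e-3
        pore = Pore(_equator(0.0), PORE_D)
        omega = pore_flux(pore, c_outer_at_pore=1.0, c_inner_at_pore=0.0,
                          env=ENV, dt=1e-3)
        assert omega == pytest.approx(-1.3210e-3, rel=1e-3)

    def test_sign_follows_gradient(self):
        pore = Pore(_equator(0.0), PORE_D)
        down = pore_flux(pore, 2.0, 1.0, ENV, 1e-3)   # outer richer: outflow
        up = pore_flux(pore, 1.0, 2.0, ENV, 1e-3)     # inner richer: inflow
        assert down < 0 < up
        assert down == pytest.approx(-up)

    def test_no_gradient_no_flux(self):
        pore = Pore(_equator(0.0), PORE_D)
        assert pore_flux(pore, 1.5, 1.5, ENV, 1e-3) == 0.0

    def test_closed_pore_no_flux(self):
        pore = Pore(_equator(0.0), PORE_D, open=False)
        assert pore_flux(pore, 2.0, 0.0, ENV, 1e-3) == 0.0


class TestSingleChannelNoPores:
    def test_probe_trace_is_exactly_one_kernel(self):
        """With no pores and one forced release the field is analytic."""
        dr = 2.0
        ch = Channel(_equator(0.0), "outer", RELEASE, THRESHOLD, tau_R=100.0)
        probe = Probe("P", _equator(dr / GEOM.radius), "outer")
        rec = run(_config(t_end=0.5), _scenario([ch], [], probes=[probe]))
        trace = rec.probe_traces
        s = Surface("outer", 20.0, 1.0)
        for _, row in trace.iloc[1:].iterrows():
            expected = RELEASE.sigma_conc * greens_kernel(dr, row["time"], s)
            assert row["P"] == pytest.approx(expected, rel=1e-10)

    def test_inner_side_stays_silent_without_pores(self):
        ch = Channel(_equator(0.0), "outer", RELEASE, THRESHOLD, tau_R=100.0)
        probe = Probe("N", _equator(0.3), "inner")
        rec = run(_config(t_end=0.3), _scenario([ch], [], probes=[probe]))
        assert np.all(rec.probe_traces["N"].to_numpy() == 0.0)


class TestFiring:
    def test_neighbour_fires_at_first_grid_crossing(self):
        """A second channel fires at the first step where the released field
        (evaluated at the previous step, explicit scheme) reaches c_th."""
        dr = 3.0
        dt = 0.01
        ch0 = Channel(_equator(0.0), "outer", RELEASE, THRESHOLD, tau_R=100.0)
        ch1 = Channel(_equator(dr / GEOM.radius), "outer", RELEASE, THRESHOLD,
                      tau_R=100.0)
        rec = run(_config(dt=dt, t_end=1.0), _scenario([ch0, ch1], []))
        s = Surface("outer", 20.0, 1.0)
        fired = rec.events[rec.events.channel_id == 1]
        assert len(fired) == 1
        t_fire = float(fired.time.iloc[0])
        # oracle: smallest grid time at which the released field crosses c_th
        grid = np.arange(dt, 1.0 + dt / 2, dt)
        field = RELEASE.sigma_conc * greens_kernel(dr, grid, s)
        crossing = grid[np.nonzero(field >= THRESHOLD.c_th)[0][0]]
        assert abs(t_fire - crossing) <= dt + 1e-12

    def test_out_of_reach_channel_never_fires(self):
        _, _, peak = propagation_condition_numeric(
            7.5, Surface("outer", 20.0, 1.0), RELEASE, THRESHOLD
        )
        assert peak < THRESHOLD.c_th  # 7.5 um is beyond reach at D=20
        ch0 = Channel(_equator(0.0), "outer", RELEASE, THRESHOLD, tau_R=100.0)
        ch1 = Channel(_equator(7.5 / GEOM.radius), "outer", RELEASE, THRESHOLD,
                      tau_R=100.0)
        rec = run(_config(dt=0.02, t_end=3.0), _scenario([ch0, ch1], []))
        assert (rec.events.channel_id == 1).sum() == 0

    def test_synchronised_pair_fires_once_each(self):
        """Two channels firing near-simultaneously re-arm into a decayed
        field, so neither refires: saltatory waves need asynchrony."""
        ch = [
            Channel(_equator(0.0), "outer", RELEASE, THRESHOLD),
            Channel(_equator(1.0 / GEOM.radius), "outer", RELEASE, THRESHOLD),
        ]
        rec = run(_config(dt=0.05, t_end=8.0), _scenario(ch, []))
        assert (rec.events.channel_id == 0).sum() == 1
        assert (rec.events.channel_id == 1).sum() == 1

    def test_compartment_refractory_blocks_refiring(self):
        """A rapidly self-retriggering driver keeps the field above
        threshold; the neighbour still cannot refire faster than its own
        compartment refractory period."""
        driver = Channel(_equator(0.0), "outer", RELEASE, THRESHOLD, tau_R=0.3)
        follower = Channel(_equator(1.0 / GEOM.radius), "outer", RELEASE,
                           THRESHOLD)
        dt = 0.05
        rec = run(_config(dt=dt, t_end=8.0), _scenario([driver, follower], []))
        tau = refractory_period(Surface("outer", 20.0, 1.0), RELEASE, THRESHOLD)
        times = np.sort(rec.events[rec.events.channel_id == 1].time.to_numpy())
        assert len(times) >= 3  # the driver keeps re-triggering it
        assert np.diff(times).min() >= tau - dt


class TestPoreCoupling:
    def _two_sided(self, n_pores=64):
        ch = Channel(_equator(0.0), "outer", RELEASE, THRESHOLD, tau_R=100.0)
        pores = [Pore(p, PORE_D) for p in golden_spiral_points(n_pores, GEOM)]
        probes = [Probe("N", _equator(0.25), "inner"),
                  Probe("O", _equator(0.25), "outer")]
        return _scenario([ch], pores, probes=probes)

    def test_pulse_pairs_conserve_calcium(self):
        rec = run(_config(dt=0.01, t_end=0.5), self._two_sided())
        sums = rec.pulse_sums
        assert len(sums) > 0
        np.testing.assert_allclose(
            sums["outer_total"].to_numpy() + sums["inner_total"].to_numpy(),
            0.0, atol=1e-18,
        )

    def test_calcium_actually_crosses(self):
        rec = run(_config(dt=0.01, t_end=0.5), self._two_sided())
        assert rec.probe_traces["N"].max() > 0.0
        # outer stays the dominant side this early at this pore count
        assert rec.probe_traces["N"].max() < rec.probe_traces["O"].max()

    def test_per_pore_pulses_recorded_on_request(self):
        rec = run(_config(dt=0.01, t_end=0.2, record_pulses=True),
                  self._two_sided(16))
        assert rec.pulses is not None
        assert rec.pulses.shape[1] == 16
        # every recorded per-pore row sums to the recorded outer total
        row_sums = rec.pulses.sum(axis=1).to_numpy()
        outer_tot = rec.pulse_sums.set_index("time").loc[
            rec.pulses.index, "outer_total"
        ].to_numpy()
        np.testing.assert_allclose(row_sums, outer_tot, atol=1e-18)


class TestDeterminismAndControl:
    def test_same_seed_bitwise_identical(self):
        cfg = _config(dt=0.02, t_end=0.6)
        scen = TestPoreCoupling()._two_sided(32)
        a, b = run(cfg, scen), run(cfg, scen)
        assert a.events.equals(b.events)
        assert a.probe_traces.equals(b.probe_traces)
        assert a.pulse_sums.equals(b.pulse_sums)

    def test_shutoff_silences_a_side(self):
        ch = [
            Channel(_equator(0.0), "outer", RELEASE, THRESHOLD),
            Channel(_equator(1.0 / GEOM.radius), "outer", RELEASE, THRESHOLD),
        ]
        cfg = _config(dt=0.05, t_end=10.0, shutoff_schedule=((4.0, "outer"),))
        rec = run(cfg, _scenario(ch, []))
        times = rec.events.time.to_numpy()
        assert (times <= 4.0 + 1e-9).all()
        assert len(times) >= 2  # it was firing before the shut-off

    def test_shutoff_function_disables_manually(self):
        # a self-retriggering channel fires its forced stimulus, then stops
        # producing events once the side is shut off
        ch = Channel(_equator(0.0), "outer", RELEASE, THRESHOLD, tau_R=0.1)
        state = initialise(_scenario([ch], []), _config(dt=0.05, t_end=5.0))
        shutoff(state, "outer")
        for _ in range(40):
            step(state)
        assert [e[0] for e in state.event_log] == [0.0]  # stimulus only

    def test_early_stop_after_probe_peak(self):
        ch = Channel(_equator(0.0), "outer", RELEASE, THRESHOLD, tau_R=100.0)
        probe = Probe("P", _equator(2.0 / GEOM.radius), "outer")
        cfg = _config(dt=0.01, t_end=50.0, stop_probe="P",
                      stop_drop_fraction=0.5, stop_min_time=0.2)
        rec = run(cfg, _scenario([ch], [], probes=[probe]))
        assert rec.stopped_at < 5.0  # long before t_end
        trace = rec.probe_traces["P"].to_numpy()
        assert trace.max() > 0
        assert trace[-1] <= 0.5 * trace.max() + 1e-12
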