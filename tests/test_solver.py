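"""Physics validation of the 1D pulse-wave solver against closed-form
oracles: Moens-Korteweg transit speed, resistive steady states, junction
mass conservation, periodicity and reflection behaviour."""

import math

import numpy as np
import pytest

from renaltwin.network import ArterialNetwork, VesselSegment, WindkesselTerminal
from renaltwin.solver import (
    MMHG,
    NumericsConfig,
    SolverError,
    aortic_inflow,
    characteristic_impedance,
    simulate_subject,
    vessel_beta,
    wave_speed_series,
)
from conftest import make_single_vessel

RHO = 1060.0


def two_segment_line(radius=0.005, wall=0.0008, youngs=4.0e5, seg_len=0.4,
                     r2=1.5e8, c=5e-9):
    """Two identical segments in series, impedance-matched terminal."""
    beta = vessel_beta(youngs, wall)
    a0 = math.pi * radius**2
    zc = characteristic_impedance(beta, a0)
    va = VesselSegment(id="a", length=seg_len, lumen_radius_ref=radius,
                       wall_thickness=wall, youngs_modulus=youngs)
    vb = VesselSegment(id="b", parent="a", length=seg_len, lumen_radius_ref=radius,
                       wall_thickness=wall, youngs_modulus=youngs)
    term = WindkesselTerminal(id="b", proximal_resistance=zc,
                              distal_resistance=r2, compliance=c)
    return ArterialNetwork(vessels={"a": va, "b": vb}, terminals={"b": term},
                           inlet_vessel="a"), zc


def gaussian_pulse(base=2e-6, amp=2e-5, t0=0.10, sigma=0.012, period=0.8):
    def q(t):
        tau = np.mod(t, period)
        return base + amp * np.exp(-0.5 * ((tau - t0) / sigma) ** 2)
    return q


def _foot_time(time, series, frac=0.2):
    """First crossing of ``frac`` of the pulse height on the rising edge."""
    y = series - series[:10].mean()
    thr = frac * y.max()
    idx = int(np.argmax(y > thr))
    t1, t0_ = time[idx], time[idx - 1]
    y1, y0 = y[idx], y[idx - 1]
    return t0_ + (thr - y0) / (y1 - y0) * (t1 - t0_)


class TestWaveSpeed:
    def test_transit_time_matches_moens_korteweg(self):
        """Foot-to-foot transit of a narrow pulse between the two segment
        midpoints matches c0 = sqrt(E h / (2 rho r0)) within 2%."""
        net, zc = two_segment_line()
        v = net.vessels["a"]
        c0 = math.sqrt(v.youngs_modulus * v.wall_thickness / (2 * RHO * v.lumen_radius_ref))
        inflow = gaussian_pulse()
        q_mean = 2e-6 + 2e-5 * 0.012 * math.sqrt(2 * math.pi) / 0.8
        term = net.terminals["b"]
        # anchor the tube law at the run's operating pressure so the pulse
        # rides at the reference area
        p_op = 5 * MMHG + q_mean * (zc + term.distal_resistance)
        cfg = NumericsConfig(target_dx=0.005, periodicity_tol=5e-3, max_cycles=8,
                             samples_per_cycle=400, ref_pressure=p_op)
        waves = simulate_subject(net, inflow=inflow, numerics=cfg)
        ta = _foot_time(waves["a"].time, waves["a"].pressure)
        tb = _foot_time(waves["b"].time, waves["b"].pressure)
        c_meas = 0.4 / (tb - ta)  # midpoints are one segment length apart
        assert c_meas == pytest.approx(c0, rel=0.02)

    def test_instantaneous_series_from_tube_law(self):
        beta, a0 = vessel_beta(4e5, 8e-4), math.pi * 0.005**2
        c0 = math.sqrt(beta / (2 * RHO * math.sqrt(a0)))
        series = wave_speed_series(np.full(10, a0), beta, a0, RHO)
        assert series == pytest.approx(c0, rel=1e-12)
        doubled = wave_speed_series(np.full(10, a0), 2 * beta, a0, RHO)
        assert doubled[0] == pytest.approx(math.sqrt(2) * c0, rel=1e-12)
        with pytest.raises(ValueError):
            wave_speed_series(np.array([a0, -a0]), beta, a0)

    def test_simulated_wave_speed_consistent_with_transit(self):
        """The tube-law wave-speed series of the converged run brackets the
        transit-time estimate."""
        net, zc = two_segment_line()
        v = net.vessels["a"]
        c0 = math.sqrt(v.youngs_modulus * v.wall_thickness / (2 * RHO * v.lumen_radius_ref))
        q_mean = 2e-6 + 2e-5 * 0.012 * math.sqrt(2 * math.pi) / 0.8
        p_op = 5 * MMHG + q_mean * (zc + net.terminals["b"].distal_resistance)
        cfg = NumericsConfig(target_dx=0.005, periodicity_tol=5e-3, max_cycles=8,
                             ref_pressure=p_op)
        waves = simulate_subject(net, inflow=gaussian_pulse(), numerics=cfg)
        c_series = waves["a"].wave_speed
        assert c_series.min() < c0 * 1.02
        assert c_series.max() > c0 * 0.98


class TestSteadyState:
    def test_pressure_drop_equals_resistance_times_flow(self, single_vessel):
        """Constant inflow: midpoint pressure equals venous pressure plus
        flow times (terminal + half-vessel viscous) resistance, within
        0.5%."""
        q0 = 5e-6
        cfg = NumericsConfig(periodicity_tol=1e-6, max_cycles=40)
        waves = simulate_subject(
            single_vessel,
            inflow=lambda t: np.full_like(np.asarray(t, dtype=float), q0),
            numerics=cfg,
        )
        w = waves["tube"]
        term = single_vessel.terminals["tube"]
        mu = 4.0e-3
        v = single_vessel.vessels["tube"]
        r_half = 22.0 * math.pi * mu * (v.length / 2) / float(w.area.mean()) ** 2
        expected = cfg.venous_pressure + q0 * (term.total_resistance + r_half)
        drop = float(w.pressure.mean()) - cfg.venous_pressure
        assert drop == pytest.approx(expected - cfg.venous_pressure, rel=0.005)
        assert float(w.flow.mean()) == pytest.approx(q0, rel=0.005)


class TestJunctions:
    def test_cycle_mean_mass_conservation_at_bifurcation(self):
        """At the periodic state the cycle-mean flow into a bifurcation
        equals the sum of the daughter flows."""
        parent = VesselSegment(id="p", length=0.3, lumen_radius_ref=0.006,
                               wall_thickness=0.0009, youngs_modulus=4e5)
        kids = {}
        terms = {}
        for name, r in (("c1", 0.0042), ("c2", 0.0035)):
            kids[name] = VesselSegment(id=name, parent="p", length=0.25,
                                       lumen_radius_ref=r, wall_thickness=0.15 * r,
                                       youngs_modulus=6e5)
            beta = vessel_beta(6e5, 0.15 * r)
            zc = characteristic_impedance(beta, math.pi * r**2)
            terms[name] = WindkesselTerminal(id=name, proximal_resistance=zc,
                                             distal_resistance=3e8, compliance=3e-9)
        net = ArterialNetwork(vessels={"p": parent, **kids}, terminals=terms,
                              inlet_vessel="p")
        cfg = NumericsConfig(periodicity_tol=1e-5, max_cycles=40)
        waves = simulate_subject(
            net, numerics=cfg, cardiac_output=4e-5,
            record=["p:distal", "c1:proximal", "c2:proximal"],
        )
        qp = float(waves["p:distal"].flow.mean())
        qk = float(waves["c1:proximal"].flow.mean()
                   + waves["c2:proximal"].flow.mean())
        assert abs(qp - qk) / qp < 1e-6

    def test_mean_pressure_decreases_towards_periphery(self):
        """Time-averaged pressure falls monotonically from the inlet to the
        terminals along every path (energy sanity)."""
        from renaltwin.reference import build_full_reference

        net = build_full_reference()
        cfg = NumericsConfig(target_dx=0.013, cfl=0.9, min_cells=2, max_cycles=16)
        path = ["ascending_aorta", "thoracic_aorta_a", "abdominal_aorta_c",
                "l_renal", "L_renal_main", "L_renal_seg1", "L_renal_int11",
                "L_renal_arc111"]
        waves = simulate_subject(net, numerics=cfg, record=path)
        means = [float(waves[p].pressure.mean()) for p in path]
        assert all(a > b for a, b in zip(means, means[1:]))


class TestPeriodicityAndDeterminism:
    def test_warm_restart_reproduces_cycle(self, single_vessel):
        """A converged state re-simulated for further cycles reproduces the
        same waveform within the periodicity tolerance."""
        cfg = NumericsConfig(periodicity_tol=1e-4, max_cycles=30)
        w1, st = simulate_subject(single_vessel, numerics=cfg, cardiac_output=6e-5,
                                  return_state=True)
        w2 = simulate_subject(single_vessel, numerics=cfg, cardiac_output=6e-5,
                              init_state=st)
        p1, p2 = w1["tube"].pressure, w2["tube"].pressure
        pulse = p1.max() - p1.min()
        assert np.max(np.abs(p1 - p2)) / pulse < 5e-4

    def test_identical_runs_are_bitwise_equal(self, single_vessel):
        w1 = simulate_subject(single_vessel, cardiac_output=6e-5)
        w2 = simulate_subject(single_vessel, cardiac_output=6e-5)
        assert np.array_equal(w1["tube"].pressure, w2["tube"].pressure)
        assert np.array_equal(w1["tube"].flow, w2["tube"].flow)

    def test_unknown_record_location(self, single_vessel):
        with pytest.raises(SolverError, match="nowhere"):
            simulate_subject(single_vessel, record=["nowhere"])


class TestNumerics:
    def test_grid_convergence_on_single_vessel(self):
        """Halving the cell size changes systolic midpoint pressure by
        less than 1%."""
        sys_p = {}
        for dx in (0.02, 0.01):
            net = make_single_vessel()
            cfg = NumericsConfig(target_dx=dx, periodicity_tol=1e-4, max_cycles=30)
            w = simulate_subject(net, numerics=cfg, cardiac_output=6e-5)
            sys_p[dx] = float(w["tube"].pressure.max())
        assert abs(sys_p[0.01] - sys_p[0.02]) / sys_p[0.01] < 0.01

    def test_matched_terminal_is_nearly_reflection_free(self):
        """With the proximal terminal resistance at the characteristic
        impedance (and the distal windkessel effectively removed), the
        backward component of a narrow pulse stays below 5% of the forward
        component (linear wave splitting at the midpoint)."""
        radius, wall, youngs = 0.005, 0.0008, 4.0e5
        beta = vessel_beta(youngs, wall)
        a0 = math.pi * radius**2
        zc = characteristic_impedance(beta, a0)
        net = make_single_vessel(radius=radius, wall=wall, youngs=youngs,
                                 proximal_resistance=zc,
                                 distal_resistance=zc * 1e-6, compliance=1e-13)
        q_mean = 1e-6 + 2e-5 * 0.012 * math.sqrt(2 * math.pi) / 0.8
        cfg = NumericsConfig(target_dx=0.005, periodicity_tol=5e-3, max_cycles=8,
                             samples_per_cycle=400,
                             ref_pressure=5 * MMHG + q_mean * zc)
        waves = simulate_subject(net, inflow=gaussian_pulse(base=1e-6), numerics=cfg)
        w = waves["tube"]
        dp = w.pressure - w.pressure.mean()
        dq = w.flow - w.flow.mean()
        forward = 0.5 * (dp + zc * dq)
        backward = 0.5 * (dp - zc * dq)
        assert np.ptp(backward) / np.ptp(forward) < 0.05

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NumericsConfig(cfl=1.5)
        with pytest.raises(ValueError):
            NumericsConfig(max_cycles=1)


class TestWaveformStore:
    def test_hdf5_round_trip(self, single_vessel, tmp_path):
        waves = simulate_subject(single_vessel, cardiac_output=6e-5)
        from renaltwin.solver import load_waveforms, save_waveforms

        path = tmp_path / "waves.h5"
        save_waveforms(path, waves, subject_id="s1", attrs={"seed": 3})
        again = load_waveforms(path, "s1")
        assert set(again) == set(waves)
        w0, w1 = waves["tube"], again["tube"]
        assert np.array_equal(w0.pressure, w1.pressure)
        assert np.array_equal(w0.flow, w1.flow)
        assert w1.period == pytest.approx(w0.period)
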