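import numpy as np
import pytest

from minslab import Geometry, Totals, homogeneous_steady_state
from minslab.model import FieldState
from minslab.simulate import (Trajectory, SimulationError, extract_kymograph,
                              measure_growth_rate, simulate)

from conftest import totals_at


def _make_traj(params, totals, series, times, L_x=60.0, dx=0.5):
    """Wrap a constructed membrane series into a Trajectory shell."""
    geom = Geometry(H=4.0, dz=0.5, L_x=L_x, dx=dx)
    return Trajectory(times=np.asarray(times, float), states=[], params=params,
                      geom=geom, totals=totals), geom


class TestFixedPoint:
    def test_steady_state_persists(self, params, totals):
        """A vertically stable steady state survives 500 s of integration."""
        tot = totals_at(totals, 0.625)
        geom = Geometry(H=2.0, dz=2.0 / 48)
        traj = simulate(params, geom, tot, "steady_state", t_end=500.0,
                        output_dt=250.0, dt=0.02)
        st0, st1 = traj.states[0], traj.states[-1]
        for name in ("c_DD", "c_DT", "c_E"):
            a0, a1 = getattr(st0, name), getattr(st1, name)
            assert np.abs(a1 - a0).max() / np.abs(a0).max() < 1e-4, name
        m0 = st0.membranes["bottom"]
        m1 = st1.membranes["bottom"]
        for k in ("m_d", "m_de"):
            assert abs(m1[k][0] - m0[k][0]) / m0[k][0] < 1e-4


class TestConservation:
    def test_mass_conserved_through_patterned_dynamics(self, params, totals):
        """N_D and N_E drift below 1e-6 relative even while a pattern grows
        to large amplitude."""
        tot = totals_at(totals, 0.8)
        geom = Geometry(H=2.0, dz=2.0 / 16, L_x=60.0, dx=0.5)
        traj = simulate(params, geom, tot, "steady_state_plus_noise", seed=5,
                        t_end=120.0, output_dt=20.0, dt=0.02,
                        noise_amplitude=1e-2)
        dd, de = traj.mass_drift()
        assert dd < 1e-6 and de < 1e-6
        # the pattern really developed (this is not a quiescent run)
        ser = traj.membrane_series("bottom")
        assert ser[-1].std() / ser[-1].mean() > 0.05


class TestGrowthRateFit:
    def test_constructed_exponential_growth(self, params, totals):
        t = np.arange(0, 80.0, 0.5)
        geom_L, n = 60.0, 4
        q = n * np.pi / geom_L
        x = (np.arange(120) + 0.5) * 0.5
        series = 100 + np.exp(0.1 * t)[:, None] * np.cos(q * x)[None, :]
        traj, geom = _make_traj(params, totals, series, t, L_x=geom_L, dx=0.5)
        sig = measure_growth_rate(traj, q, series=series)
        assert sig.real == pytest.approx(0.1, rel=1e-3)

    def test_constructed_decay(self, params, totals):
        t = np.arange(0, 80.0, 0.5)
        geom_L, n = 60.0, 4
        q = n * np.pi / geom_L
        x = (np.arange(120) + 0.5) * 0.5
        series = 100 + 5 * np.exp(-0.07 * t)[:, None] * np.cos(q * x)[None, :]
        traj, geom = _make_traj(params, totals, series, t, L_x=geom_L, dx=0.5)
        sig = measure_growth_rate(traj, q, series=series)
        assert sig.real == pytest.approx(-0.07, rel=1e-3)

    def test_oscillatory_growth_frequency(self, params, totals):
        t = np.arange(0, 120.0, 0.5)
        geom_L, n = 60.0, 4
        q = n * np.pi / geom_L
        x = (np.arange(120) + 0.5) * 0.5
        series = 50 + (np.exp(0.05 * t) * np.cos(0.5 * t))[:, None] * np.cos(q * x)[None, :]
        traj, geom = _make_traj(params, totals, series, t, L_x=geom_L, dx=0.5)
        sig = measure_growth_rate(traj, q, series=series)
        assert sig.real == pytest.approx(0.05, rel=0.02)
        assert sig.imag == pytest.approx(0.5, rel=0.02)


class TestKymograph:
    def _uniform_traj(self, params, totals, value=7.0, nt=11):
        geom = Geometry(H=4.0, dz=0.5, L_x=20.0, dx=0.5)
        states = []
        for i in range(nt):
            st = FieldState(
                c_DD=np.zeros((geom.nx, geom.nz)),
                c_DT=np.zeros((geom.nx, geom.nz)),
                c_E=np.zeros((geom.nx, geom.nz)),
                membranes={f: {"m_d": np.full(geom.nx, value), "m_de": np.zeros(geom.nx)}
                           for f in ("bottom", "top")},
                time=float(i))
            states.append(st)
        return Trajectory(times=np.arange(nt, dtype=float), states=states,
                          params=params, geom=geom, totals=totals), geom

    def test_constant_trajectory_gives_constant_kymograph(self, params, totals):
        traj, geom = self._uniform_traj(params, totals)
        kymo = extract_kymograph(traj, ("membrane", "bottom"))
        assert np.all(kymo.data == 7.0)
        assert kymo.data.shape == (geom.nx, 11)

    def test_traveling_wave_slope(self, params, totals):
        """A constructed traveling wave yields stripes whose space-time slope
        is the propagation speed in calibrated units."""
        geom = Geometry(H=4.0, dz=0.5, L_x=50.0, dx=0.5)
        v, lam = 2.0, 25.0
        k = 2 * np.pi / lam
        times = np.arange(0, 12.0, 0.25)
        x = geom.x_centers
        states = []
        for t in times:
            md = 10 + np.cos(k * (x - v * t))
            st = FieldState(
                c_DD=np.zeros((geom.nx, geom.nz)), c_DT=np.zeros((geom.nx, geom.nz)),
                c_E=np.zeros((geom.nx, geom.nz)),
                membranes={f: {"m_d": md.copy(), "m_de": np.zeros(geom.nx)}
                           for f in ("bottom", "top")}, time=float(t))
            states.append(st)
        traj = Trajectory(times=times, states=states, params=params, geom=geom,
                          totals=totals)
        kymo = extract_kymograph(traj, ("membrane", "bottom"))
        # phase of the k-mode advances at speed v
        ph = np.unwrap(np.angle(np.exp(-1j * k * x) @ kymo.data))
        slope = np.polyfit(kymo.times, ph, 1)[0]
        assert slope / k == pytest.approx(-v, rel=1e-2) or \
            slope / k == pytest.approx(v, rel=1e-2)

    def test_empty_time_window_raises(self, params, totals):
        traj, _ = self._uniform_traj(params, totals)
        with pytest.raises(SimulationError, match="empty"):
            extract_kymograph(traj, ("membrane", "bottom"), t_window=(100.0, 200.0))

    def test_line_outside_domain_raises(self, params, totals):
        traj, _ = self._uniform_traj(params, totals)
        with pytest.raises(SimulationError):
            extract_kymograph(traj, ("z", 99.0), quantity="c_E")


class TestGridConvergence:
    def test_pattern_scales_stable_under_refinement(self, params, totals):
        """Halving dx and dz changes the developed pattern's dominant
        wavelength and period by < 5%."""
        from minslab.patterns import temporal_period_kymo

        tot = totals_at(totals, 0.8)
        scales = {}
        for nzf, dxf in ((16, 0.5), (32, 0.25)):
            geom = Geometry(H=2.0, dz=2.0 / nzf, L_x=60.0, dx=dxf)
            traj = simulate(params, geom, tot, "steady_state_plus_noise",
                            seed=9, t_end=260.0, output_dt=1.0, dt=0.02,
                            noise_amplitude=1e-2)
            kymo = extract_kymograph(traj, ("membrane", "bottom"),
                                     t_window=(140.0, 260.0))
            prof = kymo.data.mean(axis=1)
            spec = np.abs(np.fft.rfft(kymo.data - kymo.data.mean(), axis=0)).mean(axis=1)
            spec[0] = 0
            k_bin = np.argmax(spec)
            lam = 60.0 / k_bin
            per = temporal_period_kymo(kymo.data, kymo.dt)
            scales[nzf] = (lam, per)
        (l1, p1), (l2, p2) = scales[16], scales[32]
        assert abs(l1 - l2) / l2 < 0.05
        assert abs(p1 - p2) / p2 < 0.05


class TestSweepBasics:
    def test_flat_sweep_single_class(self, params, totals):
        from minslab.simulate import adiabatic_sweep

        tot = totals_at(totals, 0.8)
        rec = adiabatic_sweep(params, tot, 2.0, 2.0, n_steps=3,
                              segment_time=120.0, L_x=60.0, dx=0.5,
                              dz_target=0.125, seed=1, dt=0.02,
                              equilibrate=120.0)
        assert len(set(rec.labels)) == 1
        assert rec.transitions == []
        assert np.all(np.diff(rec.H_values) == 0)

    def test_monotone_height_schedule(self, params, totals):
        from minslab.simulate import adiabatic_sweep

        tot = totals_at(totals, 0.8)
        rec = adiabatic_sweep(params, tot, 2.0, 3.0, n_steps=3,
                              segment_time=60.0, L_x=30.0, dx=0.5,
                              dz_target=0.125, seed=1, dt=0.02)
        assert np.all(np.diff(rec.H_values) > 0)
        assert rec.direction == "up"
        assert len(rec.labels) == 3
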