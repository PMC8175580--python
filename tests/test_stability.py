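import cmath
from dataclasses import replace

import numpy as np
import pytest

from minslab import (Geometry, Totals, classify_modes, critical_height,
                     dispersion_branch, homogeneous_steady_state)
from minslab.stability import (BulkPropagator, DispersionResult, ModeFlags,
                               boundary_determinant, find_roots, mm_growth_rate,
                               point_mode_flags)

from conftest import totals_at
from oracles import leading_vertical_eigs, single_species_flux_response_fd


class TestBulkPropagator:
    @pytest.mark.parametrize("parity,form", [
        ("symmetric", lambda D, a, H: D * a * cmath.tanh(a * H / 2)),
        ("antisymmetric", lambda D, a, H: D * a / cmath.tanh(a * H / 2)),
    ])
    def test_single_species_closed_form(self, params, parity, form):
        """With no bulk reaction the response is the textbook tanh/coth
        transfer coefficient."""
        H, q, sigma = 7.0, 0.4, 0.23
        prop = BulkPropagator(sigma=sigma, q=q, params=params, H=H, parity=parity)
        a = cmath.sqrt(q**2 + sigma / params.D_b)
        assert prop.response(0.0) == pytest.approx(form(params.D_b, a, H), rel=1e-12)

    def test_flat_profile_zero_flux(self, params):
        """σ = 0, q = 0, no bulk reaction: a flat vertical profile exchanges
        no flux (symmetric parity)."""
        prop = BulkPropagator(sigma=0.0, q=0.0, params=params, H=5.0,
                              parity="symmetric")
        assert abs(prop.response(0.0)) < 1e-12

    @pytest.mark.parametrize("sigma", [0.3, 0.05 + 0.4j, -0.1 + 0.9j])
    @pytest.mark.parametrize("parity", ["symmetric", "antisymmetric"])
    def test_matches_discretized_bvp(self, params, sigma, parity):
        """General (σ, q): response agrees with a dense finite-difference
        solve of the vertical two-point boundary problem."""
        H, q = 9.0, 0.31
        for r in (0.0, params.lambda_exch):
            prop = BulkPropagator(sigma=sigma, q=q, params=params, H=H, parity=parity)
            ref = single_species_flux_response_fd(params.D_b, r, sigma, q, H, parity)
            assert prop.response(r) == pytest.approx(ref, rel=1e-6)


class TestBoundaryDeterminant:
    def test_conservation_forces_neutral_double_root(self, params, totals):
        """At q = 0, symmetric parity, σ = 0 is a double root of the
        determinant for any valid parameter draw (two conserved totals)."""
        rng = np.random.default_rng(7)
        n_checked = 0
        for _ in range(20):
            p = replace(
                params,
                k_D=params.k_D * rng.uniform(0.3, 3),
                k_dD=params.k_dD * rng.uniform(0.3, 3),
                k_dE=params.k_dE * rng.uniform(0.3, 3),
                k_de=params.k_de * rng.uniform(0.3, 3),
                lambda_exch=params.lambda_exch * rng.uniform(0.3, 3),
            )
            tot = Totals.from_ed_ratio(totals.n_D * rng.uniform(0.5, 2),
                                       rng.uniform(0.4, 0.85))
            H = rng.uniform(2, 30)
            geom = Geometry(H=H, dz=H / 16)
            try:
                ss = homogeneous_steady_state(p, geom, tot)
            except Exception:
                continue
            d0 = boundary_determinant(0.0, 0.0, ss, "symmetric")
            assert abs(d0) < 1e-10
            # double root: det ~ c σ² near 0, so det(ε)/ε → 0 while
            # det(ε)/ε² approaches a (generically) nonzero constant
            eps = 1e-5
            vals = [boundary_determinant(eps * cmath.exp(1j * ph), 0.0, ss,
                                         "symmetric") for ph in (0.3, 1.7, 3.9)]
            assert max(abs(v) / eps for v in vals) < 1e-3
            n_checked += 1
        assert n_checked >= 15

    def test_pure_membrane_diffusion_limit(self, params, totals):
        """All kinetic rates zero: membrane branches satisfy σ = −D_m q²."""
        p = replace(params, k_D=0.0, k_dD=0.0, k_dE=0.0, k_de=0.0,
                    lambda_exch=0.0)
        geom = Geometry(H=5.0, dz=5.0 / 16)
        ss = homogeneous_steady_state(p, geom, totals)
        q = 0.8
        sig = -p.D_m * q**2
        for parity in ("symmetric", "antisymmetric"):
            d = boundary_determinant(sig + 0j, q, ss, parity)
            assert abs(d) < 1e-10


class TestDispersionAndOracle:
    def test_roots_match_dense_eigensolver(self, params, totals):
        """Leading determinant roots at q = 0 agree with the brute-force
        eigendecomposition of the discretized vertical problem, per parity."""
        geom = Geometry(H=14.0, dz=14.0 / 32)
        ss = homogeneous_steady_state(params, geom, totals)
        eigs = leading_vertical_eigs(params, 14.0, ss, 0.0, N=400)
        anti_ref = next(s for s, par in eigs if par == "antisymmetric" and s.imag >= 0)
        roots = find_roots(0.0, ss, "antisymmetric", n_roots=2)
        assert roots[0] == pytest.approx(anti_ref, rel=5e-3)

    def test_branch_continuation_tracks_unstable_lateral_mode(self, params, totals):
        """The σ(q) branch through the fastest-growing lateral mode matches
        the dense eigensolver at a nonzero q."""
        tot = totals_at(totals, 0.8)
        geom = Geometry(H=2.0, dz=2.0 / 16)
        ss = homogeneous_steady_state(params, geom, tot)
        qg = np.concatenate([[0.0], np.linspace(0.02, 0.3, 12)])
        disp = dispersion_branch(params, geom, tot, "symmetric", qg, steady=ss)
        lead = disp.leading()
        i = int(np.nanargmax(lead))
        q_star = disp.q_grid[i]
        eigs = leading_vertical_eigs(params, 2.0, ss, q_star, N=400)
        ref = max((s for s, _ in eigs), key=lambda s: s.real)
        assert lead[i] == pytest.approx(ref.real, rel=2e-2, abs=1e-4)

    def test_membranes_decouple_at_large_height(self, params, totals):
        """As H grows beyond the penetration depth the symmetric and
        antisymmetric q = 0 spectra converge (membranes decouple)."""
        tot = totals_at(totals, 0.55)
        gaps = []
        for H in (20.0, 40.0, 80.0, 160.0):
            geom = Geometry(H=H, dz=H / 24)
            ss = homogeneous_steady_state(params, geom, tot)
            ra = find_roots(0.0, ss, "antisymmetric", n_roots=1)
            rs = find_roots(0.0, ss, "symmetric", n_roots=1, exclude_neutral=True)
            assert ra and rs
            gaps.append(abs(ra[0] - rs[0]))
        assert gaps[0] > gaps[1] > gaps[2] > gaps[3]
        assert gaps[3] < 1e-6


class TestClassification:
    def _mk(self, params, geom, totals, parity, sig_rows, q_grid):
        sig = np.array(sig_rows, dtype=complex)
        return DispersionResult(q_grid=np.asarray(q_grid, float), sigma=sig,
                                parity=parity, params=params, geom=geom,
                                totals=totals)

    def test_all_stable_gives_no_flags(self, params, totals, slab_geom):
        q = [0.0, 0.5]
        ds = self._mk(params, slab_geom, totals, "symmetric",
                      [[-0.1 + 0j], [-0.2 + 0j]], q)
        da = self._mk(params, slab_geom, totals, "antisymmetric",
                      [[-0.3 + 0j], [-0.4 + 0j]], q)
        f = classify_modes(ds, da)
        assert not (f.lateral_unstable or f.mm_unstable or f.mb_unstable)

    def test_constructed_mm_only(self, params, totals, slab_geom):
        q = [0.0, 0.5]
        ds = self._mk(params, slab_geom, totals, "symmetric",
                      [[0.0 + 0j], [-0.2 + 0j]], q)  # only the neutral root
        da = self._mk(params, slab_geom, totals, "antisymmetric",
                      [[0.05 + 0.3j], [-0.1 + 0j]], q)
        f = classify_modes(ds, da)
        assert f.regimes() == {"mm"}
        assert f.mm_oscillatory

    def test_reference_point_has_lateral_and_mm(self, params, totals):
        """At intermediate height and E:D = 0.75 both the lateral and the
        membrane-to-membrane mode are unstable."""
        f = point_mode_flags(params, totals, 14.0)
        assert f.lateral_unstable and f.mm_unstable


class TestCriticalHeight:
    def test_no_attachment_is_never_unstable(self, params, totals):
        p0 = replace(params, k_D=0.0, k_dD=0.0)
        res = critical_height(p0, totals, H_range=(1.0, 10.0), n_scan=6)
        assert res.H_c is None

    def test_bisection_matches_dense_scan(self, params, totals):
        res = critical_height(params, totals, H_range=(1.0, 12.0), tol=0.05)
        assert res.H_c is not None
        Hs = np.linspace(1.0, 12.0, 200)
        g = np.array([mm_growth_rate(params, totals, H) for H in Hs])
        crossings = np.nonzero((g[:-1] <= 0) & (g[1:] > 0))[0]
        assert len(crossings) >= 1
        H_scan = Hs[crossings[0] + 1]
        assert abs(res.H_c - H_scan) <= (Hs[1] - Hs[0]) + 0.05
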