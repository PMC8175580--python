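"""Linear stability analysis of the homogeneous steady state in the
two-membrane slab.

Perturbations δ·exp(σt + iqx) of the steady state separate, by the up–down
mirror symmetry of the slab, into a symmetric (in-phase membranes) and an
antisymmetric (antiphase membranes) sector.  In each sector the bulk fields
are resolved analytically: in the eigenbasis of the bulk reaction matrix —
u = c_DD (relaxation rate λ), w = c_DD + c_DT (rate 0), e = c_E (rate 0) —
each component decays vertically as cosh/sinh(α(z − H/2)) with

    α = sqrt(q² + (σ + r)/D_b),   r ∈ {λ, 0, 0}.

Eliminating the bulk leaves a 5×5 boundary problem coupling the boundary
amplitudes (u₀, w₀, e₀) to the membrane perturbations (δm_d, δm_de); growth
rates are roots of its determinant.  Mass-transport modes are read off the
dispersion relations:

* lateral mode — fastest-growing root at q > 0,
* membrane-to-membrane (m-to-m) — antisymmetric root at q = 0,
* membrane-to-bulk (m-to-b) — symmetric root at q = 0 (conserved-mass
  neutral roots at σ = 0 excluded).

The critical height H_c is the lowest H at which the m-to-m mode is unstable.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .model import ConvergenceError, SteadyState, homogeneous_steady_state
from .params import Geometry, KineticParameters, Totals

Parity = Literal["symmetric", "antisymmetric"]

#: roots with |σ| below this at q = 0 are conserved-mass neutral modes.
#: The neutral root is a double root, which Newton polishing only resolves to
#: about sqrt(machine epsilon), so the exclusion window must be well above that.
NEUTRAL_TOL = 1e-6

DEFAULT_SEARCH_REGION = (-5.0, 5.0, 0.0, 5.0)  # Re_min, Re_max, Im_min, Im_max


class StabilityError(RuntimeError):
    pass


class PropagatorPoleError(StabilityError):
    """Evaluation requested at (σ, q) on a pole of the bulk transfer function."""


# ---------------------------------------------------------------------------
# Bulk propagator
# ---------------------------------------------------------------------------

def _response_sym(D: complex, alpha: complex, H: float) -> complex:
    """D·α·tanh(αH/2): flux a membrane must inject into the bulk to sustain a
    symmetric vertical eigenprofile of unit boundary amplitude."""
    x = alpha * H / 2
    if abs(x) < 1e-7:
        return D * alpha * x * (1 - x * x / 3)
    return D * alpha * cmath.tanh(x)


def _response_anti(D: complex, alpha: complex, H: float) -> complex:
    """D·α·coth(αH/2), the antisymmetric counterpart."""
    x = alpha * H / 2
    if abs(x) < 1e-7:
        return D * alpha * (1.0 / x + x / 3)
    s = cmath.tanh(x)
    if abs(s) < 1e-300:
        raise PropagatorPoleError(f"coth pole at alpha*H/2 = {x}")
    return D * alpha / s

@dataclass(frozen=True)
class BulkPropagator:
    """Boundary response of the linearized vertical bulk problem.

    For a bulk eigen-species with relaxation rate r and diffusivity D the
    vertical decay rate is α = sqrt(q² + (σ + r)/D) and the boundary flux
    response is D·α·tanh(αH/2) (symmetric parity) or D·α·coth(αH/2)
    (antisymmetric).  The response maps the boundary perturbation amplitude to
    the flux the membrane injects into the bulk; equivalently the bulk
    *delivers* −response·amplitude to the membrane.
    """

    sigma: complex
    q: float
    params: KineticParameters
    H: float
    parity: Parity

    def alpha(self, r: float, D: float | None = None) -> complex:
        D = self.params.D_b if D is None else D
        return cmath.sqrt(self.q**2 + (self.sigma + r) / D)

    def response(self, r: float, D: float | None = None) -> complex:
        D = self.params.D_b if D is None else D
        a = self.alpha(r, D)
        if self.parity == "symmetric":
            return _response_sym(D, a, self.H)
        return _response_anti(D, a, self.H)

    def species_responses(self) -> tuple[complex, complex, complex]:
        """(R_u, R_w, R_e) for the DD-like eigenmode (r = λ), the conserved
        MinD total (r = 0), and MinE (r = 0)."""
        p = self.params
        R_u = self.response(p.lambda_exch, p.D_bulk_D)
        R_w = self.response(0.0, p.D_bulk_D)
        R_e = self.response(0.0, p.D_bulk_E)
        return R_u, R_w, R_e


# ---------------------------------------------------------------------------
# Boundary determinant
# ---------------------------------------------------------------------------

def boundary_matrix(sigma: complex, q: float, ss: SteadyState, parity: Parity) -> np.ndarray:
    """5×5 complex matrix M(σ, q) acting on (u₀, w₀, e₀, δm_d, δm_de).

    Rows: flux balance of c_DD, c_DT, c_E at the membrane, then the
    linearized kinetics of m_d and m_de.  det M = 0 defines the dispersion
    relation.
    """
    p = ss.params
    prop = BulkPropagator(sigma=sigma, q=q, params=p, H=ss.geom.H, parity=parity)
    R_u, R_w, R_e = prop.species_responses()
    kdD, kdE, kde, Dm = p.k_dD, p.k_dE, p.k_de, p.D_m
    a_D = p.k_D + kdD * ss.m_d
    cDT0, cE, m_d = ss.c_DT_boundary, ss.c_E, ss.m_d

    M = np.zeros((5, 5), dtype=complex)
    # c_DD: bulk delivers -R_u·u0 to the membrane; membrane releases kde·δm_de
    M[0] = [R_u, 0.0, 0.0, 0.0, -kde]
    # c_DT: bulk delivers R_u·u0 - R_w·w0; equals uptake a_D·(w0-u0) + kdD·cDT0·δm_d
    M[1] = [-R_u - a_D, R_w + a_D, 0.0, kdD * cDT0, 0.0]
    # c_E: uptake kdE·(m_d·e0 + cE·δm_d) - kde·δm_de equals -R_e·e0
    M[2] = [0.0, 0.0, R_e + kdE * m_d, kdE * cE, -kde]
    # δm_d kinetics
    M[3] = [a_D, -a_D, kdE * m_d, sigma + Dm * q**2 - kdD * cDT0 + kdE * cE, 0.0]
    # δm_de kinetics
    M[4] = [0.0, 0.0, -kdE * m_d, -kdE * cE, sigma + Dm * q**2 + kde]
    return M


def boundary_determinant(sigma: complex, q: float, ss: SteadyState, parity: Parity) -> complex:
    """Scaled determinant of the boundary matrix (normalized by row norms so
    magnitudes are comparable across (σ, q))."""
    M = boundary_matrix(sigma, q, ss, parity)
    norms = np.sqrt((np.abs(M) ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    return complex(np.linalg.det(M / norms[:, None]))


def _det_batch(sigmas: np.ndarray, q: float, ss: SteadyState, parity: Parity) -> np.ndarray:
    out = np.empty(sigmas.shape, dtype=complex)
    flat = sigmas.ravel()
    res = np.empty(flat.shape, dtype=complex)
    for i, s in enumerate(flat):
        try:
            res[i] = boundary_determinant(s, q, ss, parity)
        except PropagatorPoleError:
            res[i] = np.inf
    out.ravel()[:] = res
    return out


def _polish(sigma0: complex, q: float, ss: SteadyState, parity: Parity,
            tol: float = 1e-12, maxiter: int = 80,
            deflate: tuple[complex, ...] = ()) -> complex | None:
    """Newton iteration on the scaled determinant with a central-difference
    derivative in complex σ.  ``deflate`` lists roots already found at this q;
    dividing them out lets nearby (e.g. split double) roots be recovered."""

    def f_at(s: complex) -> complex:
        v = boundary_determinant(s, q, ss, parity)
        for r in deflate:
            d = s - r
            if abs(d) < 1e-14:
                d = 1e-14
            v /= d
        return v

    s = complex(sigma0)
    if abs(s.imag) < 1e-9:
        # a purely real iteration can never leave the real axis; nudge off it
        # so conjugate-pair roots just off the axis are reachable
        s += 1e-4j
    h = 1e-7
    for _ in range(maxiter):
        try:
            f = f_at(s)
            if abs(f) < tol:
                return s
            df = (f_at(s + h) - f_at(s - h)) / (2 * h)
        except PropagatorPoleError:
            return None
        if df == 0:
            return None
        step = f / df
        if abs(step) > 2.0:
            step *= 2.0 / abs(step)
        s = s - step
        if abs(step) < 1e-14 * max(1.0, abs(s)):
            break
    try:
        return s if abs(f_at(s)) < 1e-10 else None
    except PropagatorPoleError:
        return None


def find_roots(
    q: float,
    ss: SteadyState,
    parity: Parity,
    n_roots: int = 4,
    region: tuple[float, float, float, float] = DEFAULT_SEARCH_REGION,
    n_grid: int = 40,
    exclude_neutral: bool = False,
) -> list[complex]:
    """Roots of the boundary determinant found by a rectangular grid scan of
    the upper half σ-plane (conjugate roots implied) followed by Newton
    polishing.  Returns the leading (largest Re σ) roots, descending."""
    re0, re1, im0, im1 = region
    # at q = 0, symmetric parity, conservation of total MinD and MinE forces an
    # exact double root at σ = 0; deflate it analytically so the remaining
    # roots are found cleanly and no numerically-polished near-zero root leaks
    # into the membrane-to-bulk classification
    deflate: tuple[complex, ...] = ()
    if q == 0 and parity == "symmetric":
        deflate = (0.0 + 0.0j, 0.0 + 0.0j)
    res = np.linspace(re0, re1, n_grid)
    ims = np.linspace(im0, im1, n_grid)
    S = res[None, :] + 1j * ims[:, None]
    G = np.abs(_det_batch(S, q, ss, parity))
    if deflate:
        with np.errstate(divide="ignore", invalid="ignore"):
            G = G / np.abs(S) ** 2
        G[~np.isfinite(G)] = np.inf
    cand: list[complex] = []
    for i in range(n_grid):
        for j in range(n_grid):
            v = G[i, j]
            if not np.isfinite(v):
                continue
            nb = G[max(0, i - 1): i + 2, max(0, j - 1): j + 2]
            if v == np.nanmin(nb):
                cand.append(complex(S[i, j]))
    roots: list[complex] = []
    for s0 in cand:
        r = _polish(s0, q, ss, parity, deflate=deflate)
        if r is None:
            continue
        if r.imag < 0:
            r = r.conjugate()
        if not (re0 - 0.5 <= r.real <= re1 + 0.5 and r.imag <= im1 + 0.5):
            continue
        if all(abs(r - x) > 1e-7 * max(1.0, abs(r)) for x in roots):
            roots.append(r)
    if deflate and not exclude_neutral:
        roots.append(0.0 + 0.0j)  # report the neutral double root once
    roots.sort(key=lambda r: -r.real)
    return roots[:n_roots]


# ---------------------------------------------------------------------------
# Dispersion relations
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    """Leading complex growth rates per lateral wavenumber for one parity.

    ``sigma`` has shape (len(q_grid), n_branches); entries are NaN where a
    branch was lost (no root recovered near the continuation seed)."""

    q_grid: np.ndarray
    sigma: np.ndarray
    parity: Parity
    params: KineticParameters
    geom: Geometry
    totals: Totals

    def leading(self) -> np.ndarray:
        """Leading Re σ per q (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmax(self.sigma.real, axis=1)

    def leading_sigma_at(self, q_index: int) -> complex | None:
        row = self.sigma[q_index]
        ok = row[~np.isnan(row.real)]
        if len(ok) == 0:
            return None
        return complex(ok[np.argmax(ok.real)])

    def max_lateral(self) -> tuple[float, complex] | None:
        """(q_max, σ_max) of the fastest-growing mode at q > 0."""
        mask = self.q_grid > 0
        if not mask.any():
            return None
        lead = self.leading()[mask]
        qs = self.q_grid[mask]
        if np.all(np.isnan(lead)):
            return None
        i = int(np.nanargmax(lead))
        s = self.leading_sigma_at(int(np.nonzero(mask)[0][i]))
        return float(qs[i]), s


def default_q_grid(q_min: float = 0.02, q_max: float = 1.6, n: int = 60) -> np.ndarray:
    """0 plus a log+linear hybrid grid: log-spaced up to 0.3 μm⁻¹ where the
    slow lateral branches live, then linear out to q_max."""
    n_log = n // 2
    n_lin = n - n_log
    lo = np.geomspace(q_min, 0.3, n_log, endpoint=False)
    hi = np.linspace(0.3, q_max, n_lin)
    return np.concatenate([[0.0], lo, hi])


def dispersion_branch(
    params: KineticParameters,
    geom: Geometry,
    totals: Totals,
    parity: Parity,
    q_grid: np.ndarray | None = None,
    n_branches: int = 4,
    steady: SteadyState | None = None,
) -> DispersionResult:
    """Track the leading determinant roots along q by continuation.

    At the first q the complex plane is grid-scanned; afterwards each branch
    is continued by Newton from its previous value, with a step-halving
    refinement (extra intermediate q) when a branch jumps or is lost.  Lost
    branches are marked NaN, never fabricated.
    """
    if geom.membranes != "both_faces":
        raise StabilityError("parity decomposition requires both_faces geometry")
    ss = steady or homogeneous_steady_state(params, geom, totals)
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    sig = np.full((len(q_grid), n_branches), np.nan + 0j, dtype=complex)

    prev: list[complex] = []
    prev_q = None
    for k, q in enumerate(q_grid):
        roots: list[complex] = []
        if prev_q is None or not prev:
            roots = find_roots(q, ss, parity, n_roots=n_branches)
            if parity == "symmetric" and q == 0 and any(abs(r) < NEUTRAL_TOL for r in roots):
                # the conserved-mass neutral root is a double root: seed two
                # branches from it so both split branches are tracked at q > 0
                roots.append(0.0 + 0.0j)
                roots.sort(key=lambda r: -r.real)
        else:
            for p in prev:
                r = _continue_root(p, prev_q, q, ss, parity)
                if r is None:
                    continue
                if any(abs(r - x) < 1e-7 * max(1, abs(r)) + 1e-12 for x in roots):
                    # collided with an already-continued branch (split double
                    # roots): deflate and retry from the seed
                    r = _polish(p, q, ss, parity, deflate=tuple(roots))
                    if r is None:
                        continue
                    if r.imag < 0:
                        r = r.conjugate()
                    if any(abs(r - x) < 1e-9 * max(1, abs(r)) + 1e-13 for x in roots):
                        continue
                if r.imag < 0:
                    r = r.conjugate()
                roots.append(r)
            if not roots:
                roots = find_roots(q, ss, parity, n_roots=n_branches)
            roots.sort(key=lambda r: -r.real)
        for b, r in enumerate(roots[:n_branches]):
            sig[k, b] = r
        prev = roots[:n_branches]
        prev_q = q
    return DispersionResult(q_grid=q_grid, sigma=sig, parity=parity,
                            params=params, geom=geom, totals=totals)


def _continue_root(s_prev: complex, q_prev: float, q: float, ss: SteadyState,
                   parity: Parity, depth: int = 0) -> complex | None:
    r = _polish(s_prev, q, ss, parity)
    if r is not None and (abs(r - s_prev) < 0.5 * (1 + abs(s_prev)) or depth >= 3):
        return r
    if depth >= 3:
        return r
    # jump or loss: halve the q step
    qm = 0.5 * (q_prev + q)
    mid = _continue_root(s_prev, q_prev, qm, ss, parity, depth + 1)
    if mid is None:
        return None
    return _continue_root(mid, qm, q, ss, parity, depth + 1)


# ---------------------------------------------------------------------------
# Mode classification
# ---------------------------------------------------------------------------

@dataclass
class ModeFlags:
    """Which mass-transport modes are unstable, read off the dispersion
    relations of the two parity sectors."""

    lateral_unstable: bool
    mm_unstable: bool
    mb_unstable: bool
    lateral_oscillatory: bool = False
    mm_oscillatory: bool = False
    mb_oscillatory: bool = False
    q_max: float | None = None
    sigma_max: complex | None = None

    def regimes(self) -> set[str]:
        out = set()
        if self.lateral_unstable:
            out.add("lateral")
        if self.mm_unstable:
            out.add("mm")
        if self.mb_unstable:
            out.add("mb")
        return out


def _q0_leading(disp: DispersionResult, exclude_neutral: bool) -> complex | None:
    idx = np.nonzero(disp.q_grid == 0)[0]
    if len(idx) == 0:
        return None
    row = disp.sigma[idx[0]]
    cands = [complex(s) for s in row if not np.isnan(s.real)]
    if exclude_neutral:
        cands = [s for s in cands if abs(s) > NEUTRAL_TOL]
    if not cands:
        return None
    return max(cands, key=lambda s: s.real)


def classify_modes(disp_sym: DispersionResult, disp_anti: DispersionResult) -> ModeFlags:
    """Instability flags per the q = 0 parity structure: m-to-m is the
    antisymmetric q = 0 mode, m-to-b the symmetric one (conserved-mass
    neutral roots excluded), lateral the fastest-growing q > 0 mode of either
    parity."""
    if disp_sym.params is not disp_anti.params and disp_sym.params != disp_anti.params:
        raise StabilityError("dispersion results come from different parameters")
    if disp_sym.parity != "symmetric" or disp_anti.parity != "antisymmetric":
        raise StabilityError("classify_modes needs one symmetric and one antisymmetric result")

    s_mm = _q0_leading(disp_anti, exclude_neutral=False)
    s_mb = _q0_leading(disp_sym, exclude_neutral=True)
    mm = s_mm is not None and s_mm.real > 0
    mb = s_mb is not None and s_mb.real > 0

    lat_best: tuple[float, complex] | None = None
    for disp in (disp_sym, disp_anti):
        m = disp.max_lateral()
        if m is not None and (lat_best is None or m[1].real > lat_best[1].real):
            lat_best = m
    lateral = lat_best is not None and lat_best[1].real > 0

    return ModeFlags(
        lateral_unstable=bool(lateral),
        mm_unstable=bool(mm),
        mb_unstable=bool(mb),
        lateral_oscillatory=bool(lateral and abs(lat_best[1].imag) > 1e-9),
        mm_oscillatory=bool(mm and abs(s_mm.imag) > 1e-9),
        mb_oscillatory=bool(mb and abs(s_mb.imag) > 1e-9),
        q_max=lat_best[0] if lat_best else None,
        sigma_max=lat_best[1] if lat_best else None,
    )


def mm_growth_rate(params: KineticParameters, totals: Totals, H: float,
                   dz_frac: float = 1 / 16) -> float | None:
    """Leading Re σ of the antisymmetric q = 0 (membrane-to-membrane) mode;
    None if the steady state does not exist."""
    geom = Geometry(H=H, dz=H * dz_frac)
    try:
        ss = homogeneous_steady_state(params, geom, totals)
    except ConvergenceError:
        return None
    roots = find_roots(0.0, ss, "antisymmetric")
    if not roots:
        return None
    return float(roots[0].real)


@dataclass
class CriticalHeightResult:
    """Result of the H_c search.  H_c is None when the m-to-m mode never
    becomes unstable on the scanned range; max_growth then certifies it."""

    H_c: float | None
    max_growth: float
    H_scanned: np.ndarray
    growth_scanned: np.ndarray

    def __bool__(self) -> bool:
        return self.H_c is not None


def critical_height(
    params: KineticParameters,
    totals: Totals,
    H_range: tuple[float, float] = (1.0, 30.0),
    tol: float = 0.05,
    n_scan: int = 12,
) -> CriticalHeightResult:
    """Lowest bulk height at which the membrane-to-membrane mode is unstable.

    A coarse scan of Re σ_mm(H) over H_range locates the first sign change,
    which is then refined by bisection to |error| < tol.
    """
    H_lo, H_hi = H_range
    Hs = np.linspace(H_lo, H_hi, n_scan)
    g = np.array([_neg_inf_if_none(mm_growth_rate(params, totals, H)) for H in Hs])
    finite = np.isfinite(g)
    if not finite.any() or np.all(g[finite] <= 0):
        return CriticalHeightResult(None, float(np.nanmax(np.where(finite, g, np.nan)))
                                    if finite.any() else -np.inf,
                                    H_scanned=Hs, growth_scanned=g)
    # first index where g > 0 with a stable point before it
    pos = np.nonzero(finite & (g > 0))[0]
    i1 = pos[0]
    if i1 == 0:
        # already unstable at H_lo: H_c is at or below the range start
        return CriticalHeightResult(float(Hs[0]), float(np.nanmax(g[finite])),
                                    H_scanned=Hs, growth_scanned=g)
    lo, hi = Hs[i1 - 1], Hs[i1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        gm = mm_growth_rate(params, totals, mid)
        if gm is not None and gm > 0:
            hi = mid
        else:
            lo = mid
    return CriticalHeightResult(float(0.5 * (lo + hi)), float(np.nanmax(g[finite])),
                                H_scanned=Hs, growth_scanned=g)


def _neg_inf_if_none(v):
    return -np.inf if v is None else v


# ---------------------------------------------------------------------------
# Phase diagram
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    H_grid: np.ndarray
    ed_grid: np.ndarray
    flags: list  # list of lists of ModeFlags | None (None: steady state failed)
    H_c_contour: dict  # ed -> H_c (or None)

    def regimes_at(self, i_H: int, j_ed: int) -> set[str] | None:
        f = self.flags[i_H][j_ed]
        return None if f is None else f.regimes()


def point_mode_flags(
    params: KineticParameters,
    totals: Totals,
    H: float,
    q_grid: np.ndarray | None = None,
    dz_frac: float = 1 / 16,
) -> ModeFlags:
    """classify_modes evaluated at a single (H, totals) point."""
    geom = Geometry(H=H, dz=H * dz_frac, L_x=None, dx=None)
    ss = homogeneous_steady_state(params, geom, totals)
    qg = default_q_grid(n=30) if q_grid is None else q_grid
    disp_s = dispersion_branch(params, geom, totals, "symmetric", qg, steady=ss)
    disp_a = dispersion_branch(params, geom, totals, "antisymmetric", qg, steady=ss)
    return classify_modes(disp_s, disp_a)


def phase_diagram(
    params: KineticParameters,
    H_grid: np.ndarray,
    ed_grid: np.ndarray,
    n_D: float,
    q_grid: np.ndarray | None = None,
    with_contour: bool = True,
) -> PhaseDiagram:
    """Pointwise mode classification over a (H, E:D) grid, with the m-to-m
    onset contour H_c(E:D) attached."""
    H_grid = np.asarray(H_grid, dtype=float)
    ed_grid = np.asarray(ed_grid, dtype=float)
    if len(H_grid) < 1 or len(ed_grid) < 1:
        raise StabilityError("grids must be non-empty")
    if np.any(np.diff(H_grid) < 0) or np.any(np.diff(ed_grid) < 0):
        raise StabilityError("grids must be sorted ascending")
    flags: list[list[ModeFlags | None]] = []
    for H in H_grid:
        row: list[ModeFlags | None] = []
        for ed in ed_grid:
            totals = Totals.from_ed_ratio(n_D, ed)
            try:
                row.append(point_mode_flags(params, totals, H, q_grid))
            except (ConvergenceError, StabilityError):
                row.append(None)
        flags.append(row)
    contour: dict[float, float | None] = {}
    if with_contour:
        for ed in ed_grid:
            totals = Totals.from_ed_ratio(n_D, ed)
            res = critical_height(params, totals, (float(H_grid[0]), float(H_grid[-1])))
            contour[float(ed)] = res.H_c
    return PhaseDiagram(H_grid=H_grid, ed_grid=ed_grid, flags=flags, H_c_contour=contour)
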