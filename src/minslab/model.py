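"""Skeleton MinDE model: species, membrane kinetics, conserved totals, and the
laterally homogeneous steady state of the two-membrane slab.

Bulk species (molecules/μm³): c_DD (MinD-ADP), c_DT (MinD-ATP), c_E (MinE).
Membrane species (molecules/μm²) on each membrane face: m_d (MinD), m_de
(MinDE complex).  Bulk reactions: nucleotide exchange c_DD → c_DT at rate λ.
Membrane kinetics at each face, driven by the bulk concentrations at that
face (subscript b)::

    attachment    (k_D + k_dD · m_d) · c_DT_b      [μm⁻² s⁻¹]
    recruitment   k_dE · m_d · c_E_b
    detachment    k_de · m_de        (releases one MinD-ADP and one MinE)

    dm_d/dt  = attachment − recruitment  (+ membrane diffusion)
    dm_de/dt = recruitment − detachment  (+ membrane diffusion)

The attachment/recruitment fluxes are withdrawn from the bulk at the membrane
(reactive boundary conditions); detachment injects into the bulk.  Total MinD
(c_DD + c_DT + m_d + m_de) and total MinE (c_E + m_de) are conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .params import Geometry, KineticParameters, Totals


class ModelError(RuntimeError):
    pass


class ConvergenceError(ModelError):
    """Root finding failed; carries the best iterate found."""

    def __init__(self, msg: str, residual: float | None = None, iterate=None):
        super().__init__(msg)
        self.residual = residual
        self.iterate = iterate


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class FieldState:
    """Complete simulated state on the (x, z) cell-centred grid.

    Bulk arrays have shape (nx, nz); membrane arrays shape (nx,).  The
    ``membranes`` dict maps face name ('bottom', 'top') to a dict with keys
    'm_d' and 'm_de'.  For bottom_only geometries only 'bottom' is present.
    """

    c_DD: np.ndarray
    c_DT: np.ndarray
    c_E: np.ndarray
    membranes: dict
    time: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(
            c_DD=self.c_DD.copy(),
            c_DT=self.c_DT.copy(),
            c_E=self.c_E.copy(),
            membranes={
                face: {k: v.copy() for k, v in vals.items()}
                for face, vals in self.membranes.items()
            },
            time=self.time,
        )

    def validate(self, geom: Geometry, tol: float = 1e-10) -> None:
        shape = (geom.nx, geom.nz)
        for name in ("c_DD", "c_DT", "c_E"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ModelError(f"{name} has shape {arr.shape}, expected {shape}")
            if arr.min() < -tol:
                raise ModelError(f"{name} has negative values (min {arr.min():g})")
        faces = {"bottom", "top"} if geom.membranes == "both_faces" else {"bottom"}
        if set(self.membranes) != faces:
            raise ModelError(f"membrane faces {set(self.membranes)} != {faces}")
        for face, vals in self.membranes.items():
            for k in ("m_d", "m_de"):
                if vals[k].shape != (geom.nx,):
                    raise ModelError(f"{face}.{k} has shape {vals[k].shape}")
                if vals[k].min() < -tol:
                    raise ModelError(f"{face}.{k} negative (min {vals[k].min():g})")


class MembraneFluxes(NamedTuple):
    """Reactive fluxes at one membrane face, all in μm⁻² s⁻¹."""

    f_attach_DT: np.ndarray | float  # bulk → membrane flux of MinD-ATP
    f_release_DD: np.ndarray | float  # membrane → bulk flux of MinD-ADP
    f_net_E: np.ndarray | float  # net bulk → membrane flux of MinE
    dm_d_dt: np.ndarray | float  # reactive part of dm_d/dt
    dm_de_dt: np.ndarray | float  # reactive part of dm_de/dt


def membrane_fluxes(m_d, m_de, c_DT_b, c_E_b, params: KineticParameters) -> MembraneFluxes:
    """Reactive membrane fluxes for given membrane densities and boundary
    bulk concentrations (scalars or arrays broadcast together)."""
    for name, v in (("m_d", m_d), ("m_de", m_de), ("c_DT_b", c_DT_b), ("c_E_b", c_E_b)):
        if np.any(np.asarray(v) < 0):
            raise ModelError(f"negative input: {name}")
    attach = (params.k_D + params.k_dD * np.asarray(m_d)) * c_DT_b
    recruit = params.k_dE * np.asarray(m_d) * c_E_b
    detach = params.k_de * np.asarray(m_de)
    return MembraneFluxes(
        f_attach_DT=attach,
        f_release_DD=detach,
        f_net_E=recruit - detach,
        dm_d_dt=attach - recruit,
        dm_de_dt=recruit - detach,
    )


# ---------------------------------------------------------------------------
# Mass bookkeeping
# ---------------------------------------------------------------------------

def total_masses(state: FieldState, geom: Geometry) -> tuple[float, float]:
    """Total MinD and MinE per unit lateral length (slice geometry) or per
    lateral area unit for nx = 1, using the midpoint (cell-sum) quadrature
    that the finite-volume integrator conserves exactly.

    Returns (N_D, N_E) where
    N_D = ∫(c_DD + c_DT) + Σ_faces ∫(m_d + m_de), N_E = ∫c_E + Σ_faces ∫m_de.
    """
    shape = (geom.nx, geom.nz)
    for name in ("c_DD", "c_DT", "c_E"):
        if getattr(state, name).shape != shape:
            raise ModelError(
                f"{name} shape {getattr(state, name).shape} inconsistent with geometry {shape}"
            )
    dz = geom.H / geom.nz
    dx = 1.0 if geom.L_x is None else geom.L_x / geom.nx
    bulk_D = (state.c_DD + state.c_DT).sum() * dz * dx
    bulk_E = state.c_E.sum() * dz * dx
    mem_D = sum((v["m_d"] + v["m_de"]).sum() * dx for v in state.membranes.values())
    mem_E = sum(v["m_de"].sum() * dx for v in state.membranes.values())
    if geom.L_x is None:
        # report per unit lateral area (nx == 1)
        pass
    return bulk_D + mem_D, bulk_E + mem_E


# ---------------------------------------------------------------------------
# Homogeneous steady state
# ---------------------------------------------------------------------------

@dataclass
class SteadyState:
    """Laterally uniform stationary solution.

    The vertical profiles are analytic: c_E and the total MinD field
    c_DD + c_DT are uniform in z (both obey pure diffusion with zero net
    boundary flux at stationarity), while c_DD(z) decays away from the
    membranes over the penetration length ℓ = sqrt(D_b/λ)::

        both_faces:  c_DD(z) = A · cosh((z − H/2)/ℓ)
        bottom_only: c_DD(z) = A · cosh((z − H)/ℓ)

    Membrane values m_d*, m_de* are identical on both faces.
    """

    params: KineticParameters
    geom: Geometry
    totals: Totals
    m_d: float
    m_de: float
    c_E: float
    c_D_total: float  # uniform value of c_DD + c_DT
    A: float  # amplitude of the c_DD cosh profile
    residual: float

    @property
    def ell(self) -> float:
        return self.params.penetration_depth

    def c_DD_profile(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        H, ell = self.geom.H, self.ell
        center = H / 2 if self.geom.membranes == "both_faces" else H
        return self.A * np.cosh((z - center) / ell)

    def c_DT_profile(self, z) -> np.ndarray:
        return self.c_D_total - self.c_DD_profile(z)

    @property
    def c_DD_boundary(self) -> float:
        return float(self.c_DD_profile(0.0))

    @property
    def c_DT_boundary(self) -> float:
        return self.c_D_total - self.c_DD_boundary

    def to_field_state(self, geom: Geometry | None = None) -> FieldState:
        """Sample the analytic profiles on a geometry's cell-centred grid."""
        geom = geom or self.geom
        z = geom.z_centers
        cdd = np.broadcast_to(self.c_DD_profile(z), (geom.nx, geom.nz)).copy()
        cdt = np.broadcast_to(self.c_DT_profile(z), (geom.nx, geom.nz)).copy()
        ce = np.full((geom.nx, geom.nz), self.c_E)
        faces = ["bottom", "top"] if geom.membranes == "both_faces" else ["bottom"]
        membranes = {
            f: {"m_d": np.full(geom.nx, self.m_d), "m_de": np.full(geom.nx, self.m_de)}
            for f in faces
        }
        return FieldState(c_DD=cdd, c_DT=cdt, c_E=ce, membranes=membranes, time=0.0)

    def summary(self) -> dict:
        return {
            "m_d": self.m_d,
            "m_de": self.m_de,
            "c_E": self.c_E,
            "c_D_total": self.c_D_total,
            "c_DD_boundary": self.c_DD_boundary,
            "c_DT_boundary": self.c_DT_boundary,
            "penetration_depth": self.ell,
            "residual": self.residual,
        }


def _stationarity_residual(params, ss_vals, H, eff_H_per_face) -> float:
    """Max relative violation of the three stationarity conditions."""
    m_d, m_de, c_E, cDT0 = ss_vals
    attach = (params.k_D + params.k_dD * m_d) * cDT0
    recruit = params.k_dE * m_d * c_E
    detach = params.k_de * m_de
    scale = max(attach, recruit, detach, 1e-300)
    return max(abs(attach - recruit), abs(recruit - detach)) / scale


def homogeneous_steady_state(
    params: KineticParameters,
    geom: Geometry,
    totals: Totals,
    tol: float = 1e-10,
) -> SteadyState:
    """Solve for the laterally homogeneous steady state by 1D root finding.

    The E and total-D mass constraints plus the recruitment/detachment balance
    reduce the problem to a single equation in m_de (the attachment balance),
    solved with Brent's method on a sign-change bracket.
    """
    H = geom.H
    n_faces = geom.n_membranes
    if params.k_D == 0.0 and params.k_dD == 0.0:
        # no attachment pathway: empty membranes
        return SteadyState(
            params=params, geom=geom, totals=totals, m_d=0.0, m_de=0.0,
            c_E=totals.n_E, c_D_total=totals.n_D, A=0.0, residual=0.0,
        )
    ell = params.penetration_depth
    D = params.D_bulk_D
    # cosh-profile geometry factor: c_DD(0) = A cosh(h/ell), flux D A/ell sinh(h/ell)
    h = H / 2 if geom.membranes == "both_faces" else H
    sinh_h = math.sinh(h / ell)
    cosh_h = math.cosh(h / ell)
    # mean of cosh profile over [0, H]: (ell/h) sinh(h/ell) for both cases
    mean_cosh = (ell / h) * sinh_h

    def parts(m_de: float):
        c_E = totals.n_E - n_faces * m_de / H
        if c_E <= 0:
            return None
        m_d = params.k_de * m_de / (params.k_dE * c_E) if m_de > 0 else 0.0
        B = totals.n_D - n_faces * (m_d + m_de) / H
        A = params.k_de * m_de * ell / (D * sinh_h) if m_de > 0 else 0.0
        # mass constraint: mean bulk D-total = B means int (cDD+cDT) = B*H exactly,
        # c_DD mean = A * mean_cosh; c_DT mean adjusts, uniform total = B.
        cDT0 = B - A * cosh_h
        return m_d, B, A, cDT0, c_E

    def g(m_de: float) -> float:
        p = parts(m_de)
        if p is None:
            return -np.inf
        m_d, B, A, cDT0, c_E = p
        return (params.k_D + params.k_dD * m_d) * cDT0 - params.k_de * m_de

    hi = totals.n_E * H / n_faces * (1 - 1e-12)
    xs = np.linspace(1e-12, hi, 4001)
    vals = np.array([g(x) for x in xs])
    finite = np.isfinite(vals)
    sign_changes = np.where(np.diff(np.sign(vals[finite])) != 0)[0]
    if len(sign_changes) == 0:
        best = int(np.nanargmin(np.abs(vals[finite])))
        raise ConvergenceError(
            "no steady-state bracket found (no sign change of the attachment balance)",
            residual=float(np.abs(vals[finite][best])),
            iterate=float(xs[finite.nonzero()[0][best]]),
        )
    xs_f = xs[finite]
    i = sign_changes[-1]
    m_de = brentq(g, xs_f[i], xs_f[i + 1], xtol=1e-15, rtol=8.9e-16, maxiter=200)
    m_d, B, A, cDT0, c_E = parts(m_de)
    if cDT0 < 0 or m_d < 0:
        raise ConvergenceError("steady state has negative boundary concentration",
                               residual=abs(cDT0), iterate=m_de)
    residual = _stationarity_residual(params, (m_d, m_de, c_E, cDT0), H, h)
    if residual > max(tol, 1e-9):
        raise ConvergenceError(
            f"steady-state residual {residual:g} exceeds tolerance", residual=residual,
            iterate=m_de,
        )
    return SteadyState(
        params=params, geom=geom, totals=totals, m_d=float(m_d), m_de=float(m_de),
        c_E=float(c_E), c_D_total=float(B), A=float(A), residual=float(residual),
    )
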