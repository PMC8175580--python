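"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's analytic machinery: the vertical
problem is discretized by brute force and handed to a dense eigensolver /
linear solver, and the well-mixed limit is obtained by direct ODE
integration.
"""

import numpy as np
from scipy.integrate import solve_ivp


def wellmixed_fixed_point(params, H, n_D, n_E, t_end=20000.0):
    """Fixed point of the well-mixed (zero-gradient) compartment ODEs for a
    two-membrane slab of height H, by long-time integration."""
    a = 2.0 / H  # membrane area per bulk volume

    def rhs(t, y):
        cDD, cDT, cE, m_d, m_de = y
        attach = (params.k_D + params.k_dD * m_d) * cDT
        recruit = params.k_dE * m_d * cE
        detach = params.k_de * m_de
        return [
            -params.lambda_exch * cDD + a * detach,
            params.lambda_exch * cDD - a * attach,
            a * (detach - recruit),
            attach - recruit,
            recruit - detach,
        ]

    y0 = [0.0, n_D, n_E, 0.0, 0.0]
    sol = solve_ivp(rhs, (0, t_end), y0, method="LSODA", rtol=1e-11, atol=1e-12)
    return sol.y[:, -1]  # cDD, cDT, cE, m_d, m_de


def vertical_jacobian(params, H, ss_vals, q, N=300):
    """Dense Jacobian of the linearized two-membrane vertical problem at
    lateral wavenumber q; ss_vals = (m_d, c_E, c_DT_boundary)."""
    m_d, cE, cDT0 = ss_vals
    dz = H / N
    D = params.D_b
    lam = params.lambda_exch
    kdD, kdE, kde, Dm = params.k_dD, params.k_dE, params.k_de, params.D_m
    aD = params.k_D + kdD * m_d
    n = 3 * N + 4
    J = np.zeros((n, n))
    r = D / dz**2
    for b in (0, N, 2 * N):
        for i in range(N):
            if i > 0:
                J[b + i, b + i - 1] += r
                J[b + i, b + i] -= r
            if i < N - 1:
                J[b + i, b + i + 1] += r
                J[b + i, b + i] -= r
            J[b + i, b + i] -= D * q**2
    for i in range(N):
        J[i, i] -= lam
        J[N + i, i] += lam
    for cell, mdix, mdeix in [(0, 3 * N, 3 * N + 1), (N - 1, 3 * N + 2, 3 * N + 3)]:
        J[cell, mdeix] += kde / dz
        J[N + cell, N + cell] += -aD / dz
        J[N + cell, mdix] += -kdD * cDT0 / dz
        J[2 * N + cell, 2 * N + cell] += -kdE * m_d / dz
        J[2 * N + cell, mdix] += -kdE * cE / dz
        J[2 * N + cell, mdeix] += kde / dz
        J[mdix, N + cell] += aD
        J[mdix, mdix] += kdD * cDT0 - kdE * cE - Dm * q**2
        J[mdix, 2 * N + cell] += -kdE * m_d
        J[mdeix, mdix] += kdE * cE
        J[mdeix, 2 * N + cell] += kdE * m_d
        J[mdeix, mdeix] += -kde - Dm * q**2
    return J


def leading_vertical_eigs(params, H, ss, q, N=300, n_lead=6):
    """Leading eigenvalues (with membrane parity labels) of the discretized
    vertical problem, sorted by decreasing real part."""
    J = vertical_jacobian(params, H, (ss.m_d, ss.c_E, ss.c_DT_boundary), q, N)
    ev, V = np.linalg.eig(J)
    order = np.argsort(-ev.real)[: n_lead * 2]
    out = []
    for k in order:
        v = V[:, k]
        anti = abs(v[3 * N] - v[3 * N + 2]) + abs(v[3 * N + 1] - v[3 * N + 3])
        sym = abs(v[3 * N] + v[3 * N + 2]) + abs(v[3 * N + 1] + v[3 * N + 3])
        out.append((ev[k], "antisymmetric" if anti > sym else "symmetric"))
        if len(out) >= n_lead:
            break
    return out


def single_species_flux_response_fd(D, r, sigma, q, H, parity, N=4000):
    """Flux response of one bulk species by dense finite differences: solve
    the vertical two-point boundary problem with unit concentration at z=0
    and the parity condition at the midplane; return the flux the membrane
    must inject, -D c'(0)·(sign convention: response = D α tanh/coth)."""
    # solve on [0, H/2] with c(0)=1; at z=H/2: symmetric → c'=0, anti → c=0
    h = (H / 2) / N
    alpha2 = q**2 + (sigma + r) / D
    n = N + 1
    A = np.zeros((n, n), dtype=complex)
    b = np.zeros(n, dtype=complex)
    A[0, 0] = 1.0
    b[0] = 1.0
    for i in range(1, N):
        A[i, i - 1] = 1 / h**2
        A[i, i] = -2 / h**2 - alpha2
        A[i, i + 1] = 1 / h**2
    if parity == "symmetric":
        # ghost-node Neumann at z=H/2
        A[N, N - 1] = 2 / h**2
        A[N, N] = -2 / h**2 - alpha2
    else:
        A[N, N] = 1.0
    c = np.linalg.solve(A, b)
    # one-sided 4th-order derivative at z=0
    dc0 = (-25 * c[0] + 48 * c[1] - 36 * c[2] + 16 * c[3] - 3 * c[4]) / (12 * h)
    return -D * dc0
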