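"""Independent oracles used only by the test suite.

These deliberately avoid the package's own code paths: the PDE is solved
numerically instead of in closed form, and mass decomposition is a naive
nested-loop enumeration instead of the vectorized grid search.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded


def crank_nicolson_breakthrough(
    z_eval,
    t_final: float,
    D: float,
    V: float,
    L: float = 20.0,
    n_nodes: int = 2001,
    n_steps: int = 4000,
):
    """Dimensionless solution of dC/dt = D d2C/dz2 - V dC/dz on [0, L].

    Boundary conditions C(0) = 1, C(L) = 0; initial condition C = 0.
    Crank-Nicolson in time, central differences in space; returns the
    solution linearly interpolated at ``z_eval``.
    """
    z = np.linspace(0.0, L, n_nodes)
    dz = z[1] - z[0]
    dt = t_final / n_steps

    # interior operator A u = D (u_{i-1} - 2 u_i + u_{i+1})/dz^2
    #                       - V (u_{i+1} - u_{i-1})/(2 dz)
    alpha = D / dz**2
    beta = V / (2.0 * dz)
    lower = alpha + beta   # coefficient of u_{i-1}
    diag = -2.0 * alpha
    upper = alpha - beta   # coefficient of u_{i+1}

    n_int = n_nodes - 2
    # (I - dt/2 A) u^{n+1} = (I + dt/2 A) u^n + boundary terms
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -0.5 * dt * upper
    ab[1, :] = 1.0 - 0.5 * dt * diag
    ab[2, :-1] = -0.5 * dt * lower

    u = np.zeros(n_nodes)
    u[0] = 1.0
    for _ in range(n_steps):
        interior = u[1:-1]
        rhs = (
            interior
            + 0.5 * dt * (diag * interior + lower * u[:-2] + upper * u[2:])
        )
        # boundary contribution at the next time level (u0 = 1, uN = 0)
        rhs[0] += 0.5 * dt * lower * 1.0
        u[1:-1] = solve_banded((1, 1), ab, rhs)
        u[0] = 1.0
        u[-1] = 0.0
    return np.interp(np.asarray(z_eval, dtype=float), z, u)


# IUPAC monoisotopic masses, restated independently of the package
_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}


def brute_force_decompose(
    neutral: float,
    c_max: int,
    h_max: int,
    n_max: int,
    o_max: int,
    s_max: int,
    ppm_tol: float,
    c_min: int = 1,
    h_min: int = 1,
    hc_range=(0.3, 2.5),
    oc_range=(0.0, 1.2),
):
    """Naive exhaustive enumeration of CHNOS formulas matching a neutral mass.

    Loops over every element count explicitly (including hydrogen) and
    applies the same chemical filters the package claims to use: |ppm| within
    tolerance, RDBE >= 0 and integer (H, N of equal parity), H/C and O/C in
    range.  Returns a set of (nC, nH, nN, nO, nS) tuples.
    """
    tol_u = neutral * ppm_tol * 1e-6
    hits = set()
    for nc in range(c_min, c_max + 1):
        m_c = nc * _MASS["C"]
        if m_c > neutral + tol_u:
            break
        for ns in range(0, s_max + 1):
            m_cs = m_c + ns * _MASS["S"]
            if m_cs > neutral + tol_u:
                break
            for nn in range(0, n_max + 1):
                m_csn = m_cs + nn * _MASS["N"]
                if m_csn > neutral + tol_u:
                    break
                for no in range(0, o_max + 1):
                    m_csno = m_csn + no * _MASS["O"]
                    if m_csno > neutral + tol_u:
                        break
                    for nh in range(h_min, h_max + 1):
                        mass = m_csno + nh * _MASS["H"]
                        if mass > neutral + tol_u:
                            break
                        if abs(mass - neutral) > tol_u:
                            continue
                        dbe = nc - nh / 2.0 + nn / 2.0 + 1.0
                        if dbe < 0 or (nh + nn) % 2 != 0:
                            continue
                        hc = nh / nc
                        oc = no / nc
                        if not (hc_range[0] <= hc <= hc_range[1]):
                            continue
                        if not (oc_range[0] <= oc <= oc_range[1]):
                            continue
                        hits.add((nc, nh, nn, no, ns))
    return hits


def dense_grid_threshold_depth(depths, aw_values, threshold, dz: float = 1e-3):
    """Brute-force threshold crossing: scan a dense linearly interpolated grid."""
    grid = np.arange(depths[0], depths[-1] + dz / 2, dz)
    aw = np.interp(grid, depths, aw_values)
    below = np.flatnonzero(aw <= threshold)
    if below.size == 0 or below[0] == 0:
        return float(grid[below[0]]) if below.size else None
    return float(grid[below[0]])
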