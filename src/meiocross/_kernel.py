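"""Numba kernel for the explicit-Euler integration of the coarsening dynamics.

The kernel advances a batch of independent synaptonemal complexes (SCs), each
discretized on the same uniform grid, with per-simulation time steps.  Foci
must be supplied sorted by (host node, amount): within a shared node the
floating-point accumulation order onto the concentration field then depends
only on the amounts, which makes a mirrored configuration evolve into the
bitwise-mirrored final state.

No fastmath: operand grouping is chosen so that reflection symmetry of the
scheme is exact in floating point, and the compiler must not reassociate it.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def euler_coarsen(c, M, node, dt_arr, nsteps_arr, D, lam, c0, alpha, dx):
    """Advance each row of ``c``/``M`` by its own (dt, nsteps).

    Parameters
    ----------
    c : (n_sim, n_grid) float64
        HEI10 concentration per grid node, modified in place.
    M : (n_sim, n_foci) float64
        Focus amounts, modified in place.  Must be >= 0 on entry.
    node : (n_sim, n_foci) int64
        Host grid node of each focus, sorted together with M by
        (node, amount) within each row.
    dt_arr, nsteps_arr : (n_sim,) float64 / int64
        Per-simulation step size and step count (dt * nsteps = duration).
    D, lam, c0, alpha, dx : float
        Diffusivity, exchange rate, base equilibrium concentration,
        equilibrium exponent, grid spacing.

    No-flux boundaries use the finite-volume ghost form (c[-1] = c[0]),
    which conserves dx*sum(c) + sum(M) exactly up to rounding.  A step that
    would drive a focus amount negative is flux-limited so the amount lands
    on zero and only the available mass returns to the SC.
    """
    n_sim, n_grid = c.shape
    n_foci = M.shape[1]
    inv_dx = 1.0 / dx
    use_sqrt = alpha == 0.25
    for s in range(n_sim):
        dt = dt_arr[s]
        nsteps = nsteps_arr[s]
        beta = D * dt / (dx * dx)
        dtlam = dt * lam
        a = c[s].copy()
        b = np.empty(n_grid)
        Ms = M[s].copy()
        nds = node[s]
        for _ in range(nsteps):
            b[0] = a[0] + beta * (a[1] - a[0])
            for j in range(1, n_grid - 1):
                # symmetric grouping: (left + right) - 2*mid
                b[j] = a[j] + beta * ((a[j - 1] + a[j + 1]) - 2.0 * a[j])
            b[n_grid - 1] = a[n_grid - 1] + beta * (a[n_grid - 2] - a[n_grid - 1])
            for i in range(n_foci):
                nd = nds[i]
                m = Ms[i]
                if use_sqrt:
                    mp = m * np.sqrt(np.sqrt(m))  # m^(1+alpha), alpha = 1/4
                else:
                    mp = m ** (1.0 + alpha)
                dM = dtlam * (a[nd] - c0 * m / (1.0 + mp))
                if dM < -m:
                    dM = -m
                Ms[i] = m + dM
                b[nd] -= dM * inv_dx
            tmp = a
            a = b
            b = tmp
        c[s] = a
        M[s] = Ms
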