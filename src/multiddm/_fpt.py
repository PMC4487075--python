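"""Numba kernels: Crank-Nicolson first-passage-time solver.

The Fokker-Planck equation for a unit-variance diffusion with time-varying
drift mu(t) and absorbing bounds at +/-theta is solved on the bound-
normalized domain x in (-1, 1):

    p_t = -(mu/theta) p_x + (1 / (2 theta^2)) p_xx ,  p(+/-1, t) = 0.

Crank-Nicolson in time (Rannacher backward-Euler start-up to damp the
delta initial condition), central differences in space, Thomas solves for
the tridiagonal systems.  Absorbed probability per step is attributed to
the upper/lower boundary in proportion to the discrete boundary fluxes,
which makes the scheme mass-conserving by construction.
"""
import numpy as np
from numba import njit

N_RANNACHER = 2  # initial dt-steps done as two backward-Euler half-steps


@njit(cache=True)
def _thomas(sub, diag, sup, rhs, out, cp, dp):
    """Solve a tridiagonal system with constant off-diagonals."""
    n = rhs.shape[0]
    cp[0] = sup / diag
    dp[0] = rhs[0] / diag
    for i in range(1, n):
        m = diag - sub * cp[i - 1]
        cp[i] = sup / m
        dp[i] = (rhs[i] - sub * dp[i - 1]) / m
    out[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        out[i] = dp[i] - cp[i] * out[i + 1]


@njit(cache=True)
def _fpt_single(mu, theta, bias, dt, n_x, g_up, g_lo):
    """First-passage densities for one (drift timecourse, bound) pair.

    Fills g_up/g_lo (length T, mass absorbed per step / dt) and returns
    (forced_up, forced_lo): surviving mass at the deadline split by the
    sign of the particle (the forced-choice rule).
    """
    T = mu.shape[0]
    N = n_x
    dx = 2.0 / (N + 1)
    D = 1.0 / (2.0 * theta * theta)
    r = D / (dx * dx)

    p = np.zeros(N)
    # delta initial condition at x = bias, linearly split between nodes
    pos = (bias + 1.0) / dx          # node index j in 1..N at x=-1+j*dx
    j = int(np.floor(pos))
    frac = pos - j
    if j < 1:
        p[0] = 1.0
    elif j >= N:
        p[N - 1] = 1.0
    else:
        p[j - 1] += 1.0 - frac
        p[j] += frac

    q = np.empty(N)
    rhs = np.empty(N)
    cp = np.empty(N)
    dp = np.empty(N)

    for n in range(T):
        a = 0.5 * (mu[n] + mu[min(n + 1, T - 1)]) / theta
        adv = a / (2.0 * dx)
        am = r + adv      # coefficient of p_{i-1} in L
        ap = r - adv      # coefficient of p_{i+1} in L
        s_old = p.sum()

        if n < N_RANNACHER:
            # two backward-Euler half-steps (damps CN oscillations)
            h = 0.5 * dt
            sub = -h * am
            dia = 1.0 + 2.0 * h * r
            sup = -h * ap
            for _ in range(2):
                for i in range(N):
                    rhs[i] = p[i]
                _thomas(sub, dia, sup, rhs, q, cp, dp)
                for i in range(N):
                    p[i] = q[i]
            q_new = p
        else:
            h = 0.5 * dt
            # rhs = (I + h L) p
            for i in range(N):
                lo_v = p[i - 1] if i > 0 else 0.0
                hi_v = p[i + 1] if i < N - 1 else 0.0
                rhs[i] = p[i] + h * (am * lo_v - 2.0 * r * p[i] + ap * hi_v)
            _thomas(-h * am, 1.0 + 2.0 * h * r, -h * ap, rhs, q, cp, dp)
            for i in range(N):
                p[i] = q[i]
            q_new = p

        s_new = q_new.sum()
        absorbed = s_old - s_new
        if absorbed < 0.0:
            absorbed = 0.0
        # split by discrete boundary fluxes at the step midpoint
        f_up = am * q_new[N - 1]
        f_lo = ap * q_new[0]
        if f_up < 0.0:
            f_up = 0.0
        if f_lo < 0.0:
            f_lo = 0.0
        tot = f_up + f_lo
        if tot <= 0.0:
            w_up = 0.5
        else:
            w_up = f_up / tot
        g_up[n] = absorbed * w_up / dt
        g_lo[n] = absorbed * (1.0 - w_up) / dt

    # forced choices: surviving mass split by particle sign (ties even)
    forced_up = 0.0
    forced_lo = 0.0
    half = 0.5 * dx
    for i in range(N):
        x = -1.0 + (i + 1) * dx
        m = p[i]
        if m < 0.0:
            m = 0.0
        if x > half:
            forced_up += m
        elif x < -half:
            forced_lo += m
        else:
            forced_up += 0.5 * m
            forced_lo += 0.5 * m
    return forced_up, forced_lo


@njit(cache=True)
def fpt_batch(mu_b, theta_b, bias_b, dt, n_x):
    """Solve a batch of FPT problems sharing one time grid.

    Parameters: mu_b (B, T) drift samples; theta_b (B,) scaled bounds;
    bias_b (B,) start offsets in bound units; dt grid step; n_x interior
    spatial points.  Zero bounds short-circuit to an immediate decision
    with P(upper) = (1 + bias)/2 placed in the first time bin.
    """
    B, T = mu_b.shape
    g_up = np.zeros((B, T))
    g_lo = np.zeros((B, T))
    forced = np.zeros((B, 2))
    for b in range(B):
        if theta_b[b] <= 1e-12:
            p_up = 0.5 * (1.0 + bias_b[b])
            g_up[b, 0] = p_up / dt
            g_lo[b, 0] = (1.0 - p_up) / dt
        else:
            fu, fl = _fpt_single(mu_b[b], theta_b[b], bias_b[b], dt, n_x,
                                 g_up[b], g_lo[b])
            forced[b, 0] = fu
            forced[b, 1] = fl
    return g_up, g_lo, forced
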