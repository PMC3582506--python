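"""Independent finite-difference oracle for the local-binding FRAP problem.

Solves the same radially symmetric two-region PDE as the Laplace-domain
model, but by direct time stepping: Crank-Nicolson for diffusion combined
with an exact per-node update of the linear binding kinetics (Strang
splitting).  Shares no code with the model under test.
"""

import numpy as np
from scipy.linalg import solve_banded


def local_binding_frap_fd(t_eval, D, kon, koff, w, r_n, bleach_depth=0.0,
                          n_r=240, dt=None):
    """FRAP curve (mean free+bound over the disc r<w, pre-bleach-normalized).

    Free species diffuses everywhere; reversible binding to immobile sites
    only inside r < w; zero flux at r = r_n; initial condition: region 1 at
    bleach_depth times the steady state, region 2 at steady state.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    r = np.linspace(0.0, r_n, n_r + 1)
    dr = r[1] - r[0]
    inside = r <= w + 1e-12

    f_eq = koff / (kon + koff)
    c_eq = kon / (kon + koff)
    f = np.full(n_r + 1, f_eq)
    c = np.where(inside, c_eq, 0.0)
    f[inside] *= bleach_depth
    c[inside] *= bleach_depth

    if dt is None:
        dt = min(0.2 * dr**2 / D * 20, (t_eval[-1] / 4000.0))
        dt = max(dt, 1e-6)

    # Crank-Nicolson matrices for the radial Laplacian
    lap = np.zeros((3, n_r + 1))  # banded (upper, diag, lower)
    main = np.zeros(n_r + 1)
    up = np.zeros(n_r + 1)
    lo = np.zeros(n_r + 1)
    main[0], up[1] = -4.0 / dr**2, 4.0 / dr**2
    for i in range(1, n_r):
        main[i] = -2.0 / dr**2
        up[i + 1] = 1.0 / dr**2 + 1.0 / (2.0 * r[i] * dr)
        lo[i - 1] = 1.0 / dr**2 - 1.0 / (2.0 * r[i] * dr)
    main[n_r], lo[n_r - 1] = -2.0 / dr**2, 2.0 / dr**2

    alpha = 0.5 * D * dt
    ab = np.zeros((3, n_r + 1))
    ab[0] = -alpha * up
    ab[1] = 1.0 - alpha * main
    ab[2] = -alpha * lo

    def rhs_apply(v):
        out = (1.0 + alpha * main) * v
        out[:-1] += alpha * up[1:] * v[1:]
        out[1:] += alpha * lo[:-1] * v[:-1]
        return out

    # exact binding update over dt/2 (linear two-state kinetics per node)
    rate = kon + koff
    decay = np.exp(-rate * dt / 2.0)

    def react_half():
        s = f + c
        f_target = np.where(inside, koff / rate * s, f)
        c_target = np.where(inside, kon / rate * s, c)
        f_new = f_target + (f - f_target) * decay
        c_new = c_target + (c - c_target) * decay
        return np.where(inside, f_new, f), np.where(inside, c_new, c)

    # disc-average weights (trapezoid on 2 pi r dr, normalized)
    wts = np.where(inside, r, 0.0)
    wts[0] = r[1] / 8.0  # center cell contribution
    trap = wts.copy()
    idx = np.nonzero(inside)[0]
    trap[idx[0]] *= 0.5
    trap[idx[-1]] *= 0.5
    norm = trap.sum()

    def signal():
        return float(np.sum(trap * (f + c)) / norm)

    out = np.empty(t_eval.size)
    t = 0.0
    k = 0
    while k < t_eval.size:
        if t >= t_eval[k] - 1e-12:
            out[k] = signal()
            k += 1
            continue
        f, c = react_half()
        f = solve_banded((1, 1), ab, rhs_apply(f))
        f, c = react_half()
        t += dt
    return out
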