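"""Compiled inner loops for the reaction-diffusion integrator.

The medium is a two-variable activator/inhibitor system on a regular grid
with no-flux boundaries (mirror indexing).  Explicit Euler in time, 5-point
Laplacian in space; the caller is responsible for choosing a stable dt.
"""

from numba import njit


@njit(cache=True, fastmath=True)
def advance(u, v, b_field, a, eps, inv_tau_field, d_px, dt, t0, nsteps,
            act_t, act_n, prev_above, work):
    """Advance the fields ``nsteps`` Euler steps in place.

    u, v        : (H, W) float64 state fields, modified in place
    b_field     : (H, W) spatial excitability-threshold offset
    inv_tau_field: (H, W) reciprocal recovery time constant, 1/s
    d_px        : diffusion coefficient in px^2/s
    act_t       : (H*W, max_cycles) upstroke times (s), NaN-padded
    act_n       : (H*W,) int32 number of upstrokes recorded per pixel
    prev_above  : (H*W,) uint8 Schmitt-trigger state for upstroke detection
    work        : (H, W) scratch buffer
    Returns the simulation time after the last step.
    """
    H, W = u.shape
    inv_eps = 1.0 / eps
    inv_a = 1.0 / a
    max_c = act_t.shape[1]
    t = t0
    for s in range(nsteps):
        t = t0 + (s + 1) * dt
        for i in range(H):
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < H - 1 else H - 2
            for j in range(W):
                jm = j - 1 if j > 0 else 1
                jp = j + 1 if j < W - 1 else W - 2
                uc = u[i, j]
                lap = u[im, j] + u[ip, j] + u[i, jm] + u[i, jp] - 4.0 * uc
                uth = (v[i, j] + b_field[i, j]) * inv_a
                un = uc + dt * (d_px * lap
                                + inv_eps * uc * (1.0 - uc) * (uc - uth))
                v[i, j] += dt * inv_tau_field[i, j] * (uc - v[i, j])
                work[i, j] = un
                k = i * W + j
                if prev_above[k] == 0:
                    if un >= 0.5:
                        n = act_n[k]
                        if n < max_c:
                            # linear interpolation of the crossing instant
                            if un > uc:
                                act_t[k, n] = t - dt * (un - 0.5) / (un - uc)
                            else:
                                act_t[k, n] = t
                        act_n[k] = n + 1
                        prev_above[k] = 1
                else:
                    if un < 0.4:
                        prev_above[k] = 0
        for i in range(H):
            for j in range(W):
                u[i, j] = work[i, j]
    return t
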