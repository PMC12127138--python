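"""Compiled inner loops for the latent-state Gibbs sweeps.

Each sweep updates the unknown latent states one site at a time in
occasion order (a systematic single-site scan), drawing each site from its
full conditional given its temporal neighbours and the observations.
Individuals whose entire latent trajectory is determined by the data
(those recovered dead) are skipped; their states are fixed at
initialization and enter only the parameter updates.

A site whose full conditional has zero support is left unchanged and
counted: for the classical multistate model this counter exposes the
trapping mechanism of single-site updating.
"""

import numpy as np
from numba import njit

__all__ = [
    "sweep_single",
    "sweep_multistate",
    "forward_two_state",
    "forward_multistate",
]


@njit(cache=False)
def forward_two_state(live, dead, f0, s, r, p):
    """Per-history forward log-probabilities for the single-state model.

    Components: alive, and dead-with-the-death-interval-already-accounted
    (recovered or its non-recovery absorbed).  Returns (n,) log-likelihoods;
    -inf marks a history impossible under the parameters.
    """
    n, T = live.shape
    out = np.zeros(n)
    for i in range(n):
        a = 1.0
        dacc = 0.0
        ll = 0.0
        for t in range(f0[i] + 1, T):
            seen = live[i, t] == 1
            rec = dead[i, t] == 1
            if rec:
                na = 0.0
                nd = 0.0 if seen else a * (1.0 - s) * r
            elif seen:
                na = a * s * p
                nd = 0.0
            else:
                na = a * s * (1.0 - p)
                nd = a * (1.0 - s) * (1.0 - r) + dacc
            c = na + nd
            if c <= 0.0:
                ll = -np.inf
                break
            ll += np.log(c)
            a = na / c
            dacc = nd / c
        out[i] = ll
    return out


@njit(cache=False)
def forward_multistate(codes, f0, omega, theta):
    """Per-history 3-state HMM forward log-probabilities.

    ``codes`` carries observed states 1..3; the filter starts in the alive
    state at marking (no emission term for the marking occasion).
    """
    n, T = codes.shape
    out = np.zeros(n)
    alpha = np.empty(3)
    nxt = np.empty(3)
    for i in range(n):
        alpha[0] = 1.0
        alpha[1] = 0.0
        alpha[2] = 0.0
        ll = 0.0
        for t in range(f0[i] + 1, T):
            o = codes[i, t] - 1
            c = 0.0
            for k in range(3):
                acc = 0.0
                for j in range(3):
                    acc += alpha[j] * omega[j, k]
                nxt[k] = acc * theta[k, o]
                c += nxt[k]
            if c <= 0.0:
                ll = -np.inf
                break
            ll += np.log(c)
            for k in range(3):
                alpha[k] = nxt[k] / c
        out[i] = ll
    return out


@njit(cache=False)
def sweep_single(z, f0, live, recovered, s, r, p, u):
    """One systematic-scan sweep for the single-state model.

    z : (n, T) int64, 1 alive / 0 dead, fixed rows where recovered
    f0 : 0-based marking occasions
    live : (n, T) int64 live-encounter indicators (0 everywhere for
        dead-recovery data; then p must be 0)
    recovered : (n,) boolean-as-int, rows with a dead recovery (skipped)
    u : (n, T) uniforms consumed one per visited site
    Returns the number of zero-support sites encountered.
    """
    n, T = z.shape
    trapped = 0
    for i in range(n):
        if recovered[i] == 1:
            continue
        for t in range(f0[i] + 1, T):
            if z[i, t - 1] == 0:
                z[i, t] = 0
                continue
            if live[i, t] == 1:
                z[i, t] = 1
                continue
            if t < T - 1 and z[i, t + 1] == 1:
                z[i, t] = 1
                continue
            if t < T - 1:
                # successor is dead and unrecovered at t+1
                w1 = s * (1.0 - p) * (1.0 - s) * (1.0 - r)
                w0 = (1.0 - s) * (1.0 - r)
            else:
                w1 = s * (1.0 - p)
                w0 = (1.0 - s) * (1.0 - r)
            tot = w1 + w0
            if tot <= 0.0:
                trapped += 1
                continue
            z[i, t] = 1 if u[i, t] < w1 / tot else 0
    return trapped


@njit(cache=False)
def sweep_multistate(z, f0, obs, recovered, omega, theta, u):
    """One systematic-scan sweep for a 3-state model.

    z : (n, T) int64 latent codes 1..3
    obs : (n, T) int64 observed codes 1..3 (multistate encoding)
    omega, theta : (3, 3) transition and observation matrices
    Returns the number of zero-support sites (the trap counter).
    """
    n, T = z.shape
    trapped = 0
    w = np.empty(3)
    for i in range(n):
        if recovered[i] == 1:
            continue
        for t in range(f0[i] + 1, T):
            zprev = z[i, t - 1] - 1
            o = obs[i, t] - 1
            tot = 0.0
            for k in range(3):
                wk = omega[zprev, k] * theta[k, o]
                if t < T - 1:
                    wk *= omega[k, z[i, t + 1] - 1]
                w[k] = wk
                tot += wk
            if tot <= 0.0:
                trapped += 1
                continue
            x = u[i, t] * tot
            acc = w[0]
            state = 0
            while acc < x and state < 2:
                state += 1
                acc += w[state]
            z[i, t] = state + 1
    return trapped
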