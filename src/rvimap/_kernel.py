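"""Numba kernel for the structured-grid monodomain solver.

Operator splitting per time step: an explicit 5-point (2D) / 7-point (3D)
finite-difference diffusion update with harmonic-mean face conductivities
and no-flux boundaries, followed by the pointwise ionic update
(:func:`rvimap.tt06.ionic_pass`). Non-conducting (SCAR/LESION) nodes have
zero diffusivity and are skipped by the ionic pass, so they act as
internal no-flux boundaries.

Threshold-crossing events (activation and repolarisation times, linearly
interpolated within the step) are streamed into fixed-capacity per-node
event buffers during the run, so full V histories never need to be kept.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .tt06 import ionic_pass


def face_weights(D, shape, dx_mm):
    """Precompute the (n, 6) diffusion face weights w/dx^2.

    Order: [-x, +x, -y, +y, -z, +z]. Each weight is the harmonic mean of
    the two adjacent node diffusivities (zero across non-conducting nodes
    and at domain boundaries — the no-flux condition).
    """
    nx, ny, nz = shape
    Dg = np.asarray(D, dtype=np.float64).reshape(shape)
    W = np.zeros((nx, ny, nz, 6))

    def hmean(a, b):
        num = 2.0 * a * b
        den = a + b
        out = np.zeros_like(a)
        ok = (a > 0) & (b > 0)
        out[ok] = num[ok] / den[ok]
        return out

    W[1:, :, :, 0] = hmean(Dg[1:], Dg[:-1])
    W[:-1, :, :, 1] = hmean(Dg[:-1], Dg[1:])
    W[:, 1:, :, 2] = hmean(Dg[:, 1:], Dg[:, :-1])
    W[:, :-1, :, 3] = hmean(Dg[:, :-1], Dg[:, 1:])
    W[:, :, 1:, 4] = hmean(Dg[:, :, 1:], Dg[:, :, :-1])
    W[:, :, :-1, 5] = hmean(Dg[:, :, :-1], Dg[:, :, 1:])
    return np.ascontiguousarray(W.reshape(-1, 6) / (dx_mm * dx_mm))


@njit(cache=True, fastmath=True)
def _diffusion(V, W, nx, ny, nz, lap):
    """lap[n] = sum over faces of w_face * (V_nb - V_n) with precomputed
    face weights (already divided by dx^2)."""
    sy = nz
    sx = ny * nz
    n_tot = nx * ny * nz
    for n in range(n_tot):
        w = W[n]
        vn = V[n]
        acc = 0.0
        if w[0] > 0.0:
            acc += w[0] * (V[n - sx] - vn)
        if w[1] > 0.0:
            acc += w[1] * (V[n + sx] - vn)
        if w[2] > 0.0:
            acc += w[2] * (V[n - sy] - vn)
        if w[3] > 0.0:
            acc += w[3] * (V[n + sy] - vn)
        if nz > 1:
            if w[4] > 0.0:
                acc += w[4] * (V[n - 1] - vn)
            if w[5] > 0.0:
                acc += w[5] * (V[n + 1] - vn)
        lap[n] = acc


@njit(cache=True, fastmath=True)
def run_tissue(V, S, gna, gkr, gks, gto, active, W, nx, ny, nz,
               dt, n_steps, stim_nodes, stim_starts, stim_dur, stim_amp,
               tab, k1tab, at_mv, rt_mv,
               up_times, up_counts, dn_times, dn_counts,
               rec_nodes, rec_every, rec_buf, rec_t):
    """Advance the tissue ``n_steps`` steps of size ``dt`` (ms).

    Returns the failing step index on numerical blow-up (|V| > 200 mV),
    else -1. Event buffers ``up_times``/``dn_times`` have a fixed
    per-node capacity; surplus crossings are dropped (counts keep
    incrementing so overflow is detectable).

    ``rec_nodes``/``rec_every``/``rec_buf`` optionally store decimated V
    snapshots for a subset of nodes (``rec_every`` = 0 disables).
    """
    n = V.shape[0]
    lap = np.zeros(n)
    vprev = np.empty(n)
    istim = np.zeros(n)
    erev = np.zeros((n, 4))
    refresh_every = max(1, int(round(1.0 / dt)))
    cap_up = up_times.shape[1]
    cap_dn = dn_times.shape[1]
    n_rec = 0
    if rec_every > 0:
        for k in range(rec_nodes.shape[0]):
            rec_buf[0, k] = V[rec_nodes[k]]
        rec_t[0] = 0.0
        n_rec = 1

    for step in range(n_steps):
        t = step * dt
        for k in range(n):
            vprev[k] = V[k]

        _diffusion(V, W, nx, ny, nz, lap)
        for k in range(n):
            V[k] += dt * lap[k]

        stim_on = False
        for s0 in stim_starts:
            if s0 <= t < s0 + stim_dur:
                stim_on = True
                break
        if stim_on:
            for k in stim_nodes:
                istim[k] = -stim_amp
        vm = ionic_pass(V, S, gna, gkr, gks, gto, dt, tab, k1tab, istim,
                        active, erev, step % refresh_every == 0)
        if stim_on:
            for k in stim_nodes:
                istim[k] = 0.0
        if vm > 200.0 or np.isnan(vm):
            return step

        for k in range(n):
            if not active[k]:
                continue
            v0 = vprev[k]
            v1 = V[k]
            if v0 < at_mv <= v1:
                c = up_counts[k]
                if c < cap_up:
                    up_times[k, c] = t + dt * (at_mv - v0) / (v1 - v0)
                up_counts[k] = c + 1
            if v0 > rt_mv >= v1:
                c = dn_counts[k]
                if c < cap_dn:
                    dn_times[k, c] = t + dt * (rt_mv - v0) / (v1 - v0)
                dn_counts[k] = c + 1

        if rec_every > 0 and (step + 1) % rec_every == 0:
            if n_rec < rec_buf.shape[0]:
                for k in range(rec_nodes.shape[0]):
                    rec_buf[n_rec, k] = V[rec_nodes[k]]
                rec_t[n_rec] = t + dt
                n_rec += 1
    return -1
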