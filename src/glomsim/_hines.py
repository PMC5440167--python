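"""Numba core: backward-Euler integration on a compartmental tree.

The linear system at every step is tree-structured (symmetric, one
off-diagonal per child compartment), so it is solved exactly in O(n) with
Hines-ordered elimination: children are eliminated into their parents from
the leaves upward, then voltages are back-substituted from the root down.
Compartments must be topologically ordered (parent index < child index),
which the remesher guarantees.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def integrate(
    parent,      # (n,) int64, -1 at root compartment
    g_ax,        # (n,) float64, axial conductance to parent, µS (g_ax[0] unused)
    g_leak,      # (n,) float64, membrane leak conductance, µS
    cap,         # (n,) float64, capacitance, nF
    dt,          # ms
    e_rest,      # mV
    e_syn,       # mV
    ev_comp,     # (m,) int64, compartment of each synaptic event
    ev_start,    # (m,) int64, onset step of each event
    ev_g,        # (m,) float64, peak conductance of each event, µS
    wave,        # (w,) float64, normalized conductance waveform sampled at dt
    inj_comp,    # int64, current-injection compartment (-1: none)
    inj_amp,     # float64, nA, step current switched on at t=0
    n_steps,     # int64
    rec_idx,     # (r,) int64, compartments to record
):
    n = parent.shape[0]
    m = ev_comp.shape[0]
    w = wave.shape[0]
    v = np.full(n, e_rest)
    d = np.empty(n)
    b = np.empty(n)
    out = np.empty((n_steps + 1, rec_idx.shape[0]))
    for r in range(rec_idx.shape[0]):
        out[0, r] = v[rec_idx[r]]

    for k in range(n_steps):
        for i in range(n):
            cdt = cap[i] / dt
            d[i] = cdt + g_leak[i]
            b[i] = cdt * v[i] + g_leak[i] * e_rest
        # synaptic conductances, evaluated at the step start
        for e in range(m):
            off = k - ev_start[e]
            if 0 <= off < w:
                g = ev_g[e] * wave[off]
                c = ev_comp[e]
                d[c] += g
                b[c] += g * e_syn
        if inj_comp >= 0:
            b[inj_comp] += inj_amp
        # axial coupling on the diagonal
        for i in range(1, n):
            d[i] += g_ax[i]
            d[parent[i]] += g_ax[i]
        # eliminate leaves upward
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / d[i]
            d[p] -= f * g_ax[i]
            b[p] += f * b[i]
        # back-substitute from the root down
        v[0] = b[0] / d[0]
        for i in range(1, n):
            v[i] = (b[i] + g_ax[i] * v[parent[i]]) / d[i]
        for r in range(rec_idx.shape[0]):
            out[k + 1, r] = v[rec_idx[r]]
    return out
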