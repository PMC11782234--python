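"""Numba-compiled adaptive integrator for the coupled cell network.

Implements a Bogacki--Shampine 3(2) embedded Runge--Kutta pair (the same
family as MATLAB's ode23) with proportional step-size control, FSAL reuse,
inline detection of upstroke events (upward threshold crossings with a
per-cell re-arm interval) and optional fixed-interval trajectory sampling.

The integrator is called segment-by-segment by :mod:`avnode.engine`; a
segment is an interval of constant gamma and constant stimulus currents,
so all discontinuities fall on segment boundaries and the error estimate
is never polluted by a switching instant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Status codes returned by integrate_segment
OK = 0
STEP_UNDERFLOW = 1
DIVERGED = 2

_SAFETY = 0.9
_MIN_FAC = 0.1
_MAX_FAC = 5.0
_H_FLOOR = 1e-10
_V_DIVERGE = 10.0


@njit(cache=True)
def rhs(V, r, a1, a2, k, c, eps0, mu1, mu2, gmask, gamma, inv_ts,
        lfrom, lto, ld, lbeta, I_ext, dV, dr):
    """dV/dt, dr/dt in milliseconds for the whole network (in place)."""
    n = V.shape[0]
    for i in range(n):
        dV[i] = 0.0
    for l in range(lfrom.shape[0]):
        u = lfrom[l]
        v = lto[l]
        cur = ld[l] * (V[u] - lbeta[l] * V[v])
        dV[v] += cur
        dV[u] -= cur
    for i in range(n):
        g = gamma if gmask[i] else 1.0
        m1 = mu1[i] / g
        m2 = mu2[i] * g
        Vi = V[i]
        ri = r[i]
        dVi = c[i] * (k[i] * Vi * (Vi - a1[i]) * (1.0 - Vi) - ri * Vi)
        den = Vi + m2
        if den < 1e-9:
            den = 1e-9
        eps = eps0[i] + ri * m1 / den
        dri = c[i] * eps * (-ri - k[i] * Vi * (Vi - a2[i] - 1.0))
        dV[i] = (dV[i] + dVi + I_ext[i]) * inv_ts
        dr[i] = dri * inv_ts


@njit(cache=True)
def integrate_segment(t0, t1, V, r,
                      a1, a2, k, c, eps0, mu1, mu2, gmask, gamma, inv_ts,
                      lfrom, lto, ld, lbeta, I_ext,
                      rtol, atol, max_step, thresh, rearm,
                      last_ev, ev_cell, ev_time, n_ev,
                      rec_dt, rec_t0, rec_V, rec_r, n_rec):
    """Integrate one constant-(gamma, stimulus) segment.

    Events are appended to ``ev_cell``/``ev_time`` (count returned).  If
    ``rec_dt > 0``, V and r are sampled on the global grid
    ``rec_t0 + j * rec_dt`` by linear interpolation within accepted steps.
    Returns (status, n_ev, n_rec).
    """
    n = V.shape[0]
    dV1 = np.empty(n); dr1 = np.empty(n)
    dV2 = np.empty(n); dr2 = np.empty(n)
    dV3 = np.empty(n); dr3 = np.empty(n)
    dV4 = np.empty(n); dr4 = np.empty(n)
    Vt = np.empty(n); rt = np.empty(n)
    Ve = np.empty(n); re_ = np.empty(n)

    t = t0
    h = min(max_step, t1 - t0)
    rhs(V, r, a1, a2, k, c, eps0, mu1, mu2, gmask, gamma, inv_ts,
        lfrom, lto, ld, lbeta, I_ext, dV1, dr1)
    while t < t1 - 1e-12:
        if h > t1 - t:
            h = t1 - t
        for i in range(n):
            Vt[i] = V[i] + 0.5 * h * dV1[i]
            rt[i] = r[i] + 0.5 * h * dr1[i]
        rhs(Vt, rt, a1, a2, k, c, eps0, mu1, mu2, gmask, gamma, inv_ts,
            lfrom, lto, ld, lbeta, I_ext, dV2, dr2)
        for i in range(n):
            Vt[i] = V[i] + 0.75 * h * dV2[i]
            rt[i] = r[i] + 0.75 * h * dr2[i]
        rhs(Vt, rt, a1, a2, k, c, eps0, mu1, mu2, gmask, gamma, inv_ts,
            lfrom, lto, ld, lbeta, I_ext, dV3, dr3)
        for i in range(n):
            Ve[i] = V[i] + h * (2.0 / 9.0 * dV1[i] + 1.0 / 3.0 * dV2[i] + 4.0 / 9.0 * dV3[i])
            re_[i] = r[i] + h * (2.0 / 9.0 * dr1[i] + 1.0 / 3.0 * dr2[i] + 4.0 / 9.0 * dr3[i])
        rhs(Ve, re_, a1, a2, k, c, eps0, mu1, mu2, gmask, gamma, inv_ts,
            lfrom, lto, ld, lbeta, I_ext, dV4, dr4)
        err = 0.0
        for i in range(n):
            eV = h * ((2.0 / 9.0 - 7.0 / 24.0) * dV1[i] + (1.0 / 3.0 - 0.25) * dV2[i]
                      + (4.0 / 9.0 - 1.0 / 3.0) * dV3[i] - 0.125 * dV4[i])
            er = h * ((2.0 / 9.0 - 7.0 / 24.0) * dr1[i] + (1.0 / 3.0 - 0.25) * dr2[i]
                      + (4.0 / 9.0 - 1.0 / 3.0) * dr3[i] - 0.125 * dr4[i])
            sV = atol + rtol * max(abs(V[i]), abs(Ve[i]))
            sr = atol + rtol * max(abs(r[i]), abs(re_[i]))
            e1 = abs(eV) / sV
            e2 = abs(er) / sr
            if e1 > err:
                err = e1
            if e2 > err:
                err = e2
        if err <= 1.0:
            tn = t + h
            for i in range(n):
                if V[i] < thresh and Ve[i] >= thresh:
                    tc = t + h * (thresh - V[i]) / (Ve[i] - V[i])
                    if tc - last_ev[i] > rearm:
                        ev_cell[n_ev] = i
                        ev_time[n_ev] = tc
                        n_ev += 1
                        last_ev[i] = tc
                if abs(Ve[i]) > _V_DIVERGE:
                    return DIVERGED, n_ev, n_rec
            if rec_dt > 0.0:
                j = n_rec
                ts = rec_t0 + j * rec_dt
                while ts <= tn + 1e-12 and j < rec_V.shape[1]:
                    w = (ts - t) / h if h > 0 else 0.0
                    for i in range(n):
                        rec_V[i, j] = V[i] + w * (Ve[i] - V[i])
                        rec_r[i, j] = r[i] + w * (re_[i] - r[i])
                    j += 1
                    ts = rec_t0 + j * rec_dt
                n_rec = j
            for i in range(n):
                V[i] = Ve[i]
                r[i] = re_[i]
                dV1[i] = dV4[i]
                dr1[i] = dr4[i]
            t = tn
        if err == 0.0:
            fac = _MAX_FAC
        else:
            fac = _SAFETY * err ** (-1.0 / 3.0)
            if fac > _MAX_FAC:
                fac = _MAX_FAC
            if fac < _MIN_FAC:
                fac = _MIN_FAC
        h *= fac
        if h > max_step:
            h = max_step
        if h < _H_FLOOR:
            return STEP_UNDERFLOW, n_ev, n_rec
    return OK, n_ev, n_rec
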