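"""Numba kernels for deterministic integration and Gillespie simulation.

One generic compiled kernel serves every network via the dense array
encoding of :class:`procdesign.network.CompiledNetwork`; compilation
happens once per process and is cached on disk.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes shared by both kernels
OK = 0
DIVERGED = 1
MAXSTEP = 2
STATE_CAP = 3


@njit(cache=True, fastmath=True, inline="always")
def _pow(x, n):
    # integer exponents (the usual Hill case) via repeated squaring
    ni = int(n)
    if ni == n and 0 <= ni <= 64:
        acc = 1.0
        base = x
        while ni > 0:
            if ni & 1:
                acc *= base
            base *= base
            ni >>= 1
        return acc
    return x**n


@njit(cache=True, fastmath=True)
def _rhs(y, p, Kn, in_ptr, in_sp, in_st, stoich, kind, kidx, nidx, subidx, catidx, out):
    n_r, n_s = stoich.shape
    for i in range(n_s):
        out[i] = 0.0
    for j in range(n_r):
        if kind[j] == 0:
            r = p[kidx[j]]
            for m in range(in_ptr[j], in_ptr[j + 1]):
                x = y[in_sp[m]]
                if x < 0.0:
                    x = 0.0
                for _ in range(in_st[m]):
                    r *= x
        else:
            cat = y[catidx[j]]
            sub = y[subidx[j]]
            if cat < 0.0:
                cat = 0.0
            if sub < 0.0:
                sub = 0.0
            cp = _pow(cat, p[nidx[j]])
            r = p[kidx[j]] * sub * cp / (Kn[j] + cp)
        for i in range(n_s):
            s = stoich[j, i]
            if s != 0.0:
                out[i] += s * r
    return out


@njit(cache=True)
def rk45_integrate(
    y0,
    t_grid,
    p,
    in_ptr,
    in_sp,
    in_st,
    stoich,
    kind,
    kidx,
    nidx,
    subidx,
    catidx,
    Kn,
    rtol,
    atol,
    max_steps,
    out,
):
    """Adaptive Dormand–Prince 5(4) integration, sampled exactly at
    ``t_grid`` (which must start at the initial time).  Fills ``out``
    (n_species x n_grid) and returns (status, y_final)."""
    n_s = y0.shape[0]
    n_t = t_grid.shape[0]
    y = y0.copy()
    t = t_grid[0]
    out[:, 0] = y
    gi = 1

    k1 = np.empty(n_s)
    k2 = np.empty(n_s)
    k3 = np.empty(n_s)
    k4 = np.empty(n_s)
    k5 = np.empty(n_s)
    k6 = np.empty(n_s)
    k7 = np.empty(n_s)
    ytmp = np.empty(n_s)
    y5 = np.empty(n_s)

    _rhs(y, p, Kn, in_ptr, in_sp, in_st, stoich, kind, kidx, nidx, subidx, catidx, k1)
    t_end = t_grid[n_t - 1]
    h = (t_end - t) * 1e-4
    if h <= 0.0:
        return OK, y
    steps = 0
    while gi < n_t:
        if steps >= max_steps:
            return MAXSTEP, y
        steps += 1
        target = t_grid[gi]
        if t + h >= target:
            h_use = target - t
            hit = True
        else:
            h_use = h
            hit = False
        if h_use <= 0.0:
            h_use = 1e-14

        for i in range(n_s):
            ytmp[i] = y[i] + h_use * (0.2 * k1[i])
        _rhs(ytmp, p, Kn, in_ptr, in_sp, in_st, stoich, kind, kidx, nidx, subidx, catidx, k2)
        for i in range(n_s):
            ytmp[i] = y[i] + h_use * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs(ytmp, p, Kn, in_ptr, in_sp, in_st, stoich, kind, kidx, nidx, subidx, catidx, k3)
        for i in range(n_s):
            ytmp[i] = y[i] + h_use * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i])
        _rhs(ytmp, p, Kn, in_ptr, in_sp, in_st, stoich, kind, kidx, nidx, subidx, catidx, k4)
        for i in range(n_s):
            ytmp[i] = y[i] + h_use * (
                19372.0 / 6561.0 * k1[i]
                - 25360.0 / 2187.0 * k2[i]
                + 64448.0 / 6561.0 * k3[i]
                - 212.0 / 729.0 * k4[i]
            )
        _rhs(ytmp, p, Kn, in_ptr, in_sp, in_st, stoich, kind, kidx, nidx, subidx, catidx, k5)
        for i in range(n_s):
            ytmp[i] = y[i] + h_use * (
                9017.0 / 3168.0 * k1[i]
                - 355.0 / 33.0 * k2[i]
                + 46732.0 / 5247.0 * k3[i]
                + 49.0 / 176.0 * k4[i]
                - 5103.0 / 18656.0 * k5[i]
            )
        _rhs(ytmp, p, Kn, in_ptr, in_sp, in_st, stoich, kind, kidx, nidx, subidx, catidx, k6)
        for i in range(n_s):
            y5[i] = y[i] + h_use * (
                35.0 / 384.0 * k1[i]
                + 500.0 / 1113.0 * k3[i]
                + 125.0 / 192.0 * k4[i]
                - 2187.0 / 6784.0 * k5[i]
                + 11.0 / 84.0 * k6[i]
            )
        _rhs(y5, p, Kn, in_ptr, in_sp, in_st, stoich, kind, kidx, nidx, subidx, catidx, k7)

        # embedded 4th-order error estimate
        err = 0.0
        for i in range(n_s):
            y4i = y[i] + h_use * (
                5179.0 / 57600.0 * k1[i]
                + 7571.0 / 16695.0 * k3[i]
                + 393.0 / 640.0 * k4[i]
                - 92097.0 / 339200.0 * k5[i]
                + 187.0 / 2100.0 * k6[i]
                + 1.0 / 40.0 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = (y5[i] - y4i) / sc
            err += e * e
        err = (err / n_s) ** 0.5
        if not np.isfinite(err):
            return DIVERGED, y

        if err <= 1.0:
            t = t + h_use
            for i in range(n_s):
                y[i] = y5[i]
                k1[i] = k7[i]  # FSAL
                if abs(y[i]) > 1e9:
                    return DIVERGED, y
            if hit:
                out[:, gi] = y
                gi += 1
        fac = 0.9 * (err + 1e-16) ** -0.2
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h = h_use * fac
        if h < 1e-12:
            return DIVERGED, y
    return OK, y


@njit(cache=True)
def ssa_ensemble(
    counts0,
    t_start,
    t_grid,
    p,
    in_ptr,
    in_sp,
    in_st,
    stoich_int,
    kidx,
    ev_t,
    ev_sp,
    ev_amt,
    ev_set,
    seeds,
    max_total,
    max_events,
    sum_out,
):
    """Gillespie direct method, ensemble of ``len(seeds)`` realizations.

    Trajectories are right-continuous piecewise-constant, sampled at
    ``t_grid``; ``sum_out`` (n_species x n_grid) accumulates the sum over
    successful realizations.  Returns the number of failed realizations
    (state cap or event budget exceeded)."""
    n_r = stoich_int.shape[0]
    n_s = stoich_int.shape[1]
    n_t = t_grid.shape[0]
    n_ev = ev_t.shape[0]
    a = np.empty(n_r)
    traj = np.empty((n_s, n_t))
    n_failed = 0

    for ridx in range(seeds.shape[0]):
        np.random.seed(seeds[ridx])
        counts = counts0.copy()
        t = t_start
        gi = 0
        ei = 0
        events = 0
        failed = False
        # events scheduled at the start apply before the first sample
        while ei < n_ev and ev_t[ei] <= t:
            if ev_set[ei]:
                counts[ev_sp[ei]] = ev_amt[ei]
            else:
                counts[ev_sp[ei]] += ev_amt[ei]
            ei += 1
        while gi < n_t:
            a0 = 0.0
            for j in range(n_r):
                v = p[kidx[j]]
                for m in range(in_ptr[j], in_ptr[j + 1]):
                    n = counts[in_sp[m]]
                    s = in_st[m]
                    for q in range(s):
                        v *= (n - q) / (q + 1.0)
                if v < 0.0:
                    v = 0.0
                a[j] = v
                a0 += v
            if a0 <= 0.0:
                t_next = np.inf
            else:
                u = np.random.random()
                while u <= 0.0:
                    u = np.random.random()
                t_next = t + (-np.log(u)) / a0
            if ei < n_ev and ev_t[ei] < t_next:
                while gi < n_t and t_grid[gi] < ev_t[ei]:
                    traj[:, gi] = counts
                    gi += 1
                t = ev_t[ei]
                if ev_set[ei]:
                    counts[ev_sp[ei]] = ev_amt[ei]
                else:
                    counts[ev_sp[ei]] += ev_amt[ei]
                ei += 1
                continue
            while gi < n_t and t_grid[gi] < t_next:
                traj[:, gi] = counts
                gi += 1
            if gi >= n_t:
                break
            # fire the chosen reaction at t_next
            u2 = np.random.random() * a0
            acc = 0.0
            jsel = n_r - 1
            for j in range(n_r):
                acc += a[j]
                if u2 < acc:
                    jsel = j
                    break
            total = 0
            for i in range(n_s):
                counts[i] += stoich_int[jsel, i]
                total += counts[i]
            t = t_next
            events += 1
            if total > max_total or events > max_events:
                failed = True
                break
        if failed:
            n_failed += 1
        else:
            for i in range(n_s):
                for g in range(n_t):
                    sum_out[i, g] += traj[i, g]
    return n_failed
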