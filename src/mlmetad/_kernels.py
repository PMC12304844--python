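"""Numba-jitted simulation kernels.

One unified kernel integrates BAOAB Langevin dynamics on the analytic
surfaces of :mod:`mlmetad.potentials`, optionally depositing well-tempered
metadynamics hills on 1--2 linear collective variables and stopping on a
committed first-passage event.

The bias inside the kernel is evaluated from a dense grid over the biased
variables, updated in place at every deposition (value grid plus exact
analytic gradient grids, linear interpolation in between).  Grid spacing is
chosen by the caller at a small fraction of the hill width, so the cached
bias agrees with the exact hill sum to well below the thermal energy.

Everything here is deterministic given the integer seed: the kernel seeds
numba's own ``np.random`` state and draws one Gaussian per degree of freedom
per step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stop modes
STOP_NONE = -1
STOP_ABOVE = 0
STOP_ABS_ABOVE = 1
STOP_BELOW = 2


@njit(cache=True)
def _grad(code, p, x, g):
    """Write dU/dx into g for position x; returns 0.0 (numba-friendly)."""
    dim = x.shape[0]
    for i in range(dim):
        g[i] = 0.0
    if code == 0:  # quartic double well + harmonic distractors
        a = p[0]
        kd = p[1]
        g[0] = 4.0 * a * x[0] * (x[0] * x[0] - 1.0)
        for i in range(1, dim):
            g[i] = kd * x[i]
    elif code == 2:  # 1-D polynomial, coefficients low -> high
        acc = 0.0
        xp = 1.0
        for j in range(1, p.shape[0]):
            acc += j * p[j] * xp
            xp *= x[0]
        g[0] = acc
    else:  # dissociation funnel
        xx = x[0]
        yy = x[1]
        gb = np.exp(-((xx - p[1]) ** 2 + (yy - p[2]) ** 2) / (2.0 * p[3] * p[3]))
        gi = np.exp(-((xx - p[5]) ** 2 + (yy - p[6]) ** 2) / (2.0 * p[7] * p[7]))
        ridge = np.exp(-((xx - p[9]) ** 2) / (2.0 * p[10] * p[10]))
        gate = np.exp(-((yy - p[11]) ** 2) / (2.0 * p[12] * p[12]))
        g[0] += p[0] * gb * (xx - p[1]) / (p[3] * p[3])
        g[1] += p[0] * gb * (yy - p[2]) / (p[3] * p[3])
        g[0] += p[4] * gi * (xx - p[5]) / (p[7] * p[7])
        g[1] += p[4] * gi * (yy - p[6]) / (p[7] * p[7])
        g[0] += -p[8] * (1.0 - gate) * ridge * (xx - p[9]) / (p[10] * p[10])
        g[1] += p[8] * ridge * gate * (yy - p[11]) / (p[12] * p[12])
        g[1] += p[13] * yy
        if xx > p[14]:
            g[0] += 4.0 * p[15] * (xx - p[14]) ** 3
        if xx < p[16]:
            g[0] += -4.0 * p[15] * (p[16] - xx) ** 3
        ay = abs(yy)
        if ay > p[25]:
            s = 1.0 if yy > 0.0 else -1.0
            g[1] += 4.0 * p[15] * s * (ay - p[25]) ** 3
        nd = int(p[18])
        for i in range(nd):
            g[2 + i] = p[17] * x[2 + i]
        if p[19] > 0.5:
            u = x[dim - 1]
            sw = 1.0 / (1.0 + np.exp(-(xx - p[23]) / p[24]))
            upref = p[21] - p[22] * sw
            g[dim - 1] += p[20] * (u - upref)
            g[0] += -p[20] * (u - upref) * (-p[22] * sw * (1.0 - sw) / p[24])
    return 0.0


@njit(cache=True, inline="always")
def _interp1(Vg, G0g, lo, inv_dx, n, s, out):
    """Linear interpolation of bias value and d/ds on a 1-D grid."""
    f = (s - lo) * inv_dx
    if f < 0.0:
        f = 0.0
    if f > n - 1.000001:
        f = n - 1.000001
    i = int(f)
    w = f - i
    out[0] = Vg[i] * (1.0 - w) + Vg[i + 1] * w
    out[1] = G0g[i] * (1.0 - w) + G0g[i + 1] * w


@njit(cache=True)
def simulate(code, pparams, x0, dt, friction, mass, kT,
             n_steps, stride, seed,
             bw, bmu, bsd,
             sigma, h0, gamma, pace_steps,
             grid_lo, grid_hi, grid_n, Vg, G0g, G1g,
             stop_w, stop_mu, stop_sd, stop_cutoff, stop_mode, commit_m):
    """Integrate Langevin dynamics with optional WT-MetaD bias.

    Returns (n_frames, times, frames, bias_frames, n_hills, hill_steps,
    hill_centers, hill_heights, hill_bias_at, event, event_step, err_step);
    ``err_step >= 0`` flags a non-finite position/force at that step.
    """
    np.random.seed(seed)
    dim = x0.shape[0]
    nb = bw.shape[0]

    x = x0.copy()
    v = np.zeros(dim)
    g = np.zeros(dim)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sig_v = np.sqrt(kT / mass)

    n_frames_max = n_steps // stride + 1
    times = np.zeros(n_frames_max)
    frames = np.zeros((n_frames_max, dim))
    bias_frames = np.zeros(n_frames_max)
    n_frames = 0

    max_hills = (n_steps // pace_steps + 1) if (nb > 0 and pace_steps > 0) else 0
    hill_steps = np.zeros(max_hills, dtype=np.int64)
    hill_centers = np.zeros((max_hills, nb if nb > 0 else 1))
    hill_heights = np.zeros(max_hills)
    hill_bias_at = np.zeros(max_hills)
    n_hills = 0

    # bias grids (flattened for nb == 2) are provided by the caller so that
    # pre-deposited (static) bias and restarts are possible
    n0 = grid_n[0] if nb > 0 else 1
    n1 = grid_n[1] if nb == 2 else 1
    inv_dx0 = (n0 - 1) / (grid_hi[0] - grid_lo[0]) if nb > 0 else 0.0
    inv_dx1 = (n1 - 1) / (grid_hi[1] - grid_lo[1]) if nb == 2 else 0.0

    s = np.zeros(nb if nb > 0 else 1)
    o1 = np.zeros(2)

    event = False
    event_step = np.int64(-1)
    consec = 0

    _grad(code, pparams, x, g)

    for step in range(n_steps + 1):
        # biased-variable values and cached bias at current position
        Vb = 0.0
        f0 = 0.0
        f1 = 0.0
        if nb > 0:
            for k in range(nb):
                acc = 0.0
                for j in range(dim):
                    acc += bw[k, j] * x[j]
                s[k] = (acc - bmu[k]) / bsd[k]
            if nb == 1:
                _interp1(Vg, G0g, grid_lo[0], inv_dx0, n0, s[0], o1)
                Vb = o1[0]
                f0 = o1[1]
            else:
                fa = (s[0] - grid_lo[0]) * inv_dx0
                fb = (s[1] - grid_lo[1]) * inv_dx1
                if fa < 0.0:
                    fa = 0.0
                if fa > n0 - 1.000001:
                    fa = n0 - 1.000001
                if fb < 0.0:
                    fb = 0.0
                if fb > n1 - 1.000001:
                    fb = n1 - 1.000001
                ia = int(fa)
                ib = int(fb)
                wa = fa - ia
                wb = fb - ib
                i00 = ia * n1 + ib
                i01 = i00 + 1
                i10 = i00 + n1
                i11 = i10 + 1
                w00 = (1.0 - wa) * (1.0 - wb)
                w01 = (1.0 - wa) * wb
                w10 = wa * (1.0 - wb)
                w11 = wa * wb
                Vb = Vg[i00] * w00 + Vg[i01] * w01 + Vg[i10] * w10 + Vg[i11] * w11
                f0 = G0g[i00] * w00 + G0g[i01] * w01 + G0g[i10] * w10 + G0g[i11] * w11
                f1 = G1g[i00] * w00 + G1g[i01] * w01 + G1g[i10] * w10 + G1g[i11] * w11

        if step % stride == 0:
            times[n_frames] = step * dt
            for j in range(dim):
                frames[n_frames, j] = x[j]
            bias_frames[n_frames] = Vb
            n_frames += 1

        # well-tempered deposition (bias recorded above precedes the deposit)
        if nb > 0 and pace_steps > 0 and step > 0 and step % pace_steps == 0:
            h = h0 * np.exp(-Vb / ((gamma - 1.0) * kT))
            hill_steps[n_hills] = step
            for k in range(nb):
                hill_centers[n_hills, k] = s[k]
            hill_heights[n_hills] = h
            hill_bias_at[n_hills] = Vb
            n_hills += 1
            # add the Gaussian to the cached grids over a +/-6 sigma window
            if nb == 1:
                sg = sigma[0]
                lo_i = int((s[0] - 6.0 * sg - grid_lo[0]) * inv_dx0)
                hi_i = int((s[0] + 6.0 * sg - grid_lo[0]) * inv_dx0) + 1
                if lo_i < 0:
                    lo_i = 0
                if hi_i > n0 - 1:
                    hi_i = n0 - 1
                for i in range(lo_i, hi_i + 1):
                    node = grid_lo[0] + i / inv_dx0
                    d0 = node - s[0]
                    e = h * np.exp(-d0 * d0 / (2.0 * sg * sg))
                    Vg[i] += e
                    G0g[i] += -e * d0 / (sg * sg)
            else:
                sg0 = sigma[0]
                sg1 = sigma[1]
                lo_a = int((s[0] - 6.0 * sg0 - grid_lo[0]) * inv_dx0)
                hi_a = int((s[0] + 6.0 * sg0 - grid_lo[0]) * inv_dx0) + 1
                lo_b = int((s[1] - 6.0 * sg1 - grid_lo[1]) * inv_dx1)
                hi_b = int((s[1] + 6.0 * sg1 - grid_lo[1]) * inv_dx1) + 1
                if lo_a < 0:
                    lo_a = 0
                if hi_a > n0 - 1:
                    hi_a = n0 - 1
                if lo_b < 0:
                    lo_b = 0
                if hi_b > n1 - 1:
                    hi_b = n1 - 1
                for ia in range(lo_a, hi_a + 1):
                    na = grid_lo[0] + ia / inv_dx0
                    d0 = na - s[0]
                    ea = np.exp(-d0 * d0 / (2.0 * sg0 * sg0))
                    for ib in range(lo_b, hi_b + 1):
                        nbv = grid_lo[1] + ib / inv_dx1
                        d1 = nbv - s[1]
                        e = h * ea * np.exp(-d1 * d1 / (2.0 * sg1 * sg1))
                        idx = ia * n1 + ib
                        Vg[idx] += e
                        G0g[idx] += -e * d0 / (sg0 * sg0)
                        G1g[idx] += -e * d1 / (sg1 * sg1)

        # committed first-passage check
        if stop_mode >= 0:
            acc = 0.0
            for j in range(dim):
                acc += stop_w[j] * x[j]
            sv = (acc - stop_mu) / stop_sd
            hit = False
            if stop_mode == 0:
                hit = sv > stop_cutoff
            elif stop_mode == 1:
                hit = abs(sv) > stop_cutoff
            else:
                hit = sv < stop_cutoff
            if hit:
                consec += 1
                if consec >= commit_m:
                    event = True
                    event_step = np.int64(step - commit_m + 1)
                    break
            else:
                consec = 0

        if step == n_steps:
            break

        # BAOAB step
        for j in range(dim):
            v[j] += 0.5 * dt * (-(g[j]) / mass)
        if nb > 0:
            # chain rule: dV/dx_j = sum_k (dV/ds_k) w_kj / bsd_k
            for j in range(dim):
                fb_j = f0 * bw[0, j] / bsd[0]
                if nb == 2:
                    fb_j += f1 * bw[1, j] / bsd[1]
                v[j] += 0.5 * dt * (-(fb_j) / mass)
        for j in range(dim):
            x[j] += 0.5 * dt * v[j]
            v[j] = c1 * v[j] + c2 * sig_v * np.random.normal()
            x[j] += 0.5 * dt * v[j]
        _grad(code, pparams, x, g)
        if nb > 0:
            for k in range(nb):
                acc = 0.0
                for j in range(dim):
                    acc += bw[k, j] * x[j]
                s[k] = (acc - bmu[k]) / bsd[k]
            if nb == 1:
                _interp1(Vg, G0g, grid_lo[0], inv_dx0, n0, s[0], o1)
                f0 = o1[1]
                f1 = 0.0
            else:
                fa = (s[0] - grid_lo[0]) * inv_dx0
                fb = (s[1] - grid_lo[1]) * inv_dx1
                if fa < 0.0:
                    fa = 0.0
                if fa > n0 - 1.000001:
                    fa = n0 - 1.000001
                if fb < 0.0:
                    fb = 0.0
                if fb > n1 - 1.000001:
                    fb = n1 - 1.000001
                ia = int(fa)
                ib = int(fb)
                wa = fa - ia
                wb = fb - ib
                i00 = ia * n1 + ib
                i01 = i00 + 1
                i10 = i00 + n1
                i11 = i10 + 1
                f0 = (G0g[i00] * (1.0 - wa) * (1.0 - wb) + G0g[i01] * (1.0 - wa) * wb
                      + G0g[i10] * wa * (1.0 - wb) + G0g[i11] * wa * wb)
                f1 = (G1g[i00] * (1.0 - wa) * (1.0 - wb) + G1g[i01] * (1.0 - wa) * wb
                      + G1g[i10] * wa * (1.0 - wb) + G1g[i11] * wa * wb)
        for j in range(dim):
            v[j] += 0.5 * dt * (-(g[j]) / mass)
        if nb > 0:
            for j in range(dim):
                fb_j = f0 * bw[0, j] / bsd[0]
                if nb == 2:
                    fb_j += f1 * bw[1, j] / bsd[1]
                v[j] += 0.5 * dt * (-(fb_j) / mass)
        bad = False
        for j in range(dim):
            if not np.isfinite(x[j]) or not np.isfinite(g[j]):
                bad = True
        if bad:
            err_step = np.int64(step + 1)
            return (n_frames, times, frames, bias_frames,
                    n_hills, hill_steps, hill_centers, hill_heights,
                    hill_bias_at, event, event_step, err_step)

    err_step = np.int64(-1)
    return (n_frames, times, frames, bias_frames,
            n_hills, hill_steps, hill_centers, hill_heights, hill_bias_at,
            event, event_step, err_step)
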