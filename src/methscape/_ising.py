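"""Numba kernels for the 1D Ising methylation chain.

The joint distribution over the methylation states x_n in {0,1} of the N CpGs
of a window, written on +/-1 spins s_n = 2 x_n - 1, is

    P(s) = (1/Z) exp( sum_n a_n s_n + sum_n c_n s_n s_{n+1} )

with per-site field a_n = alpha + beta * rho_n (rho = local CpG density) and
pair coupling c_n = gamma * w_n (w = inverse-distance weight).  All kernels
use per-step renormalized transfer-matrix messages so that arbitrarily strong
fields/couplings stay in range.

Spin index convention inside kernels: 0 -> s = -1 (unmethylated),
1 -> s = +1 (methylated).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SPIN = np.array([-1.0, 1.0])


@njit(cache=True)
def forward_messages(a, c):
    """Normalized forward messages.

    Returns (fhat, logscale, lpre) where fhat[n, i] is the forward message at
    site n including the field of site n, normalized to sum 1; logscale[n] is
    the accumulated log normalizer (so logZ = logscale[N-1]); lpre[n, i] is
    the log of the prefix message flowing into site n *excluding* site n's
    field (lpre[0] = 0).
    """
    n = a.shape[0]
    fhat = np.empty((n, 2))
    logscale = np.empty(n)
    lpre = np.zeros((n, 2))
    e0 = np.exp(-a[0])
    e1 = np.exp(a[0])
    s = e0 + e1
    fhat[0, 0] = e0 / s
    fhat[0, 1] = e1 / s
    logscale[0] = np.log(s)
    for m in range(1, n):
        # incoming message excluding field at m
        in0 = fhat[m - 1, 0] * np.exp(c[m - 1]) + fhat[m - 1, 1] * np.exp(-c[m - 1])
        in1 = fhat[m - 1, 0] * np.exp(-c[m - 1]) + fhat[m - 1, 1] * np.exp(c[m - 1])
        lpre[m, 0] = np.log(in0) + logscale[m - 1]
        lpre[m, 1] = np.log(in1) + logscale[m - 1]
        f0 = in0 * np.exp(-a[m])
        f1 = in1 * np.exp(a[m])
        s = f0 + f1
        fhat[m, 0] = f0 / s
        fhat[m, 1] = f1 / s
        logscale[m] = logscale[m - 1] + np.log(s)
    return fhat, logscale, lpre


@njit(cache=True)
def backward_messages(a, c):
    """Normalized backward messages; rpost[n, i] is the log suffix message
    leaving site n toward the right, excluding site n's field
    (rpost[N-1] = 0)."""
    n = a.shape[0]
    bhat = np.empty((n, 2))
    logscale = np.empty(n)
    rpost = np.zeros((n, 2))
    e0 = np.exp(-a[n - 1])
    e1 = np.exp(a[n - 1])
    s = e0 + e1
    bhat[n - 1, 0] = e0 / s
    bhat[n - 1, 1] = e1 / s
    logscale[n - 1] = np.log(s)
    for m in range(n - 2, -1, -1):
        out0 = bhat[m + 1, 0] * np.exp(c[m]) + bhat[m + 1, 1] * np.exp(-c[m])
        out1 = bhat[m + 1, 0] * np.exp(-c[m]) + bhat[m + 1, 1] * np.exp(c[m])
        rpost[m, 0] = np.log(out0) + logscale[m + 1]
        rpost[m, 1] = np.log(out1) + logscale[m + 1]
        b0 = out0 * np.exp(-a[m])
        b1 = out1 * np.exp(a[m])
        s = b0 + b1
        bhat[m, 0] = b0 / s
        bhat[m, 1] = b1 / s
        logscale[m] = logscale[m + 1] + np.log(s)
    return bhat, logscale, rpost


@njit(cache=True)
def log_partition(a, c):
    _, logscale, _ = forward_messages(a, c)
    return logscale[a.shape[0] - 1]


@njit(cache=True)
def window_log_likelihood(a, c, read_starts, read_offsets, read_flat):
    """Sum over reads of log P(observed contiguous run), marginalizing the
    unobserved prefix and suffix of the chain by transfer-matrix messages."""
    n = a.shape[0]
    n_reads = read_starts.shape[0]
    if n_reads == 0:
        return 0.0
    _, logscale, lpre = forward_messages(a, c)
    _, _, rpost = backward_messages(a, c)
    log_z = logscale[n - 1]
    total = 0.0
    for r in range(n_reads):
        u = read_starts[r]
        lo = read_offsets[r]
        hi = read_offsets[r + 1]
        length = hi - lo
        first = read_flat[lo]
        last = read_flat[hi - 1]
        lp = lpre[u, first] + rpost[u + length - 1, last] - log_z
        for k in range(length):
            s = 2.0 * read_flat[lo + k] - 1.0
            lp += a[u + k] * s
            if k + 1 < length:
                s2 = 2.0 * read_flat[lo + k + 1] - 1.0
                lp += c[u + k] * s * s2
        total += lp
    return total


@njit(cache=True)
def level_count_distribution(a, c, lo, hi):
    """Exact distribution of the number of methylated CpGs among chain sites
    [lo, hi), marginalizing all other sites, by a forward DP over
    (spin, count) with per-step renormalization."""
    n = a.shape[0]
    m = hi - lo
    # F[i, k]: unnormalized joint of (s_n = spin i, count so far = k)
    f = np.zeros((2, m + 1))
    k0 = 1 if lo <= 0 < hi else 0
    f[0, 0] = np.exp(-a[0])
    f[1, k0] = np.exp(a[0])
    tot = f[0, 0] + f[1, k0]
    f /= tot
    for site in range(1, n):
        g = np.zeros((2, m + 1))
        in_region = lo <= site < hi
        ec = np.exp(c[site - 1])
        emc = np.exp(-c[site - 1])
        ea = np.exp(a[site])
        ema = np.exp(-a[site])
        for k in range(m + 1):
            f0, f1 = f[0, k], f[1, k]
            if f0 == 0.0 and f1 == 0.0:
                continue
            g[0, k] += (f0 * ec + f1 * emc) * ema
            k1 = k + 1 if in_region else k
            g[1, k1] += (f0 * emc + f1 * ec) * ea
        tot = g.sum()
        f = g / tot
    out = np.empty(m + 1)
    for k in range(m + 1):
        out[k] = f[0, k] + f[1, k]
    return out


@njit(cache=True)
def sample_chain(a, c, u):
    """Exact sample from the chain by forward-filter backward-sampling;
    ``u`` is a vector of N uniforms."""
    n = a.shape[0]
    fhat, _, _ = forward_messages(a, c)
    out = np.empty(n, dtype=np.int8)
    p1 = fhat[n - 1, 1]
    out[n - 1] = 1 if u[n - 1] < p1 else 0
    for m in range(n - 2, -1, -1):
        s_next = 2.0 * out[m + 1] - 1.0
        w0 = fhat[m, 0] * np.exp(-c[m] * s_next)
        w1 = fhat[m, 1] * np.exp(c[m] * s_next)
        p1 = w1 / (w0 + w1)
        out[m] = 1 if u[m] < p1 else 0
    return out


@njit(cache=True)
def _nll(theta, rho, w, read_starts, read_offsets, read_flat):
    a = theta[0] + theta[1] * rho
    c = theta[2] * w
    ll = window_log_likelihood(a, c, read_starts, read_offsets, read_flat)
    if not np.isfinite(ll):
        return 1.0e300
    return -ll


@njit(cache=True)
def nelder_mead_fit(
    x0,
    lb,
    ub,
    free_mask,
    rho,
    w,
    read_starts,
    read_offsets,
    read_flat,
    fatol,
    xatol,
    max_iter,
):
    """Bounded (projected) Nelder-Mead over the free coordinates of
    (alpha, beta, gamma).  Returns (theta_hat, best_nll, converged)."""
    ndim = 0
    for i in range(3):
        if free_mask[i]:
            ndim += 1
    idx = np.empty(ndim, dtype=np.int64)
    j = 0
    for i in range(3):
        if free_mask[i]:
            idx[j] = i
            j += 1

    theta = x0.copy()

    def clipped(full):
        out = full.copy()
        for i in range(3):
            if out[i] < lb[i]:
                out[i] = lb[i]
            if out[i] > ub[i]:
                out[i] = ub[i]
        return out

    if ndim == 0:
        t = clipped(theta)
        return t, _nll(t, rho, w, read_starts, read_offsets, read_flat), True

    # initial simplex
    npt = ndim + 1
    sim = np.empty((npt, ndim))
    fval = np.empty(npt)
    for k in range(npt):
        full = theta.copy()
        if k > 0:
            d = idx[k - 1]
            step = 0.25
            if full[d] + step > ub[d]:
                step = -0.25
            full[d] += step
        full = clipped(full)
        for q in range(ndim):
            sim[k, q] = full[idx[q]]
        fval[k] = _nll(full, rho, w, read_starts, read_offsets, read_flat)

    def eval_point(pt):
        full = theta.copy()
        for q in range(ndim):
            full[idx[q]] = pt[q]
        full = clipped(full)
        for q in range(ndim):
            pt[q] = full[idx[q]]
        return _nll(full, rho, w, read_starts, read_offsets, read_flat)

    converged = False
    for _ in range(max_iter):
        order = np.argsort(fval)
        sim = sim[order]
        fval = fval[order]
        spread = 0.0
        for k in range(1, npt):
            d = abs(fval[k] - fval[0])
            if d > spread:
                spread = d
        xspread = 0.0
        for k in range(1, npt):
            for q in range(ndim):
                dx = abs(sim[k, q] - sim[0, q])
                if dx > xspread:
                    xspread = dx
        if spread <= fatol and xspread <= xatol:
            converged = True
            break
        centroid = np.zeros(ndim)
        for k in range(npt - 1):
            for q in range(ndim):
                centroid[q] += sim[k, q] / (npt - 1)
        # reflection
        xr = centroid + (centroid - sim[npt - 1])
        fr = eval_point(xr)
        if fr < fval[0]:
            # expansion
            xe = centroid + 2.0 * (centroid - sim[npt - 1])
            fe = eval_point(xe)
            if fe < fr:
                sim[npt - 1] = xe
                fval[npt - 1] = fe
            else:
                sim[npt - 1] = xr
                fval[npt - 1] = fr
        elif fr < fval[npt - 2]:
            sim[npt - 1] = xr
            fval[npt - 1] = fr
        else:
            # contraction
            if fr < fval[npt - 1]:
                xc = centroid + 0.5 * (xr - centroid)
                fc = eval_point(xc)
                use = fc <= fr
            else:
                xc = centroid + 0.5 * (sim[npt - 1] - centroid)
                fc = eval_point(xc)
                use = fc < fval[npt - 1]
            if use:
                sim[npt - 1] = xc
                fval[npt - 1] = fc
            else:
                # shrink
                for k in range(1, npt):
                    for q in range(ndim):
                        sim[k, q] = sim[0, q] + 0.5 * (sim[k, q] - sim[0, q])
                    fval[k] = eval_point(sim[k])

    order = np.argsort(fval)
    best = sim[order[0]]
    out = theta.copy()
    for q in range(ndim):
        out[idx[q]] = best[q]
    out = clipped(out)
    return out, fval[order[0]], converged


@njit(cache=True)
def fit_window_multistart(
    starts3,
    lb,
    ub,
    free_mask,
    x_fixed,
    rho,
    w,
    read_starts,
    read_offsets,
    read_flat,
    fatol,
    xatol,
    max_iter,
):
    """Run Nelder-Mead from each row of ``starts3``; keep the best objective,
    breaking ties by lowest start index."""
    best_theta = np.zeros(3)
    best_nll = 1.0e301
    best_conv = False
    for s in range(starts3.shape[0]):
        x0 = starts3[s].copy()
        for i in range(3):
            if not free_mask[i]:
                x0[i] = x_fixed[i]
        theta, nll, conv = nelder_mead_fit(
            x0, lb, ub, free_mask, rho, w, read_starts, read_offsets, read_flat,
            fatol, xatol, max_iter,
        )
        if nll < best_nll - 1e-12:
            best_theta = theta
            best_nll = nll
            best_conv = conv
    return best_theta, best_nll, best_conv


@njit(cache=True)
def simulate_window_reads(a, c, n_reads, read_span, u_offsets, u_spins):
    """Sample ``n_reads`` contiguous-run reads from the window chain.

    Each read draws a full-chain configuration exactly from the Ising
    distribution and exposes ``read_span`` consecutive CpGs at a uniform
    random offset.  Returns (starts, states_flat, offsets).
    """
    n = a.shape[0]
    span = min(read_span, n)
    starts = np.empty(n_reads, dtype=np.int32)
    offsets = np.empty(n_reads + 1, dtype=np.int64)
    flat = np.empty(n_reads * span, dtype=np.int8)
    offsets[0] = 0
    for r in range(n_reads):
        config = sample_chain(a, c, u_spins[r])
        max_start = n - span
        st = int(u_offsets[r] * (max_start + 1))
        if st > max_start:
            st = max_start
        starts[r] = st
        for k in range(span):
            flat[r * span + k] = config[st + k]
        offsets[r + 1] = (r + 1) * span
    return starts, flat, offsets


def warmup():
    """Trigger JIT compilation of all kernels on a tiny problem."""
    a = np.array([0.1, -0.2, 0.3])
    c = np.array([0.05, -0.1])
    rs = np.array([0, 1], dtype=np.int32)
    ro = np.array([0, 2, 4], dtype=np.int64)
    rf = np.array([0, 1, 1, 0], dtype=np.int8)
    forward_messages(a, c)
    backward_messages(a, c)
    log_partition(a, c)
    window_log_likelihood(a, c, rs, ro, rf)
    level_count_distribution(a, c, 0, 2)
    sample_chain(a, c, np.array([0.3, 0.6, 0.9]))
    fit_window_multistart(
        np.zeros((1, 3)),
        np.array([-5.0, -20.0, -5.0]),
        np.array([5.0, 20.0, 5.0]),
        np.array([True, True, True]),
        np.zeros(3),
        np.array([0.1, 0.1, 0.1]),
        np.array([1.0, 1.0]),
        rs,
        ro,
        rf,
        1e-6,
        1e-4,
        5,
    )
    simulate_window_reads(
        a, c, 2, 2, np.array([0.2, 0.8]), np.random.default_rng(0).random((2, 3))
    )
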