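"""Compiled inner loop for atom scoring.

The t0/sigma refinement evaluates the atom–signal partial correlation
thousands of times per recording; this module provides a numba-compiled
scalar kernel for it.  The kernel only *scores* candidate parameters — the
final coefficient fit and the subtraction stay in the numpy path, so the
audit-trail reconstruction of the corrected signal is unaffected by
whether compilation is available.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(fn):
            return fn
        return wrap


@njit(cache=False, fastmath=False)
def refine_kernel(x: np.ndarray, fs: float, t0: float, sigma: float,
                  f: float, ksup: float, harmonic: bool,
                  step_fine: float, max_fine: int,
                  sig_step: float, sig_lo: float, sig_hi: float,
                  polish: bool):
    """Coarse-to-fine hill-climb of (t0, sigma) maximising the atom score.

    Mirrors the Python-level refinement: coarse t0 climb (5x the fine
    step), coarse sigma climb (4x the grid step), the fine t0 climb, and
    an optional fine sigma polish.  Returns (t0, sigma, score).
    """
    # coarse t0
    t0, score = _climb_t0_k(x, fs, t0, sigma, f, ksup, harmonic,
                            5.0 * step_fine, 25, -np.inf)
    # coarse sigma: full scan of the grid at 4x spacing (a directional
    # climb would stay inside whatever basin the seed landed in)
    cand = sig_lo
    while cand <= sig_hi:
        s = score_kernel(x, fs, t0, cand, f, ksup, harmonic)
        if s > score:
            sigma = cand
            score = s
        cand += 4.0 * sig_step
    # fine t0
    t0, score = _climb_t0_k(x, fs, t0, sigma, f, ksup, harmonic,
                            step_fine, max_fine, score)
    if polish:
        sigma, score = _climb_sig_k(x, fs, t0, sigma, f, ksup, harmonic,
                                    sig_step, 20, sig_lo, sig_hi, score)
        # the (t0, sigma) score surface has secondary basins (notably for
        # near-quadrature phases); probe a jump in each direction and
        # re-climb if it wins
        for fac in (0.7, 1.4):
            cand = sigma * fac
            if cand < sig_lo or cand > sig_hi:
                continue
            s = score_kernel(x, fs, t0, cand, f, ksup, harmonic)
            if s > score:
                sigma, score = _climb_sig_k(x, fs, t0, cand, f, ksup,
                                            harmonic, sig_step, 20,
                                            sig_lo, sig_hi, s)
                t0, score = _climb_t0_k(x, fs, t0, sigma, f, ksup, harmonic,
                                        step_fine, max_fine, score)
        # continuous parabolic refinement removes the grid-quantisation
        # residual (~2% envelope error would otherwise scale with A)
        for _ in range(2):
            sigma, score = _parab_k(x, fs, t0, sigma, f, ksup, harmonic,
                                    sig_step, sig_lo, sig_hi, score, False)
            t0, score = _parab_k(x, fs, t0, sigma, f, ksup, harmonic,
                                 step_fine, t0 - 1e-3, t0 + 1e-3, score, True)
    return t0, sigma, score


@njit(cache=False, fastmath=False)
def _parab_k(x, fs, t0, sigma, f, ksup, harmonic, step, lo, hi, score,
             vary_t0):
    """One parabolic-interpolation step on t0 or sigma."""
    if vary_t0:
        s_m = score_kernel(x, fs, t0 - step, sigma, f, ksup, harmonic)
        s_p = score_kernel(x, fs, t0 + step, sigma, f, ksup, harmonic)
    else:
        s_m = score_kernel(x, fs, t0, sigma - step, f, ksup, harmonic)
        s_p = score_kernel(x, fs, t0, sigma + step, f, ksup, harmonic)
    denom = s_m - 2.0 * score + s_p
    if denom >= 0.0 or not np.isfinite(denom):
        return (t0, score) if vary_t0 else (sigma, score)
    delta = 0.5 * step * (s_m - s_p) / denom
    if delta > step:
        delta = step
    elif delta < -step:
        delta = -step
    cand = (t0 + delta) if vary_t0 else (sigma + delta)
    if cand < lo or cand > hi:
        return (t0, score) if vary_t0 else (sigma, score)
    if vary_t0:
        s_c = score_kernel(x, fs, cand, sigma, f, ksup, harmonic)
        if s_c > score:
            return cand, s_c
        return t0, score
    s_c = score_kernel(x, fs, t0, cand, f, ksup, harmonic)
    if s_c > score:
        return cand, s_c
    return sigma, score


@njit(cache=False, fastmath=False)
def _climb_t0_k(x, fs, t0, sigma, f, ksup, harmonic, step, max_steps, score):
    if score == -np.inf:
        score = score_kernel(x, fs, t0, sigma, f, ksup, harmonic)
    direction = 0.0
    s_plus = score_kernel(x, fs, t0 + step, sigma, f, ksup, harmonic)
    if s_plus > score:
        direction = 1.0
    else:
        s_minus = score_kernel(x, fs, t0 - step, sigma, f, ksup, harmonic)
        if s_minus > score:
            direction = -1.0
    if direction != 0.0:
        for _ in range(max_steps):
            cand = t0 + direction * step
            s = score_kernel(x, fs, cand, sigma, f, ksup, harmonic)
            if s <= score:
                break
            t0 = cand
            score = s
    return t0, score


@njit(cache=False, fastmath=False)
def _climb_sig_k(x, fs, t0, sigma, f, ksup, harmonic, step, max_steps,
                 sig_lo, sig_hi, score):
    if score == -np.inf:
        score = score_kernel(x, fs, t0, sigma, f, ksup, harmonic)
    for d in (1.0, -1.0):
        improved = False
        for _ in range(max_steps):
            cand = sigma + d * step
            if cand < sig_lo or cand > sig_hi:
                break
            s = score_kernel(x, fs, t0, cand, f, ksup, harmonic)
            if s <= score:
                break
            sigma = cand
            score = s
            improved = True
        if improved:
            break
    return sigma, score


@njit(cache=False, fastmath=False)
def score_kernel(x: np.ndarray, fs: float, t0: float, sigma: float,
                 f: float, ksup: float, harmonic: bool) -> float:
    """Partial correlation of a quadrature Gabor atom given a quadratic trend.

    Evaluates the same statistic as the numpy scoring path: least squares
    of ``x[i0:i1]`` on [sin, cos] (x Gaussian; plus the 2f pair when
    *harmonic*) together with a quadratic baseline, returning
    sqrt((SSE_trend − SSE_full) / SSE_trend).  Returns −inf when the
    support window leaves the signal or the normal equations are singular.
    """
    i0 = int(np.round((t0 - ksup * sigma) * fs))
    i1 = int(np.round((t0 + ksup * sigma) * fs)) + 1
    if i0 < 0 or i1 > x.size or i1 - i0 < 5:
        return -np.inf
    n = i1 - i0
    na = 4 if harmonic else 2
    m = na + 3
    G = np.zeros((m, m))
    b = np.zeros(m)
    cols = np.empty(m)
    two_pi_f = 2.0 * np.pi * f
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    yy = 0.0
    for j in range(n):
        t = (i0 + j) / fs
        tau = t - t0
        env = np.exp(-tau * tau * inv2s2)
        ang = two_pi_f * tau
        s = np.sin(ang)
        c = np.cos(ang)
        cols[0] = s * env
        cols[1] = c * env
        if harmonic:
            cols[2] = 2.0 * s * c * env          # sin(2 ang)
            cols[3] = (c * c - s * s) * env      # cos(2 ang)
        tn = -1.0 + 2.0 * j / (n - 1)
        cols[na] = 1.0
        cols[na + 1] = tn
        cols[na + 2] = tn * tn
        y = x[i0 + j]
        yy += y * y
        for p in range(m):
            b[p] += cols[p] * y
            for q in range(p, m):
                G[p, q] += cols[p] * cols[q]
    for p in range(m):
        for q in range(p + 1, m):
            G[q, p] = G[p, q]
    det_ok = True
    coef = np.linalg.solve(G, b)
    for p in range(m):
        if not np.isfinite(coef[p]):
            det_ok = False
    if not det_ok:
        return -np.inf
    Gt = G[na:, na:].copy()
    bt = b[na:].copy()
    coef_t = np.linalg.solve(Gt, bt)
    sse_full = yy
    for p in range(m):
        sse_full -= b[p] * coef[p]
    sse_trend = yy
    for p in range(3):
        sse_trend -= bt[p] * coef_t[p]
    if sse_trend <= 0.0:
        return 0.0
    d = sse_trend - sse_full
    if d < 0.0:
        d = 0.0
    return np.sqrt(d / sse_trend)
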