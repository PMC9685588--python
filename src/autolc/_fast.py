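"""Numba kernels for the optimizer hot path.

The two-stage gradient optimizer evaluates the retention-model objective
on the order of a million times per iteration of the method-development
loop (2000 candidates x up to 500 local-refinement evaluations, plus the
genetic algorithm).  These kernels mirror the public scalar routines in
:mod:`autolc.retention` and :mod:`autolc.scores` for the LSS law; tests
assert bit-level agreement between the two routes.

Layout of the 16-parameter vector everywhere: phi_1..phi_6, t_1..t_5,
tG_1..tG_5.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_INF_DUR = 1e300


@njit(cache=True)
def repair16(vec: np.ndarray, t_max: float) -> np.ndarray:
    """Project a raw 16-vector onto the feasible set.

    Compositions are clipped to [0, 1] and sorted non-decreasing; times are
    clipped at 0 and rescaled uniformly if their sum exceeds the budget.
    """
    out = vec.copy()
    for i in range(6):
        v = out[i]
        if v < 0.0:
            v = 0.0
        elif v > 1.0:
            v = 1.0
        out[i] = v
    out[:6] = np.sort(out[:6])
    total = 0.0
    for i in range(6, 16):
        if out[i] < 0.0:
            out[i] = 0.0
        total += out[i]
    if total > t_max:
        # shave one part in 1e12 so float rounding cannot leave the sum
        # above the (inclusive) budget after rescaling
        scale = t_max / total * (1.0 - 1e-12)
        for i in range(6, 16):
            out[i] *= scale
    return out


@njit(cache=True)
def build_pieces(vec: np.ndarray, tD: float, purge_phi: float):
    """Piecewise-linear inlet profile of a repaired 16-vector.

    Returns (t_start, dur, phi0, slope, n) arrays; the last piece is the
    purge held quasi-indefinitely.
    """
    t_start = np.empty(12)
    dur = np.empty(12)
    phi0 = np.empty(12)
    slope = np.empty(12)
    n = 0
    t = 0.0
    if tD > 0.0:
        t_start[n] = 0.0
        dur[n] = tD
        phi0[n] = vec[0]
        slope[n] = 0.0
        n += 1
        t = tD
    for seg in range(5):
        hold = vec[6 + seg]
        ramp = vec[11 + seg]
        if hold > 0.0:
            t_start[n] = t
            dur[n] = hold
            phi0[n] = vec[seg]
            slope[n] = 0.0
            n += 1
            t += hold
        if ramp > 0.0:
            t_start[n] = t
            dur[n] = ramp
            phi0[n] = vec[seg]
            slope[n] = (vec[seg + 1] - vec[seg]) / ramp
            n += 1
            t += ramp
    t_start[n] = t
    dur[n] = _INF_DUR
    phi0[n] = purge_phi
    slope[n] = 0.0
    n += 1
    return t_start, dur, phi0, slope, n


@njit(cache=True)
def batch_elution(
    t_start: np.ndarray,
    dur: np.ndarray,
    phi0: np.ndarray,
    slope: np.ndarray,
    n_pieces: int,
    k0s: np.ndarray,
    Ss: np.ndarray,
    t0: float,
):
    """Solve the LSS migration integral for every analyte under one profile.

    Returns (t_R, phi_e, slope_e) arrays; t_R measured from injection.
    """
    n = k0s.size
    t_r = np.empty(n)
    phi_e = np.empty(n)
    slope_e = np.empty(n)
    for a in range(n):
        k0 = k0s[a]
        s = Ss[a]
        acc = 0.0
        for p in range(n_pieces):
            b = slope[p]
            d = dur[p]
            if b == 0.0:
                contrib = d * math.exp(s * phi0[p]) / k0
            else:
                sb = s * b
                contrib = math.exp(s * phi0[p]) * math.expm1(sb * d) / (k0 * sb)
            if acc + contrib >= t0 or p == n_pieces - 1:
                rem = t0 - acc
                if b == 0.0:
                    step = rem * k0 * math.exp(-s * phi0[p])
                else:
                    sb = s * b
                    step = math.log1p(rem * k0 * sb * math.exp(-s * phi0[p])) / sb
                t_r[a] = t_start[p] + step + t0
                pe = phi0[p] + b * step
                if pe < 0.0:
                    pe = 0.0
                elif pe > 1.0:
                    pe = 1.0
                phi_e[a] = pe
                slope_e[a] = b
                break
            acc += contrib
    return t_r, phi_e, slope_e


@njit(cache=True)
def predict_peaks16(
    vec: np.ndarray,
    k0s: np.ndarray,
    Ss: np.ndarray,
    Ns: np.ndarray,
    t0: float,
    tD: float,
    purge_phi: float,
    floor: float,
    use_compression: bool,
):
    """Predicted (t_R, base width) per analyte for one repaired 16-vector."""
    t_start, dur, phi0, slope, n_pieces = build_pieces(vec, tD, purge_phi)
    t_r, phi_e, slope_e = batch_elution(t_start, dur, phi0, slope, n_pieces, k0s, Ss, t0)
    n = k0s.size
    widths = np.empty(n)
    for a in range(n):
        k_e = k0s[a] * math.exp(-Ss[a] * phi_e[a])
        g = 1.0
        if use_compression:
            p = Ss[a] * slope_e[a] * t0 * k_e / (1.0 + k_e)
            if p > 0.0:
                g = math.sqrt(1.0 + p + p * p / 3.0) / (1.0 + p)
        w = 4.0 * t0 / math.sqrt(Ns[a]) * (1.0 + k_e) * g
        if w < floor:
            w = floor
        widths[a] = w
    return t_r, widths


@njit(cache=True)
def score_peaks_fast(
    t_r: np.ndarray, widths: np.ndarray, cap: float, t_max: float
):
    """(o_rs, o_t, t_last) for a predicted peak set; mirrors autolc.scores."""
    n = t_r.size
    if n == 0:
        return 1.0, 0.0, 0.0
    order = np.argsort(t_r)
    t_last = t_r[order[n - 1]]
    o_t = t_last / t_max
    if o_t > 1.0:
        o_t = 1.0
    if n == 1:
        return 1.0, o_t, t_last
    sum_rs = 0.0
    for i in range(n - 1):
        a = order[i]
        b = order[i + 1]
        rs = 2.0 * (t_r[b] - t_r[a]) / (widths[a] + widths[b])
        if rs > cap:
            rs = cap
        sum_rs += rs
    ideal = cap * (n - 1)
    return (ideal - sum_rs) / ideal, o_t, t_last


@njit(cache=True)
def rm_objective(
    vec: np.ndarray,
    k0s: np.ndarray,
    Ss: np.ndarray,
    Ns: np.ndarray,
    t0: float,
    tD: float,
    purge_phi: float,
    t_max: float,
    floor: float,
    cap: float,
    w_rs: float,
    w_t: float,
    include_time: bool,
    use_compression: bool,
) -> float:
    """Full objective for one raw 16-vector: repair, simulate, score.

    Returns o_rs alone during stage-one refinement (``include_time``
    False) and the weighted performance score during the genetic
    algorithm.
    """
    rep = repair16(vec, t_max)
    t_r, widths = predict_peaks16(
        rep, k0s, Ss, Ns, t0, tD, purge_phi, floor, use_compression
    )
    o_rs, o_t, _ = score_peaks_fast(t_r, widths, cap, t_max)
    if include_time:
        return w_rs * o_rs + w_t * o_t
    return o_rs
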