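"""Numba-compiled scalar kernels for the likelihood hot loop.

The closed-form compartment solution is built from divided differences of
the exponential; the scalar helpers below mirror the vectorized versions in
:mod:`erythropy.kinetics`, with series fallbacks near removable
singularities (coinciding eigenvalues).
"""

import math

from numba import njit

__all__ = ["nll_kernel"]


@njit(cache=True)
def _phi1(z):
    # (e^z - 1)/z
    if abs(z) < 1e-8:
        return 1.0 + z / 2.0 + z * z / 6.0
    return math.expm1(z) / z


@njit(cache=True)
def _phi1_prime(z):
    # d/dz phi1; series sum_{k>=0} (k+1)/(k+2)! z^k near 0
    if abs(z) < 0.1:
        acc = 0.0
        term = 1.0
        fact = 1.0
        for k in range(10):
            fact *= k + 2
            acc += (k + 1) / fact * term
            term *= z
        return acc
    return (math.exp(z) * (z - 1.0) + 1.0) / (z * z)


@njit(cache=True)
def _phi2(u, v):
    # first divided difference of phi1, stable for u ~ v
    if abs(u - v) < 1e-6 * max(1.0, abs(u), abs(v)):
        return _phi1_prime(0.5 * (u + v))
    return (_phi1(u) - _phi1(v)) / (u - v)


@njit(cache=True)
def _dd1(x, y, t):
    # first divided difference of s -> e^{s t} at (x, y)
    return t * math.exp(y * t) * _phi1((x - y) * t)


@njit(cache=True)
def _dd2(a, b, c, t):
    # second divided difference of s -> e^{s t} at (a, b, c)
    return t * t * math.exp(c * t) * _phi2((a - c) * t, (b - c) * t)


@njit(cache=True)
def nll_kernel(
    rho_S,
    delta_SC,
    rho_C,
    delta_CB,
    rho_B,
    b1,
    b2,
    sr_t,
    sr_y,
    sr_s0,
    dm_t,
    dm_s0,
    live_idx,
    live_y,
    pct_idx,
    pct_y,
):
    """-2 log L (constant dropped); returns inf for infeasible parameters."""
    if b1 <= 0.0 or b2 <= 0.0 or delta_SC < 0.0 or delta_CB < 0.0:
        return math.inf
    total = 0.0
    # self-renewal medium: S-only exponential growth, observable 1 only
    for i in range(sr_t.size):
        f = sr_s0 * math.exp(rho_S * sr_t[i])
        if not (f > 0.0 and math.isfinite(f)):
            return math.inf
        sd = b1 * f
        r = (sr_y[i] - f) / sd
        total += r * r + 2.0 * math.log(sd)
    # differentiation medium: full three-compartment dynamics
    n = dm_t.size
    if n:
        tot_arr = dm_t * 0.0
        pct_arr = dm_t * 0.0
        a = rho_S - delta_SC
        b = rho_C - delta_CB
        for i in range(n):
            t = dm_t[i]
            S = dm_s0 * math.exp(a * t)
            C = delta_SC * dm_s0 * _dd1(a, b, t)
            B = delta_CB * delta_SC * dm_s0 * _dd2(a, b, rho_B, t)
            T = S + C + B
            tot_arr[i] = T
            pct_arr[i] = 100.0 * B / T if T > 0.0 else -1.0
        for i in range(live_idx.size):
            f = tot_arr[live_idx[i]]
            if not (f > 0.0 and math.isfinite(f)):
                return math.inf
            sd = b1 * f
            r = (live_y[i] - f) / sd
            total += r * r + 2.0 * math.log(sd)
        for i in range(pct_idx.size):
            f = pct_arr[pct_idx[i]]
            if not (f > 0.0 and math.isfinite(f)):
                return math.inf
            sd = b2 * f
            r = (pct_y[i] - f) / sd
            total += r * r + 2.0 * math.log(sd)
    return total
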