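"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, by a
different route than the library: bisection on the raw mass balances,
exhaustive enumeration of site-occupancy states, explicit sort/trim
statistics, and the analytic frequency-domain two-state exchange line
shape obtained by direct 2x2 matrix inversion (no FID, no FFT).
"""

import math

import numpy as np


def bisect_1to1_complex(p0, l0, kd, tol=1e-15):
    """Bisection on the 1:1 mass balance kd*[PL] = (P0-[PL])(L0-[PL])."""
    lo, hi = 0.0, min(p0, l0)
    if hi == 0.0:
        return 0.0

    def f(pl):
        return (p0 - pl) * (l0 - pl) - kd * pl

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1e-300):
            break
    return 0.5 * (lo + hi)


def bisect_two_site_free_ligand(n0, l0, kd):
    """Bisection on x + 2*N0*x/(kd+x) = L0 for the free ligand x."""
    if l0 == 0.0:
        return 0.0
    lo, hi = 0.0, l0

    def f(x):
        return x + 2.0 * n0 * x / (kd + x) - l0

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def enumerate_two_site_fractions(theta):
    """Species fractions by exhaustive enumeration of the 4 occupancy states.

    Two independent sites, each bound with probability theta; states
    (0,0), (0,1), (1,0), (1,1) are grouped by total ligands bound.
    """
    probs = {0: 0.0, 1: 0.0, 2: 0.0}
    for s1 in (0, 1):
        for s2 in (0, 1):
            p = (theta if s1 else 1 - theta) * (theta if s2 else 1 - theta)
            probs[s1 + s2] += p
    return probs[0], probs[1], probs[2]


def brute_force_trimmed_threshold(values, trim_fraction, n_sigma):
    """Explicit sort/slice trimmed mean + n_sigma * sample std of the trimmed set."""
    v = sorted(float(x) for x in values)
    k = int(trim_fraction * len(v))
    kept = v[k : len(v) - k] if k else v
    mean = sum(kept) / len(kept)
    if len(kept) > 1:
        var = sum((x - mean) ** 2 for x in kept) / (len(kept) - 1)
    else:
        var = 0.0
    return mean + n_sigma * math.sqrt(var)


def mcconnell_spectrum(ppm, acquisition, offsets_ppm, r2s, populations, k_fb, k_bf):
    """Closed-form two-state exchange absorption line shape.

    Direct frequency-domain evaluation 2*Re[1^T (i*w*I - L)^{-1} M0] with
    the 2x2 inverse written out analytically; matches the package's
    time-domain propagation + FFT route in the continuum limit.
    """
    f_mhz = acquisition.observe_frequency_mhz
    w = 2.0 * math.pi * (np.asarray(ppm) - acquisition.center_ppm) * f_mhz
    w_f = 2.0 * math.pi * (offsets_ppm[0] - acquisition.center_ppm) * f_mhz
    w_b = 2.0 * math.pi * (offsets_ppm[1] - acquisition.center_ppm) * f_mhz
    a11 = 1j * w - 1j * w_f + r2s[0] + k_fb
    a22 = 1j * w - 1j * w_b + r2s[1] + k_bf
    a12 = -k_bf + 0j
    a21 = -k_fb + 0j
    det = a11 * a22 - a12 * a21
    m0f, m0b = populations
    total = (m0f * (a22 - a21) + m0b * (a11 - a12)) / det
    return 2.0 * total.real
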