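"""Numba kernels for the O(N^2) template-matching entropies.

All three statistics use the Chebyshev (max-coordinate) distance and count a
match when d <= r.  The kernels return raw counts / distance arrays so the
Python wrappers (and the test oracles) can assert bitwise agreement on the
combinatorial part.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sampen_counts(x, m, r):
    """Template-match counts for sample entropy.

    Counts ordered pairs i < j over the N - m templates of length m whose
    Chebyshev distance is <= r (count B), and how many of those still match
    when extended to length m + 1 (count A).  Self-matches are excluded by
    construction.  Using N - m templates for both lengths keeps A and B on
    the same pair set (Richman & Moorman).
    """
    n = x.shape[0]
    L = n - m
    a = 0
    b = 0
    for i in range(L):
        for j in range(i + 1, L):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d <= r:
                b += 1
                t = abs(x[i + m] - x[j + m])
                if t > d:
                    d = t
                if d <= r:
                    a += 1
    return a, b


@njit(cache=True)
def apen_phis(x, m, r):
    """(Phi^m, Phi^(m+1)) for approximate entropy in one pass.

    Phi^m is the mean over i of log(C_i^m) with C_i^m = B_i^m / (N - m + 1)
    and self-matches included, so C_i >= 1/(N-m+1) and the logarithm is
    always finite.  Match counting exploits symmetry (half loop) and the
    recursion d_{m+1} = max(d_m, |x[i+m] - x[j+m]|).
    """
    n = x.shape[0]
    l1 = n - m + 1  # number of length-m templates
    l2 = n - m      # number of length-(m+1) templates
    count_m = np.ones(l1, dtype=np.int64)   # self-matches
    count_m1 = np.ones(l2, dtype=np.int64)
    for i in range(l1):
        for j in range(i + 1, l1):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d <= r:
                count_m[i] += 1
                count_m[j] += 1
                if j < l2:
                    t = abs(x[i + m] - x[j + m])
                    if t > d:
                        d = t
                    if d <= r:
                        count_m1[i] += 1
                        count_m1[j] += 1
    phi_m = 0.0
    for i in range(l1):
        phi_m += np.log(count_m[i] / l1)
    phi_m /= l1
    phi_m1 = 0.0
    for i in range(l2):
        phi_m1 += np.log(count_m1[i] / l2)
    phi_m1 /= l2
    return phi_m, phi_m1


@njit(cache=True)
def fuzzy_distances(x, m):
    """Condensed pairwise Chebyshev distances of baseline-removed templates.

    Returns (d_m, d_m1): distances between the N - m templates of length m
    and of length m + 1, each template first centred on its own mean.  The
    exponential similarity and averaging happen in the wrapper where
    vectorised ``np.exp`` is cheap.
    """
    n = x.shape[0]
    L = n - m
    em = np.empty((L, m))
    em1 = np.empty((L, m + 1))
    for i in range(L):
        s = 0.0
        for k in range(m):
            s += x[i + k]
        mu = s / m
        for k in range(m):
            em[i, k] = x[i + k] - mu
        s += x[i + m]
        mu1 = s / (m + 1)
        for k in range(m + 1):
            em1[i, k] = x[i + k] - mu1
    npairs = L * (L - 1) // 2
    d_m = np.empty(npairs)
    d_m1 = np.empty(npairs)
    p = 0
    for i in range(L):
        for j in range(i + 1, L):
            d = 0.0
            for k in range(m):
                t = abs(em[i, k] - em[j, k])
                if t > d:
                    d = t
            d_m[p] = d
            d = 0.0
            for k in range(m + 1):
                t = abs(em1[i, k] - em1[j, k])
                if t > d:
                    d = t
            d_m1[p] = d
            p += 1
    return d_m, d_m1
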