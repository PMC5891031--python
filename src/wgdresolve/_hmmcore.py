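"""Numba kernels for the assignment-vector HMM along the genome.

The hidden chain runs over the 2^n subgenome-assignment vectors.  The
junction kernel factorizes over genomes (each genome flips independently with
its own probability), so one junction update costs O(n * 2^n) instead of
O(4^n).  The kernel is symmetric, hence the same update serves the forward
and backward recursions.  Rows are rescaled at every position; log scale
factors are accumulated into the returned log-likelihood.
"""

import numpy as np
from numba import njit


@njit(inline="always")
def _apply_kernel(f, flips, out):
    """out <- K f for the factorized per-genome flip kernel (symmetric)."""
    V = f.shape[0]
    n = flips.shape[0]
    for v in range(V):
        out[v] = f[v]
    for g in range(n):
        t = flips[g]
        if t == 0.0:
            continue
        mask = 1 << g
        for v in range(V):
            if v & mask == 0:
                a = out[v]
                b = out[v | mask]
                out[v] = (1.0 - t) * a + t * b
                out[v | mask] = t * a + (1.0 - t) * b


@njit
def forward(emis, flips):
    """Scaled forward recursion.

    emis : (m, V) emission likelihoods (any per-row scaling; the caller adds
        its own log offsets to the returned log-likelihood).
    flips : (m-1, n) per-junction per-genome flip probabilities.

    Returns (loglik, alpha) with alpha normalized per row.  A data row with
    zero total likelihood yields -inf.
    """
    m, V = emis.shape
    alpha = np.empty((m, V))
    work = np.empty(V)
    f = emis[0] / V
    c = f.sum()
    if c <= 0.0:
        return -np.inf, alpha
    loglik = np.log(c)
    alpha[0] = f / c
    for i in range(1, m):
        _apply_kernel(alpha[i - 1], flips[i - 1], work)
        for v in range(V):
            work[v] *= emis[i, v]
        c = work.sum()
        if c <= 0.0:
            return -np.inf, alpha
        loglik += np.log(c)
        alpha[i] = work / c
    return loglik, alpha


@njit
def backward(emis, flips):
    """Scaled backward recursion; beta rows normalized to sum 1."""
    m, V = emis.shape
    beta = np.empty((m, V))
    work = np.empty(V)
    tmp = np.empty(V)
    beta[m - 1] = 1.0 / V
    for i in range(m - 2, -1, -1):
        for v in range(V):
            tmp[v] = beta[i + 1, v] * emis[i + 1, v]
        _apply_kernel(tmp, flips[i], work)
        c = work.sum()
        if c <= 0.0:
            beta[i] = 1.0 / V
        else:
            beta[i] = work / c
    return beta
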