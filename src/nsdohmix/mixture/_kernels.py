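"""Compiled inner loop for the collapsed Gibbs reallocation sweep.

A full sweep visits every row in order, removes it from the sufficient
statistics, and redraws its allocation from the (tempered) collapsed full
conditional.  The uniforms driving the categorical draws are pre-generated
by the caller so that all randomness flows from one numpy Generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweep(x, z, n_k, s_jk, gamma, alpha, beta, temp, unif):
    """One in-place sweep over all rows; returns nothing.

    x: (n, p) uint8; z: (n,) int64; n_k: (K,) int64; s_jk: (K, p) int64;
    unif: (n,) uniforms, one per row.
    """
    n, p = x.shape
    k_comp = n_k.shape[0]
    logw = np.empty(k_comp)
    w = np.empty(k_comp)
    for i in range(n):
        k_old = z[i]
        n_k[k_old] -= 1
        for j in range(p):
            if x[i, j]:
                s_jk[k_old, j] -= 1
        for k in range(k_comp):
            lw = np.log(n_k[k] + gamma) - p * np.log(alpha + beta + n_k[k])
            for j in range(p):
                if x[i, j]:
                    lw += np.log(alpha + s_jk[k, j])
                else:
                    lw += np.log(beta + n_k[k] - s_jk[k, j])
            logw[k] = lw * temp
        mx = logw[0]
        for k in range(1, k_comp):
            if logw[k] > mx:
                mx = logw[k]
        tot = 0.0
        for k in range(k_comp):
            w[k] = np.exp(logw[k] - mx)
            tot += w[k]
        r = unif[i] * tot
        acc = 0.0
        k_new = k_comp - 1
        for k in range(k_comp):
            acc += w[k]
            if r < acc:
                k_new = k
                break
        z[i] = k_new
        n_k[k_new] += 1
        for j in range(p):
            if x[i, j]:
                s_jk[k_new, j] += 1
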