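"""Collapsed Gibbs sampling kernel for LDA (numba-compiled).

One flat pass over all tokens per sweep. For token t in document d with word
w, the current assignment is removed from the count tables and a new topic is
drawn from the collapsed conditional

    p(z = k | rest)  ∝  (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta),

then the tables are updated in place. The RNG is numba's per-thread Mersenne
Twister, seeded inside the kernel, so a fixed seed reproduces the chain
bit-for-bit.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def run_gibbs(doc_ids, word_ids, z, n_dk, n_kw, n_k, alpha, beta, n_sweeps, seed,
              theta_sum, phi_sum, burn_in, accumulate):
    """Run ``n_sweeps`` full sweeps in place; optionally accumulate post-burn-in
    posterior means of theta and phi into ``theta_sum``/``phi_sum``.
    Returns the number of accumulated samples."""
    np.random.seed(seed)
    n_tokens = doc_ids.shape[0]
    K = n_kw.shape[0]
    V = n_kw.shape[1]
    vbeta = V * beta
    p = np.empty(K)
    n_samples = 0
    for sweep in range(n_sweeps):
        for t in range(n_tokens):
            d = doc_ids[t]
            w = word_ids[t]
            k = z[t]
            n_dk[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            total = 0.0
            for j in range(K):
                pj = (n_dk[d, j] + alpha) * (n_kw[j, w] + beta) / (n_k[j] + vbeta)
                total += pj
                p[j] = total
            u = np.random.random() * total
            k_new = 0
            while p[k_new] < u:
                k_new += 1
            z[t] = k_new
            n_dk[d, k_new] += 1
            n_kw[k_new, w] += 1
            n_k[k_new] += 1
        if accumulate and sweep >= burn_in:
            n_samples += 1
            for j in range(K):
                denom = n_k[j] + vbeta
                for w in range(V):
                    phi_sum[j, w] += (n_kw[j, w] + beta) / denom
            D = n_dk.shape[0]
            for d in range(D):
                dlen = 0
                for j in range(K):
                    dlen += n_dk[d, j]
                denom_d = dlen + K * alpha
                for j in range(K):
                    theta_sum[d, j] += (n_dk[d, j] + alpha) / denom_d
    return n_samples


@njit(cache=False)
def init_assignments(doc_ids, word_ids, K, D, V, seed):
    """Random initial topic assignments and consistent count tables."""
    np.random.seed(seed)
    n_tokens = doc_ids.shape[0]
    z = np.empty(n_tokens, dtype=np.int64)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    for t in range(n_tokens):
        k = np.random.randint(0, K)
        z[t] = k
        n_dk[doc_ids[t], k] += 1
        n_kw[k, word_ids[t]] += 1
        n_k[k] += 1
    return z, n_dk, n_kw, n_k
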