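"""Independent oracles used by unit and acceptance tests."""

import itertools

import numpy as np
from scipy.special import betaln, gammaln


def collapsed_assignment_posterior(bins, n_bins, alpha, phi_prior):
    """Exact per-observation assignment posterior for a K=2 truncated
    stick-breaking mixture of one categorical stream.

    Enumerates all 2^N assignments under the collapsed likelihood with
    phi and the stick integrated out analytically:

        P(z) prop. B(1 + n_1, alpha + n_2) / B(1, alpha)
               * prod_k DirMult(counts_k; phi_prior)

    Returns an (N, 2) array of P(z_i = k | data).
    """
    bins = np.asarray(bins)
    n = bins.size
    post = np.zeros((n, 2))
    logps, zs = [], []
    for z in itertools.product([0, 1], repeat=n):
        z = np.array(z)
        n1 = int((z == 0).sum())
        n2 = n - n1
        logp = betaln(1 + n1, alpha + n2) - betaln(1, alpha)
        for k in (0, 1):
            counts = np.bincount(bins[z == k], minlength=n_bins)
            nk = counts.sum()
            logp += (
                gammaln(n_bins * phi_prior)
                - gammaln(n_bins * phi_prior + nk)
                + np.sum(gammaln(phi_prior + counts) - gammaln(phi_prior))
            )
        logps.append(logp)
        zs.append(z)
    logps = np.array(logps)
    w = np.exp(logps - logps.max())
    w /= w.sum()
    for wi, z in zip(w, zs):
        for i in range(n):
            post[i, z[i]] += wi
    return post
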