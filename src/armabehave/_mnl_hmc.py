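"""Hamiltonian Monte Carlo backend for the multinomial mixed logit.

Numba-jitted log-posterior gradient and a self-contained HMC chain with
dual-averaging step-size adaptation and diagonal mass-matrix estimation
during warmup.  The parameter vector is laid out as

    [beta (S-1, P) row-major | tau (S-1) | u (S-1, I) row-major]

where S is the number of states (state 0 = reference), P the number of
design columns (intercept included), I the number of individuals,
``tau = log(sigma)`` the log random-intercept scales, and ``u`` the
non-centered standard-normal individual effects (b = sigma * u).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def logp_grad(theta, X, y, ind, S, I, sd_beta, sd_sigma, grad):
    """Log joint posterior density (up to a constant) and its gradient."""
    N, P = X.shape
    K = S - 1
    beta = theta[: K * P].reshape(K, P)
    tau = theta[K * P : K * P + K]
    u = theta[K * P + K :].reshape(K, I)
    sigma = np.exp(tau)

    grad[:] = 0.0
    gbeta = grad[: K * P].reshape(K, P)
    gtau = grad[K * P : K * P + K]
    gu = grad[K * P + K :].reshape(K, I)

    logp = 0.0
    eta = np.empty(K)
    for i in range(N):
        m = 0.0
        for k in range(K):
            e = 0.0
            for p in range(P):
                e += X[i, p] * beta[k, p]
            e += sigma[k] * u[k, ind[i]]
            eta[k] = e
            if e > m:
                m = e
        denom = np.exp(-m)  # reference state contributes exp(0 - m)
        for k in range(K):
            denom += np.exp(eta[k] - m)
        lse = m + np.log(denom)
        if y[i] > 0:
            logp += eta[y[i] - 1]
        logp -= lse
        for k in range(K):
            r = -np.exp(eta[k] - lse)
            if y[i] == k + 1:
                r += 1.0
            for p in range(P):
                gbeta[k, p] += r * X[i, p]
            gu[k, ind[i]] += r * sigma[k]
            gtau[k] += r * sigma[k] * u[k, ind[i]]

    # priors: beta ~ N(0, sd_beta^2); u ~ N(0,1); sigma ~ halfN(0, sd_sigma)
    for k in range(K):
        for p in range(P):
            logp -= 0.5 * beta[k, p] ** 2 / sd_beta**2
            gbeta[k, p] -= beta[k, p] / sd_beta**2
        for j in range(I):
            logp -= 0.5 * u[k, j] ** 2
            gu[k, j] -= u[k, j]
        # half-normal on sigma with log-scale Jacobian (+tau)
        logp += -0.5 * sigma[k] ** 2 / sd_sigma**2 + tau[k]
        gtau[k] += -sigma[k] ** 2 / sd_sigma**2 + 1.0
    return logp


@njit(cache=True)
def _leapfrog(theta, p, eps, n_steps, inv_mass, X, y, ind, S, I, sb, ss, grad):
    lp = logp_grad(theta, X, y, ind, S, I, sb, ss, grad)
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        theta = theta + eps * inv_mass * p
        lp = logp_grad(theta, X, y, ind, S, I, sb, ss, grad)
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return theta, p, lp


@njit(cache=True)
def run_chain(
    theta0,
    X,
    y,
    ind,
    S,
    I,
    sd_beta,
    sd_sigma,
    n_warmup,
    n_samples,
    seed,
    target_accept=0.8,
):
    """One HMC chain; returns (samples, accept_rate, n_divergent)."""
    np.random.seed(seed)
    D = theta0.size
    theta = theta0.copy()
    grad = np.empty(D)
    inv_mass = np.ones(D)
    sqrt_mass = np.ones(D)  # momentum std = sqrt(M) = 1/sqrt(inv_mass)

    eps = 0.1
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    w1 = n_warmup // 2
    var_lo = w1 // 2
    acc_buf = np.zeros((w1 - var_lo, D))

    samples = np.empty((n_samples, D))
    n_acc = 0.0
    n_div = 0
    total = n_warmup + n_samples

    for it in range(total):
        p0 = np.empty(D)
        for d in range(D):
            p0[d] = np.random.normal(0.0, 1.0) * sqrt_mass[d]
        lp0 = logp_grad(theta, X, y, ind, S, I, sd_beta, sd_sigma, grad)
        k0 = 0.0
        for d in range(D):
            k0 += 0.5 * p0[d] * p0[d] * inv_mass[d]
        h0 = lp0 - k0

        n_steps = 8 + int(np.random.random() * 25)  # jittered 8..32
        theta_new, p_new, lp_new = _leapfrog(
            theta, p0, eps, n_steps, inv_mass, X, y, ind, S, I, sd_beta, sd_sigma, grad
        )
        k1 = 0.0
        for d in range(D):
            k1 += 0.5 * p_new[d] * p_new[d] * inv_mass[d]
        h1 = lp_new - k1
        dh = h1 - h0
        if not np.isfinite(dh):
            dh = -np.inf
        accept_prob = np.exp(min(0.0, dh))
        if dh < -1000.0 and it >= n_warmup:
            n_div += 1
        if np.random.random() < accept_prob:
            theta = theta_new
            if it >= n_warmup:
                n_acc += 1.0

        if it < n_warmup:
            # dual averaging toward the target acceptance rate
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if var_lo <= it < w1:
                acc_buf[it - var_lo] = theta
            if it == w1 - 1:
                # set diagonal mass from warmup variance, restart adaptation
                for d in range(D):
                    mdean = acc_buf[:, d].mean()
                    v = ((acc_buf[:, d] - mdean) ** 2).mean()
                    inv_mass[d] = max(v, 1e-6)
                    sqrt_mass[d] = 1.0 / np.sqrt(inv_mass[d])
                mu = np.log(10.0 * eps)
                h_bar = 0.0
                log_eps_bar = np.log(eps)
                da_count = 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            samples[it - n_warmup] = theta

    return samples, n_acc / n_samples, n_div
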