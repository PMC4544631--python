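"""Numba kernels for the Bayesian whole-genome regression Gibbs samplers.

Both samplers share the linear model ``y = 1*mu + X*beta + e`` with
single-site (coordinate-wise) updates of the marker effects and a running
residual, which keeps one full sweep at O(n_lines * n_markers).

* Bayesian ridge: common effect variance ``beta_j ~ N(0, s2_beta)`` with a
  scaled-inverse-chi-square prior on ``s2_beta``.
* Bayesian LASSO (Park & Casella hierarchy): ``beta_j ~ N(0, s2_e * tau2_j)``,
  ``tau2_j ~ Exp(lambda2/2)`` giving the double-exponential marginal, and a
  Gamma(shape, rate) hyperprior on ``lambda2``.

Scaled-inverse-chi-square draws are taken as ``(df*S + q) / chi2(df + k)``.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _rinvgauss(mu, lam):
    # Michael–Schucany–Haas transform
    v = np.random.normal()
    y = v * v
    x = mu + mu * mu * y / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def brr_gibbs(X, y, S_eps, df_eps, S_beta, df_beta, burn_in, n_iter, thin, seed):
    """Gibbs sampler for Bayesian ridge regression.

    Returns (mu_mean, beta_mean, s2e_samples, s2b_samples); the scalar
    variance samples are thinned post-burn-in draws.
    """
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s
    beta = np.zeros(p)
    mu = y.mean()
    e = y - mu
    s2e = S_eps
    s2b = S_beta
    n_keep = (n_iter - burn_in + thin - 1) // thin
    s2e_samples = np.empty(n_keep)
    s2b_samples = np.empty(n_keep)
    mu_sum = 0.0
    beta_sum = np.zeros(p)
    kept = 0
    n_post = 0
    for it in range(n_iter):
        # intercept
        off = e.mean()
        mu_new = mu + off + np.random.normal() * np.sqrt(s2e / n)
        e -= mu_new - mu
        mu = mu_new
        # marker effects
        for j in range(p):
            old = beta[j]
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * e[i]
            rhs += xtx[j] * old
            c = xtx[j] + s2e / s2b
            m = rhs / c
            new = m + np.random.normal() * np.sqrt(s2e / c)
            d = new - old
            if d != 0.0:
                for i in range(n):
                    e[i] -= X[i, j] * d
            beta[j] = new
        # common effect variance
        bb = 0.0
        for j in range(p):
            bb += beta[j] * beta[j]
        s2b = (df_beta * S_beta + bb) / np.random.chisquare(df_beta + p)
        # residual variance
        ee = 0.0
        for i in range(n):
            ee += e[i] * e[i]
        s2e = (df_eps * S_eps + ee) / np.random.chisquare(df_eps + n)
        if it >= burn_in:
            mu_sum += mu
            beta_sum += beta
            n_post += 1
            if (it - burn_in) % thin == 0 and kept < n_keep:
                s2e_samples[kept] = s2e
                s2b_samples[kept] = s2b
                kept += 1
    return mu_sum / n_post, beta_sum / n_post, s2e_samples[:kept], s2b_samples[:kept]


@njit(cache=True)
def blasso_gibbs(
    X, y, S_eps, df_eps, lambda2_init, gamma_shape, gamma_rate, burn_in, n_iter, thin, seed
):
    """Gibbs sampler for the Bayesian LASSO.

    Returns (mu_mean, beta_mean, s2e_samples, lambda2_samples).
    """
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s
    beta = np.zeros(p)
    mu = y.mean()
    e = y - mu
    s2e = S_eps
    lam2 = lambda2_init
    tau2 = np.full(p, 2.0 / lam2)  # prior mean of Exp(lam2/2)
    n_keep = (n_iter - burn_in + thin - 1) // thin
    s2e_samples = np.empty(n_keep)
    lam2_samples = np.empty(n_keep)
    mu_sum = 0.0
    beta_sum = np.zeros(p)
    kept = 0
    n_post = 0
    for it in range(n_iter):
        off = e.mean()
        mu_new = mu + off + np.random.normal() * np.sqrt(s2e / n)
        e -= mu_new - mu
        mu = mu_new
        for j in range(p):
            old = beta[j]
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * e[i]
            rhs += xtx[j] * old
            c = xtx[j] + 1.0 / tau2[j]
            m = rhs / c
            new = m + np.random.normal() * np.sqrt(s2e / c)
            d = new - old
            if d != 0.0:
                for i in range(n):
                    e[i] -= X[i, j] * d
            beta[j] = new
        # latent scales: 1/tau2_j | rest ~ InvGauss(sqrt(lam2*s2e/beta_j^2), lam2)
        tsum = 0.0
        for j in range(p):
            b2 = beta[j] * beta[j]
            if b2 < 1e-20:
                b2 = 1e-20
            inv = _rinvgauss(np.sqrt(lam2 * s2e / b2), lam2)
            tau2[j] = 1.0 / inv
            tsum += tau2[j]
        # shrinkage hyperparameter
        lam2 = np.random.gamma(gamma_shape + p, 1.0 / (gamma_rate + 0.5 * tsum))
        # residual variance (includes the scaled effect sum of squares)
        ee = 0.0
        for i in range(n):
            ee += e[i] * e[i]
        bq = 0.0
        for j in range(p):
            bq += beta[j] * beta[j] / tau2[j]
        s2e = (df_eps * S_eps + ee + bq) / np.random.chisquare(df_eps + n + p)
        if it >= burn_in:
            mu_sum += mu
            beta_sum += beta
            n_post += 1
            if (it - burn_in) % thin == 0 and kept < n_keep:
                s2e_samples[kept] = s2e
                lam2_samples[kept] = lam2
                kept += 1
    return mu_sum / n_post, beta_sum / n_post, s2e_samples[:kept], lam2_samples[:kept]
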