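"""Numba kernels for meiosis and the Bayesian LASSO Gibbs sampler.

All randomness consumed inside the kernels is either pre-drawn with a
numpy Generator (meiosis) or produced by numba's own legacy RNG seeded
explicitly per call (Gibbs sampler), so that runs are reproducible on a
single thread.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["make_gametes_kernel", "gibbs_lasso_kernel"]


@njit(cache=True)
def make_gametes_kernel(parent_haps, parent_idx, start_hap,
                        xo_counts, xo_pos, xo_offsets,
                        mut_counts, mut_pos, mut_offsets,
                        locus_pos, out):
    """Build recombinant (and possibly mutated) gametes.

    parent_haps : (n_parents, 2, L) uint8
    parent_idx  : (G,) index of the parent contributing each gamete
    start_hap   : (G,) which parental haplotype the telomere copies from
    xo_counts / xo_pos / xo_offsets : Poisson crossover counts and their
        (unsorted) positions in Morgans, flattened with per-gamete offsets
    mut_counts / mut_pos / mut_offsets : recurrent-mutation counts and
        target locus indices, flattened likewise
    locus_pos   : (L,) sorted locus positions in Morgans
    out         : (G, L) uint8 output
    """
    G, L = out.shape
    for g in range(G):
        p = parent_idx[g]
        cur = start_hap[g]
        k = xo_counts[g]
        if k == 0:
            out[g, :] = parent_haps[p, cur, :]
        else:
            off = xo_offsets[g]
            # insertion sort of the (tiny) crossover position list
            for i in range(1, k):
                key = xo_pos[off + i]
                j = i - 1
                while j >= 0 and xo_pos[off + j] > key:
                    xo_pos[off + j + 1] = xo_pos[off + j]
                    j -= 1
                xo_pos[off + j + 1] = key
            prev = 0
            for c in range(k):
                cut = np.searchsorted(locus_pos, xo_pos[off + c])
                if cut > prev:
                    out[g, prev:cut] = parent_haps[p, cur, prev:cut]
                    prev = cut
                cur = 1 - cur
            out[g, prev:L] = parent_haps[p, cur, prev:L]
        for c in range(mut_counts[g]):
            j = mut_pos[mut_offsets[g] + c]
            out[g, j] = 1 - out[g, j]


@njit(cache=True, fastmath=True)
def _dot(v, w):
    s = 0.0
    for i in range(v.shape[0]):
        s += v[i] * w[i]
    return s


@njit(cache=True, fastmath=True)
def _axpy(alpha, v, w):
    for i in range(v.shape[0]):
        w[i] += alpha * v[i]


@njit(cache=True)
def gibbs_lasso_kernel(y, Xt, Zt, xtx, ztz,
                       df_e, S_e, df_d, S_d, lam_shape, lam_rate,
                       n_iter, burn_in, seed,
                       fix_variances, sig_e2_fix, sig_d2_fix, tau2_fix):
    """Single-site Gibbs sampler for y = mu + X a + Z d + e.

    Priors: a_j ~ N(0, sig_e2 * tau2_j), tau2_j ~ Exp(rate = lam2 / 2),
    lam2 ~ Gamma(lam_shape, rate=lam_rate), d_j ~ N(0, sig_d2),
    sig_d2 ~ scaled-inv-chi2(df_d, S_d), sig_e2 ~ scaled-inv-chi2(df_e, S_e).

    With ``fix_variances`` all variance parameters are clamped to the
    supplied values (used to check the sampler against the conjugate
    closed form).

    Returns posterior means of (a, d, mu, sig_e2, sig_d2, lam2) over the
    post-burn-in samples.
    """
    np.random.seed(seed)
    n = y.shape[0]
    m = Xt.shape[0]

    a = np.zeros(m)
    d = np.zeros(m)
    tau2 = np.ones(m)
    mu = y.mean()
    e = y - mu
    sig_e2 = max(np.var(y) * 0.5, 1e-8)
    sig_d2 = S_d
    lam2 = 1.0
    if fix_variances:
        sig_e2 = sig_e2_fix
        sig_d2 = sig_d2_fix
        for j in range(m):
            tau2[j] = tau2_fix

    a_sum = np.zeros(m)
    d_sum = np.zeros(m)
    mu_sum = 0.0
    se_sum = 0.0
    sd_sum = 0.0
    lam_sum = 0.0
    kept = 0

    for it in range(n_iter):
        # intercept
        s = 0.0
        for i in range(n):
            s += e[i]
        mu_new = mu + s / n + np.random.normal() * np.sqrt(sig_e2 / n)
        delta = mu_new - mu
        for i in range(n):
            e[i] -= delta
        mu = mu_new

        # additive effects, marker-specific shrinkage
        for j in range(m):
            xj = Xt[j]
            rhs = _dot(xj, e) + xtx[j] * a[j]
            prec = xtx[j] + 1.0 / tau2[j]
            mean = rhs / prec
            new = mean + np.random.normal() * np.sqrt(sig_e2 / prec)
            diff = new - a[j]
            if diff != 0.0:
                _axpy(-diff, xj, e)
            a[j] = new

        if not fix_variances:
            # tau2_j | a_j: 1/tau2_j ~ inverse-Gaussian
            for j in range(m):
                aj2 = a[j] * a[j]
                if aj2 < 1e-16:
                    aj2 = 1e-16
                mu_ig = np.sqrt(lam2 * sig_e2 / aj2)
                if mu_ig > 1e8:
                    mu_ig = 1e8
                inv_t = np.random.wald(mu_ig, lam2)
                if inv_t < 1e-12:
                    inv_t = 1e-12
                tau2[j] = 1.0 / inv_t
            # lambda^2 | tau2
            lam2 = np.random.gamma(lam_shape + m,
                                   1.0 / (lam_rate + 0.5 * tau2.sum()))

        # dominance effects, common variance
        for j in range(m):
            zj = Zt[j]
            rhs = (_dot(zj, e) + ztz[j] * d[j]) / sig_e2
            prec = ztz[j] / sig_e2 + 1.0 / sig_d2
            mean = rhs / prec
            new = mean + np.random.normal() / np.sqrt(prec)
            diff = new - d[j]
            if diff != 0.0:
                _axpy(-diff, zj, e)
            d[j] = new

        if not fix_variances:
            # sig_d2 | d
            ssd = 0.0
            for j in range(m):
                ssd += d[j] * d[j]
            sig_d2 = (df_d * S_d + ssd) / np.random.chisquare(df_d + m)
            # sig_e2 | rest (the additive-effect prior scales with sig_e2,
            # so its sum of squares enters this conditional)
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            ssa = 0.0
            for j in range(m):
                ssa += a[j] * a[j] / tau2[j]
            sig_e2 = (df_e * S_e + sse + ssa) / np.random.chisquare(df_e + n + m)

        if it >= burn_in:
            kept += 1
            mu_sum += mu
            se_sum += sig_e2
            sd_sum += sig_d2
            lam_sum += lam2
            for j in range(m):
                a_sum[j] += a[j]
                d_sum[j] += d[j]

    return (a_sum / kept, d_sum / kept, mu_sum / kept,
            se_sum / kept, sd_sum / kept, lam_sum / kept)
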