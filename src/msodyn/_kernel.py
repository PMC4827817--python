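"""Numba-compiled Gibbs sampler core for the dynamic multistate occupancy model.

One chain = one call to :func:`run_chain`. The sweep structure is

1. detection log-likelihoods L[i, t, m] from the current detection coefficients;
2. forward-filtering backward-sampling (FFBS) of every territory's latent
   trajectory — an exact draw from p(z | y, θ);
3. conjugate Dirichlet update of the initial state probabilities;
4. adaptive random-walk Metropolis updates of each season's transition
   effects given the latent transition counts;
5. conjugate normal updates of transition hyper-means, Metropolis on the log
   hyper-SDs;
6. adaptive Metropolis updates of each (season, true state) block of
   detection coefficients given the imputed states;
7. conjugate/Metropolis updates of the detection hyperparameters.

States are 0-based in this module (0..3); the public API is 1-based (1..4).
Proposal scales adapt by Robbins–Monro only during burn-in and are frozen
afterwards, so retained draws target the exact posterior.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (independent of numpy's Python-level RNG)."""
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _lse1p(eta):
    """log(1 + Σ exp(eta)) for a 1-D eta, stabilized."""
    m = 0.0
    for v in eta:
        if v > m:
            m = v
    s = np.exp(-m)
    for v in eta:
        s += np.exp(v - m)
    return m + np.log(s)


@njit(cache=True)
def _tpm_from_beta(beta_t):
    """(4, 4) row-stochastic TPM from (4, 3) effects, baseline state 0."""
    out = np.empty((4, 4))
    for m in range(4):
        lse = _lse1p(beta_t[m])
        out[m, 0] = np.exp(-lse)
        for n in range(3):
            out[m, n + 1] = np.exp(beta_t[m, n] - lse)
    return out


@njit(cache=True)
def _det_logp(alpha_mi, mi, jd, y0):
    """log p(observed y0 | true state mi+1) for one visit.

    ``alpha_mi`` is the (3, 3) coefficient block for true-state index mi+1
    (rows = observed states 1..mi+1, i.e. 2..m in 1-based labels).
    """
    jd2 = jd * jd
    eta = np.empty(mi + 1)
    for n in range(mi + 1):
        eta[n] = alpha_mi[n, 0] + alpha_mi[n, 1] * jd + alpha_mi[n, 2] * jd2
    lse = _lse1p(eta)
    if y0 == 0:
        return -lse
    if y0 - 1 > mi:
        return NEG_INF
    return eta[y0 - 1] - lse


@njit(cache=True)
def _detection_logL(n_terr, T, v_terr, v_season, v_jd, v_y, alpha):
    """L[i, t, m] = log p(all season-t visits of territory i | z_it = m)."""
    L = np.zeros((n_terr, T, 4))
    for v in range(v_terr.shape[0]):
        i = v_terr[v]
        t = v_season[v]
        y0 = v_y[v] - 1
        jd = v_jd[v]
        # true state 0: only non-detection possible
        if y0 != 0:
            L[i, t, 0] = NEG_INF
        for m in range(1, 4):
            lp = _det_logp(alpha[t, m - 1], m - 1, jd, y0)
            L[i, t, m] += lp
    return L


@njit(cache=True)
def _ffbs_territory(phi0, tpms, Li, z_out):
    """Exact conditional draw of one territory's latent path given its L rows.

    ``Li`` is (T, 4); ``z_out`` a length-T int array filled in place with
    0-based states. Forward pass is normalized each season.
    """
    T = Li.shape[0]
    f = np.empty((T, 4))
    w = np.empty(4)
    # season 0
    mx = Li[0].max()
    for m in range(4):
        w[m] = phi0[m] * np.exp(Li[0, m] - mx)
    s = w.sum()
    for m in range(4):
        f[0, m] = w[m] / s
    for t in range(1, T):
        mx = Li[t].max()
        for n in range(4):
            acc = 0.0
            for m in range(4):
                acc += f[t - 1, m] * tpms[t - 1, m, n]
            w[n] = acc * np.exp(Li[t, n] - mx)
        s = w.sum()
        for n in range(4):
            f[t, n] = w[n] / s
    # backward sample
    u = np.random.random()
    c = 0.0
    z_out[T - 1] = 3
    for m in range(4):
        c += f[T - 1, m]
        if u <= c:
            z_out[T - 1] = m
            break
    for t in range(T - 2, -1, -1):
        s = 0.0
        for m in range(4):
            w[m] = f[t, m] * tpms[t, m, z_out[t + 1]]
            s += w[m]
        u = np.random.random() * s
        c = 0.0
        z_out[t] = 3
        for m in range(4):
            c += w[m]
            if u <= c:
                z_out[t] = m
                break


@njit(cache=True)
def _dirichlet(conc):
    g = np.empty(conc.shape[0])
    for k in range(conc.shape[0]):
        g[k] = np.random.gamma(conc[k], 1.0)
    return g / g.sum()


@njit(cache=True, inline="always")
def _trans_block_lp(b, c, mu_row, sig_row):
    """Multinomial + normal-prior log density of one (season, origin) β block."""
    lse = _lse1p(b)
    ctot = c[0] + c[1] + c[2] + c[3]
    lp = -ctot * lse
    for n in range(3):
        lp += c[n + 1] * b[n]
        d = (b[n] - mu_row[n]) / sig_row[n]
        lp += -0.5 * d * d
    return lp


@njit(cache=True)
def _det_block_lp(a_block, mi, t, z, v_terr, v_season, v_jd, v_y, lo, hi, mu_blk, sig_blk):
    """Detection-block log density: season-t visits at territories in state mi+1."""
    lp = 0.0
    for v in range(lo, hi):
        if z[v_terr[v], t] == mi + 1:
            lp += _det_logp(a_block, mi, v_jd[v], v_y[v] - 1)
    for n in range(mi + 1):
        for k in range(3):
            d = (a_block[n, k] - mu_blk[n, k]) / sig_blk[n, k]
            lp += -0.5 * d * d
    return lp


@njit(cache=True, inline="always")
def _log_sd_target(lsig, resid_sq_sum, n, gamma_shape, gamma_rate, on_variance):
    """Log target of a hyper-SD on the log scale (Jacobian included)."""
    sig = np.exp(lsig)
    lp = -n * lsig - 0.5 * resid_sq_sum / (sig * sig)
    if on_variance:
        # Gamma(shape, rate) on σ²; density over log σ picks up 2σ² Jacobian
        lp += (gamma_shape - 1.0) * 2.0 * lsig - gamma_rate * sig * sig + 2.0 * lsig
    else:
        # Gamma(shape, rate) on σ; Jacobian adds one log σ
        lp += gamma_shape * lsig - gamma_rate * sig
    return lp


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    n_burn,
    thin,
    n_terr,
    T,
    v_terr,
    v_season,
    v_jd,
    v_y,
    season_off,
    conc,
    mean_prior_sd,
    gamma_shape,
    gamma_rate,
    sd_prior_on_variance,
):
    """Run one MCMC chain; returns retained draws and acceptance rates.

    Returns
    -------
    tuple of arrays
        ``(phi0, beta, mu_t, sig_t, alpha, mu_d, sig_d, z, acc_rates)`` with a
        leading retained-draw axis; ``z`` is 1-based int8; ``acc_rates`` holds
        post-burn-in Metropolis acceptance rates for (β, α, σ_trans, σ_det).
    """
    np.random.seed(seed)
    n_trans = T - 1
    S = (n_iter - n_burn + thin - 1) // thin

    # --- state ---
    phi0 = _dirichlet(conc)
    beta = np.random.normal(0.0, 0.5, (n_trans, 4, 3))
    mu_t = np.zeros((4, 3))
    sig_t = np.ones((4, 3))
    alpha = np.zeros((T, 3, 3, 3))
    for t in range(T):
        for mi in range(3):
            for n in range(mi + 1):
                alpha[t, mi, n, 0] = np.random.normal(0.0, 0.5)
                alpha[t, mi, n, 1] = np.random.normal(0.0, 0.2)
                alpha[t, mi, n, 2] = np.random.normal(0.0, 0.2)
    mu_d = np.zeros((3, 3, 3))
    sig_d = np.ones((3, 3, 3))
    z = np.zeros((n_terr, T), dtype=np.int64)

    # init z consistent with data: max observed state per territory-year
    for v in range(v_terr.shape[0]):
        y0 = v_y[v] - 1
        if y0 > z[v_terr[v], v_season[v]]:
            z[v_terr[v], v_season[v]] = y0

    # --- adaptive proposal log-scales ---
    ls_beta = np.full((n_trans, 4), np.log(0.6))
    ls_alpha = np.full((T, 3), np.log(0.4))
    ls_sig_t = np.full((4, 3), np.log(0.5))
    ls_sig_d = np.full((3, 3, 3), np.log(0.5))

    # --- storage ---
    phi0_s = np.empty((S, 4))
    beta_s = np.empty((S, n_trans, 4, 3))
    mu_t_s = np.empty((S, 4, 3))
    sig_t_s = np.empty((S, 4, 3))
    alpha_s = np.empty((S, T, 3, 3, 3))
    mu_d_s = np.empty((S, 3, 3, 3))
    sig_d_s = np.empty((S, 3, 3, 3))
    z_s = np.empty((S, n_terr, T), dtype=np.int8)

    acc = np.zeros(4)
    tries = np.zeros(4)
    prior_var0 = mean_prior_sd * mean_prior_sd

    C = np.empty((4, 4))
    z_buf = np.empty(T, dtype=np.int64)
    s_idx = 0

    for it in range(n_iter):
        adapting = it < n_burn
        gam = 1.0 / (1.0 + 0.1 * it) ** 0.6

        # 1-2. detection log-likelihoods, TPMs, FFBS
        L = _detection_logL(n_terr, T, v_terr, v_season, v_jd, v_y, alpha)
        tpms = np.empty((n_trans, 4, 4))
        for t in range(n_trans):
            tpms[t] = _tpm_from_beta(beta[t])
        for i in range(n_terr):
            _ffbs_territory(phi0, tpms, L[i], z_buf)
            for t in range(T):
                z[i, t] = z_buf[t]

        # 3. initial state probabilities | z
        post_conc = conc.copy()
        for i in range(n_terr):
            post_conc[z[i, 0]] += 1.0
        phi0 = _dirichlet(post_conc)

        # 4. transition effects | transition counts
        for t in range(n_trans):
            C[:, :] = 0.0
            for i in range(n_terr):
                C[z[i, t], z[i, t + 1]] += 1.0
            for m in range(4):
                step = np.exp(ls_beta[t, m])
                cur = beta[t, m]
                prop = np.empty(3)
                for k in range(3):
                    prop[k] = cur[k] + step * np.random.normal()
                lp0 = _trans_block_lp(cur, C[m], mu_t[m], sig_t[m])
                lp1 = _trans_block_lp(prop, C[m], mu_t[m], sig_t[m])
                a_prob = np.exp(min(0.0, lp1 - lp0))
                if np.random.random() < a_prob:
                    for k in range(3):
                        beta[t, m, k] = prop[k]
                if adapting:
                    ls_beta[t, m] += gam * (a_prob - 0.234)
                else:
                    acc[0] += a_prob
                    tries[0] += 1.0

        # 5. transition hyperparameters | β
        for m in range(4):
            for k in range(3):
                if n_trans > 0:
                    sig2 = sig_t[m, k] * sig_t[m, k]
                    prec = 1.0 / prior_var0 + n_trans / sig2
                    sb = 0.0
                    for t in range(n_trans):
                        sb += beta[t, m, k]
                    mean = (sb / sig2) / prec
                    mu_t[m, k] = mean + np.random.normal() / np.sqrt(prec)
                else:
                    mu_t[m, k] = np.random.normal(0.0, mean_prior_sd)
                rss = 0.0
                for t in range(n_trans):
                    d = beta[t, m, k] - mu_t[m, k]
                    rss += d * d
                lsig = np.log(sig_t[m, k])
                step = np.exp(ls_sig_t[m, k])
                lprop = lsig + step * np.random.normal()
                lp0 = _log_sd_target(lsig, rss, n_trans, gamma_shape, gamma_rate, sd_prior_on_variance)
                lp1 = _log_sd_target(lprop, rss, n_trans, gamma_shape, gamma_rate, sd_prior_on_variance)
                a_prob = np.exp(min(0.0, lp1 - lp0))
                if np.random.random() < a_prob:
                    sig_t[m, k] = np.exp(lprop)
                if adapting:
                    ls_sig_t[m, k] += gam * (a_prob - 0.44)
                else:
                    acc[2] += a_prob
                    tries[2] += 1.0

        # 6. detection coefficients | z, y
        for t in range(T):
            lo = season_off[t]
            hi = season_off[t + 1]
            for mi in range(3):
                step = np.exp(ls_alpha[t, mi])
                cur = alpha[t, mi]
                prop = cur.copy()
                for n in range(mi + 1):
                    for k in range(3):
                        prop[n, k] = cur[n, k] + step * np.random.normal()
                lp0 = _det_block_lp(cur, mi, t, z, v_terr, v_season, v_jd, v_y, lo, hi, mu_d[mi], sig_d[mi])
                lp1 = _det_block_lp(prop, mi, t, z, v_terr, v_season, v_jd, v_y, lo, hi, mu_d[mi], sig_d[mi])
                a_prob = np.exp(min(0.0, lp1 - lp0))
                if np.random.random() < a_prob:
                    for n in range(mi + 1):
                        for k in range(3):
                            alpha[t, mi, n, k] = prop[n, k]
                if adapting:
                    ls_alpha[t, mi] += gam * (a_prob - 0.234)
                else:
                    acc[1] += a_prob
                    tries[1] += 1.0

        # 7. detection hyperparameters | α
        for mi in range(3):
            for n in range(mi + 1):
                for k in range(3):
                    sig2 = sig_d[mi, n, k] * sig_d[mi, n, k]
                    prec = 1.0 / prior_var0 + T / sig2
                    sa = 0.0
                    for t in range(T):
                        sa += alpha[t, mi, n, k]
                    mean = (sa / sig2) / prec
                    mu_d[mi, n, k] = mean + np.random.normal() / np.sqrt(prec)
                    rss = 0.0
                    for t in range(T):
                        d = alpha[t, mi, n, k] - mu_d[mi, n, k]
                        rss += d * d
                    lsig = np.log(sig_d[mi, n, k])
                    step = np.exp(ls_sig_d[mi, n, k])
                    lprop = lsig + step * np.random.normal()
                    lp0 = _log_sd_target(lsig, rss, T, gamma_shape, gamma_rate, sd_prior_on_variance)
                    lp1 = _log_sd_target(lprop, rss, T, gamma_shape, gamma_rate, sd_prior_on_variance)
                    a_prob = np.exp(min(0.0, lp1 - lp0))
                    if np.random.random() < a_prob:
                        sig_d[mi, n, k] = np.exp(lprop)
                    if adapting:
                        ls_sig_d[mi, n, k] += gam * (a_prob - 0.44)
                    else:
                        acc[3] += a_prob
                        tries[3] += 1.0

        # --- store ---
        if it >= n_burn and (it - n_burn) % thin == 0:
            phi0_s[s_idx] = phi0
            beta_s[s_idx] = beta
            mu_t_s[s_idx] = mu_t
            sig_t_s[s_idx] = sig_t
            alpha_s[s_idx] = alpha
            mu_d_s[s_idx] = mu_d
            sig_d_s[s_idx] = sig_d
            for i in range(n_terr):
                for t in range(T):
                    z_s[s_idx, i, t] = np.int8(z[i, t] + 1)
            s_idx += 1

    rates = np.zeros(4)
    for j in range(4):
        if tries[j] > 0:
            rates[j] = acc[j] / tries[j]
    return phi0_s, beta_s, mu_t_s, sig_t_s, alpha_s, mu_d_s, sig_d_s, z_s, rates


@njit(cache=True)
def ffbs_draws(phi0, tpms, L, n_draws):
    """Repeated FFBS draws for one territory at fixed parameters (test hook).

    Seed via :func:`seed_rng` first. Returns (n_draws, T) 0-based states.
    """
    T = L.shape[0]
    out = np.empty((n_draws, T), dtype=np.int64)
    z_buf = np.empty(T, dtype=np.int64)
    for s in range(n_draws):
        _ffbs_territory(phi0, tpms, L, z_buf)
        for t in range(T):
            out[s, t] = z_buf[t]
    return out
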