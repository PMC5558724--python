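"""Numba kernels for the per-SNP mixture updates.

These loops dominate runtime: each sweep touches every entry of the
standardized genotype matrix. ``Zs`` must be Fortran-ordered so that the
inner loops walk contiguous columns. Residuals are updated incrementally;
callers are responsible for the residual-consistency invariant
(e = y - Xb - Zs g - v at all times).

The sampler uses numba's internal np.random state, seeded once per chain
via :func:`seed_kernel_rng`; everything else (Dirichlet, chi-square) runs
on a numpy Generator in the calling code.
"""

import numpy as np
from numba import njit

NCLASS = 4


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _class_log_posteriors(r_i, l_i, log_pr, class_var, sigma_e2, out):
    """Unnormalized log full-conditional of the class indicator.

    For class k with prior effect variance s2 = class_var[k], the partial
    residual statistic r_i ~ N(0, l_i*(l_i*s2 + sigma_e2)) marginally, so
    relative to the zero-variance spike:

        log f_k = log Pr_k - 0.5*log((l_i*s2 + se2)/se2)
                  + 0.5 * r_i^2 * s2 / (se2 * (l_i*s2 + se2))
    """
    for k in range(NCLASS):
        s2 = class_var[k]
        if s2 <= 0.0:
            out[k] = log_pr[k]
        else:
            denom = l_i * s2 + sigma_e2
            out[k] = (log_pr[k] - 0.5 * np.log(denom / sigma_e2)
                      + 0.5 * r_i * r_i * s2 / (sigma_e2 * denom))


@njit(cache=True)
def gibbs_sweep(Zs, w, e, g, cls, log_pr, class_var, sigma_e2, l, active,
                counts):
    """One Gibbs sweep over all SNPs, in input order.

    w is the inverse of the residual-variance diagonal (1/E_ii). ``active``
    marks SNPs still in the model (the hybrid's exclusion rule switches
    entries off). ``counts`` (length 4) receives the class tally; excluded
    SNPs count in the spike class.
    """
    n, m = Zs.shape
    logf = np.empty(NCLASS)
    for k in range(NCLASS):
        counts[k] = 0
    for i in range(m):
        if not active[i]:
            counts[0] += 1
            continue
        gi = g[i]
        r_i = 0.0
        for j in range(n):
            r_i += Zs[j, i] * w[j] * (e[j] + Zs[j, i] * gi)
        l_i = l[i]
        _class_log_posteriors(r_i, l_i, log_pr, class_var, sigma_e2, logf)
        # sample the class from the softmax of logf
        mx = logf[0]
        for k in range(1, NCLASS):
            if logf[k] > mx:
                mx = logf[k]
        tot = 0.0
        for k in range(NCLASS):
            logf[k] = np.exp(logf[k] - mx)
            tot += logf[k]
        u = np.random.random() * tot
        acc = 0.0
        knew = NCLASS - 1
        for k in range(NCLASS):
            acc += logf[k]
            if u <= acc:
                knew = k
                break
        if class_var[knew] <= 0.0:
            gnew = 0.0
        else:
            prec = l_i + sigma_e2 / class_var[knew]
            mean = r_i / prec
            sd = np.sqrt(sigma_e2 / prec)
            gnew = mean + sd * np.random.normal()
        d = gnew - gi
        if d != 0.0:
            for j in range(n):
                e[j] -= Zs[j, i] * d
        g[i] = gnew
        cls[i] = knew
        counts[knew] += 1


@njit(cache=True)
def sample_snp_effect_kernel(z_col, w, e, g_i, log_pr, class_var, sigma_e2,
                             l_i):
    """Single-SNP Gibbs update; returns (class, g_new) and updates e in place."""
    n = z_col.shape[0]
    logf = np.empty(NCLASS)
    r_i = 0.0
    for j in range(n):
        r_i += z_col[j] * w[j] * (e[j] + z_col[j] * g_i)
    _class_log_posteriors(r_i, l_i, log_pr, class_var, sigma_e2, logf)
    mx = np.max(logf)
    p = np.exp(logf - mx)
    u = np.random.random() * np.sum(p)
    acc = 0.0
    knew = NCLASS - 1
    for k in range(NCLASS):
        acc += p[k]
        if u <= acc:
            knew = k
            break
    if class_var[knew] <= 0.0:
        gnew = 0.0
    else:
        prec = l_i + sigma_e2 / class_var[knew]
        gnew = r_i / prec + np.sqrt(sigma_e2 / prec) * np.random.normal()
    d = gnew - g_i
    for j in range(n):
        e[j] -= z_col[j] * d
    return knew, gnew


@njit(cache=True)
def em_sweep(Zs, w, e, g, P, log_pr, class_var, sigma_e2, l, pev_corr):
    """One E/M sweep over all SNPs.

    E-step: responsibilities P[i, k] from the class full conditional with
    the effective precision l_i + pev_corr_i / sigma_e2 (the PEV term
    inflates apparent noise from the uncertain all-other-SNP correction).
    M-step: g_i = sum_k P[i,k] * ghat_ik (posterior-mean update).

    Returns (sum_i l_i * Var_q(g_i), sum of per-SNP prior/entropy ELBO
    contributions) for the free-energy monitor.
    """
    n, m = Zs.shape
    logf = np.empty(NCLASS)
    lsvar = 0.0
    prior_ent = 0.0
    for i in range(m):
        gi = g[i]
        r_i = 0.0
        for j in range(n):
            r_i += Zs[j, i] * w[j] * (e[j] + Zs[j, i] * gi)
        l_eff = l[i] + pev_corr[i] / sigma_e2
        _class_log_posteriors(r_i, l_eff, log_pr, class_var, sigma_e2, logf)
        mx = logf[0]
        for k in range(1, NCLASS):
            if logf[k] > mx:
                mx = logf[k]
        tot = 0.0
        for k in range(NCLASS):
            logf[k] = np.exp(logf[k] - mx)
            tot += logf[k]
        gnew = 0.0
        second = 0.0  # E_q[g_i^2]
        for k in range(NCLASS):
            pk = logf[k] / tot
            P[i, k] = pk
            if class_var[k] > 0.0 and pk > 0.0:
                prec = l_eff + sigma_e2 / class_var[k]
                ghat = r_i / prec
                vhat = sigma_e2 / prec
                gnew += pk * ghat
                second += pk * (vhat + ghat * ghat)
                # E_q[log p(g|k) - log q(g|k)] under the class-k normal
                prior_ent += pk * (0.5 * np.log(vhat / class_var[k])
                                   - (vhat + ghat * ghat)
                                   / (2.0 * class_var[k]) + 0.5)
            if pk > 0.0:
                prior_ent += pk * (log_pr[k] - np.log(pk))
        d = gnew - gi
        if d != 0.0:
            for j in range(n):
                e[j] -= Zs[j, i] * d
        g[i] = gnew
        lsvar += l[i] * (second - gnew * gnew)
    return lsvar, prior_ent


@njit(cache=True)
def em_update_snp_kernel(z_col, w, e, g_i, log_pr, class_var, sigma_e2,
                         l_i, pev_corr_i, P_row):
    """Single-SNP E/M update; fills P_row, updates e in place, returns g_new."""
    n = z_col.shape[0]
    logf = np.empty(NCLASS)
    r_i = 0.0
    for j in range(n):
        r_i += z_col[j] * w[j] * (e[j] + z_col[j] * g_i)
    l_eff = l_i + pev_corr_i / sigma_e2
    _class_log_posteriors(r_i, l_eff, log_pr, class_var, sigma_e2, logf)
    mx = np.max(logf)
    p = np.exp(logf - mx)
    p /= np.sum(p)
    gnew = 0.0
    for k in range(NCLASS):
        P_row[k] = p[k]
        if class_var[k] > 0.0:
            prec = l_eff + sigma_e2 / class_var[k]
            gnew += p[k] * (r_i / prec)
    d = gnew - g_i
    for j in range(n):
        e[j] -= z_col[j] * d
    return gnew
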