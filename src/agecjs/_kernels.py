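"""Numba kernels for the hierarchical CJS sampler.

The sampler is adaptive random-walk Metropolis-within-Gibbs on the marginal
capture-history likelihood (latent alive/dead states integrated out by the
standard forward/backward recursion with an absorbing death state). Blocks:

* one scalar update per survival intercept cell (``beta``), with the
  standard-logistic prior implied by Uniform(0,1) on the probability scale;
* one scalar update per recapture intercept cell (``alpha``), same prior;
* one scalar update per individual random effect (``eps`` for survival,
  ``omega`` for recapture) against its Normal(0, sigma^2) prior;
* one scalar update per random-effect standard deviation against the
  Uniform(0, 10) prior (bounded below at 1e-3 for numerical stability);
* one interweaving (ancillarity-sufficiency) move per standard deviation:
  a log-scale proposal that rescales the sigma together with every effect
  in its cell, holding the standardised effects fixed. Centered single-site
  updates alone mix the variance components very slowly (the usual funnel);
  the interweaving move restores mixing at the cost of one likelihood pass
  over the cell's individuals per iteration.

Cells never occupied by any individual are sampled directly from their
prior (exact, not Metropolis). Proposal scales adapt toward a 0.44
acceptance rate in batches of 50 iterations during burn-in only, so the
post-burn-in kernel is a fixed Markov chain. All randomness flows through
``np.random.seed`` inside the kernel, making chains reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SIG_LO = 1e-3
_SIG_HI = 10.0


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    ex = np.exp(x)
    return ex / (1.0 + ex)


@njit(cache=True)
def _log_sigmoid(x):
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True)
def _logistic_lpdf(x):
    # density of the standard logistic = prior on logit-scale intercepts
    ax = -abs(x)
    return ax - 2.0 * np.log1p(np.exp(ax))


@njit(cache=True)
def _ind_ll(i, k, f, last, y, bidx, aidx, egidx, ogidx,
            beta, alpha, eps, omega, use_re, ov_kind, ov_idx, ov_val):
    """Marginal log-likelihood of individual ``i``'s capture history.

    ``ov_kind`` selects a parameter override used to evaluate Metropolis
    proposals without mutating state: 0 none, 1 beta[ov_idx]=ov_val,
    2 alpha[ov_idx]=ov_val, 3 eps[ov_idx]=ov_val, 4 omega[ov_idx]=ov_val.
    """
    fi = f[i]
    li = last[i]
    ll = 0.0
    # between first and last detection the individual is certainly alive
    for t in range(fi, li):
        xb = beta[bidx[i, t]]
        if ov_kind == 1 and bidx[i, t] == ov_idx:
            xb = ov_val
        if use_re:
            e = eps[egidx[i, t]]
            if ov_kind == 3 and egidx[i, t] == ov_idx:
                e = ov_val
            xb += e
        ll += _log_sigmoid(xb)  # log phi_t
        xa = alpha[aidx[i, t]]
        if ov_kind == 2 and aidx[i, t] == ov_idx:
            xa = ov_val
        if use_re:
            w = omega[ogidx[i, t]]
            if ov_kind == 4 and ogidx[i, t] == ov_idx:
                w = ov_val
            xa += w
        if y[i, t + 1]:
            ll += _log_sigmoid(xa)
        else:
            ll += _log_sigmoid(-xa)
    # probability of never being seen after the last detection
    chi = 1.0
    for t in range(k - 2, li - 1, -1):
        xb = beta[bidx[i, t]]
        if ov_kind == 1 and bidx[i, t] == ov_idx:
            xb = ov_val
        if use_re:
            e = eps[egidx[i, t]]
            if ov_kind == 3 and egidx[i, t] == ov_idx:
                e = ov_val
            xb += e
        xa = alpha[aidx[i, t]]
        if ov_kind == 2 and aidx[i, t] == ov_idx:
            xa = ov_val
        if use_re:
            w = omega[ogidx[i, t]]
            if ov_kind == 4 and ogidx[i, t] == ov_idx:
                w = ov_val
            xa += w
        phi = _sigmoid(xb)
        pnx = _sigmoid(xa)
        chi = (1.0 - phi) + phi * (1.0 - pnx) * chi
    if chi <= 0.0:
        return -np.inf
    return ll + np.log(chi)


@njit(cache=True)
def _adapt(scales, acc, batch, batch_size):
    delta = 1.0 / np.sqrt(batch)
    if delta > 0.25:
        delta = 0.25
    for j in range(scales.shape[0]):
        rate = acc[j] / batch_size
        if rate > 0.44:
            scales[j] *= np.exp(delta)
        else:
            scales[j] *= np.exp(-delta)
        if scales[j] < 1e-3:
            scales[j] = 1e-3
        elif scales[j] > 25.0:
            scales[j] = 25.0
        acc[j] = 0.0


@njit(cache=True)
def run_chain(seed, iters, burn, thin, k,
              f, last, y, bidx, aidx, egidx, ogidx,
              eps_group, omega_group, eps_ind, omega_ind,
              m_eps_group, m_omega_group,
              aff_b_flat, aff_b_ptr, aff_a_flat, aff_a_ptr,
              grp_e_flat, grp_e_ptr, grp_o_flat, grp_o_ptr,
              beta0, alpha0, sigphi0, sigp0, use_re):
    """Run one MCMC chain; returns (nsave, nparam) retained draws.

    Parameter order in a draw: beta cells, alpha cells, sigma_phi cells,
    sigma_p cells.
    """
    np.random.seed(seed)
    n = f.shape[0]
    nb = beta0.shape[0]
    na = alpha0.shape[0]
    nsg = sigphi0.shape[0]
    nsp = sigp0.shape[0]
    neps = eps_group.shape[0]
    nom = omega_group.shape[0]

    beta = beta0.copy()
    alpha = alpha0.copy()
    sigphi = sigphi0.copy()
    sigp = sigp0.copy()
    eps = np.zeros(neps)
    omega = np.zeros(nom)

    cur = np.empty(n)
    scr = np.empty(n)
    for i in range(n):
        cur[i] = _ind_ll(i, k, f, last, y, bidx, aidx, egidx, ogidx,
                         beta, alpha, eps, omega, use_re, 0, -1, 0.0)

    sb = np.full(nb, 0.3)
    sa = np.full(na, 0.3)
    seps = np.full(neps, 0.6)
    som = np.full(nom, 0.6)
    ssphi = np.full(nsg, 0.3)
    ssp = np.full(nsp, 0.3)
    sw_phi = np.full(nsg, 0.4)  # interweaving log-scale proposal widths
    sw_p = np.full(nsp, 0.4)
    accb = np.zeros(nb)
    acca = np.zeros(na)
    acce = np.zeros(neps)
    acco = np.zeros(nom)
    accsphi = np.zeros(nsg)
    accsp = np.zeros(nsp)
    accw_phi = np.zeros(nsg)
    accw_p = np.zeros(nsp)
    sav_e = np.empty(neps)
    sav_o = np.empty(nom)

    nparam = nb + na + nsg + nsp
    nsave = (iters - burn) // thin
    out = np.empty((nsave, nparam))
    save_i = 0
    batch = 0
    batch_size = 50

    for it in range(iters):
        # ---- survival intercepts -------------------------------------
        for j in range(nb):
            lo = aff_b_ptr[j]
            hi = aff_b_ptr[j + 1]
            if hi == lo:
                u = np.random.random()  # prior-only cell: exact draw
                beta[j] = np.log(u) - np.log1p(-u)
                continue
            prop = beta[j] + np.random.normal() * sb[j]
            dlp = _logistic_lpdf(prop) - _logistic_lpdf(beta[j])
            dll = 0.0
            for q in range(lo, hi):
                i = aff_b_flat[q]
                v = _ind_ll(i, k, f, last, y, bidx, aidx, egidx, ogidx,
                            beta, alpha, eps, omega, use_re, 1, j, prop)
                scr[i] = v
                dll += v - cur[i]
            if np.log(np.random.random()) < dll + dlp:
                beta[j] = prop
                for q in range(lo, hi):
                    cur[aff_b_flat[q]] = scr[aff_b_flat[q]]
                accb[j] += 1.0
        # ---- recapture intercepts ------------------------------------
        for j in range(na):
            lo = aff_a_ptr[j]
            hi = aff_a_ptr[j + 1]
            if hi == lo:
                u = np.random.random()
                alpha[j] = np.log(u) - np.log1p(-u)
                continue
            prop = alpha[j] + np.random.normal() * sa[j]
            dlp = _logistic_lpdf(prop) - _logistic_lpdf(alpha[j])
            dll = 0.0
            for q in range(lo, hi):
                i = aff_a_flat[q]
                v = _ind_ll(i, k, f, last, y, bidx, aidx, egidx, ogidx,
                            beta, alpha, eps, omega, use_re, 2, j, prop)
                scr[i] = v
                dll += v - cur[i]
            if np.log(np.random.random()) < dll + dlp:
                alpha[j] = prop
                for q in range(lo, hi):
                    cur[aff_a_flat[q]] = scr[aff_a_flat[q]]
                acca[j] += 1.0
        # ---- individual random effects -------------------------------
        if use_re:
            for e0 in range(neps):
                i = eps_ind[e0]
                sd = sigphi[eps_group[e0]]
                prop = eps[e0] + np.random.normal() * seps[e0]
                v = _ind_ll(i, k, f, last, y, bidx, aidx, egidx, ogidx,
                            beta, alpha, eps, omega, use_re, 3, e0, prop)
                dlp = -0.5 * (prop * prop - eps[e0] * eps[e0]) / (sd * sd)
                if np.log(np.random.random()) < v - cur[i] + dlp:
                    eps[e0] = prop
                    cur[i] = v
                    acce[e0] += 1.0
            for e0 in range(nom):
                i = omega_ind[e0]
                sd = sigp[omega_group[e0]]
                prop = omega[e0] + np.random.normal() * som[e0]
                v = _ind_ll(i, k, f, last, y, bidx, aidx, egidx, ogidx,
                            beta, alpha, eps, omega, use_re, 4, e0, prop)
                dlp = -0.5 * (prop * prop - omega[e0] * omega[e0]) / (sd * sd)
                if np.log(np.random.random()) < v - cur[i] + dlp:
                    omega[e0] = prop
                    cur[i] = v
                    acco[e0] += 1.0
            # ---- random-effect standard deviations -------------------
            S = np.zeros(nsg)
            for e0 in range(neps):
                S[eps_group[e0]] += eps[e0] * eps[e0]
            for g in range(nsg):
                m = m_eps_group[g]
                if m == 0:
                    sigphi[g] = _SIG_LO + (_SIG_HI - _SIG_LO) * np.random.random()
                    continue
                c = sigphi[g]
                prop = c + np.random.normal() * ssphi[g]
                if prop <= _SIG_LO or prop >= _SIG_HI:
                    continue
                dlp = -m * (np.log(prop) - np.log(c)) \
                    - 0.5 * S[g] * (1.0 / (prop * prop) - 1.0 / (c * c))
                if np.log(np.random.random()) < dlp:
                    sigphi[g] = prop
                    accsphi[g] += 1.0
            S2 = np.zeros(nsp)
            for e0 in range(nom):
                S2[omega_group[e0]] += omega[e0] * omega[e0]
            for g in range(nsp):
                m = m_omega_group[g]
                if m == 0:
                    sigp[g] = _SIG_LO + (_SIG_HI - _SIG_LO) * np.random.random()
                    continue
                c = sigp[g]
                prop = c + np.random.normal() * ssp[g]
                if prop <= _SIG_LO or prop >= _SIG_HI:
                    continue
                dlp = -m * (np.log(prop) - np.log(c)) \
                    - 0.5 * S2[g] * (1.0 / (prop * prop) - 1.0 / (c * c))
                if np.log(np.random.random()) < dlp:
                    sigp[g] = prop
                    accsp[g] += 1.0
            # ---- interweaving moves: rescale sigma with its effects ----
            for g in range(nsg):
                lo = grp_e_ptr[g]
                hi = grp_e_ptr[g + 1]
                if hi == lo:
                    continue
                c = sigphi[g]
                r = np.exp(np.random.normal() * sw_phi[g])
                prop = c * r
                if prop <= _SIG_LO or prop >= _SIG_HI:
                    continue
                dll = 0.0
                for q in range(lo, hi):
                    e0 = grp_e_flat[q]
                    sav_e[e0] = eps[e0]
                    eps[e0] *= r
                for q in range(lo, hi):
                    i = eps_ind[grp_e_flat[q]]
                    v = _ind_ll(i, k, f, last, y, bidx, aidx, egidx, ogidx,
                                beta, alpha, eps, omega, use_re, 0, -1, 0.0)
                    scr[i] = v
                    dll += v - cur[i]
                if np.log(np.random.random()) < dll + np.log(r):
                    sigphi[g] = prop
                    for q in range(lo, hi):
                        i = eps_ind[grp_e_flat[q]]
                        cur[i] = scr[i]
                    accw_phi[g] += 1.0
                else:
                    for q in range(lo, hi):
                        e0 = grp_e_flat[q]
                        eps[e0] = sav_e[e0]
            for g in range(nsp):
                lo = grp_o_ptr[g]
                hi = grp_o_ptr[g + 1]
                if hi == lo:
                    continue
                c = sigp[g]
                r = np.exp(np.random.normal() * sw_p[g])
                prop = c * r
                if prop <= _SIG_LO or prop >= _SIG_HI:
                    continue
                dll = 0.0
                for q in range(lo, hi):
                    e0 = grp_o_flat[q]
                    sav_o[e0] = omega[e0]
                    omega[e0] *= r
                for q in range(lo, hi):
                    i = omega_ind[grp_o_flat[q]]
                    v = _ind_ll(i, k, f, last, y, bidx, aidx, egidx, ogidx,
                                beta, alpha, eps, omega, use_re, 0, -1, 0.0)
                    scr[i] = v
                    dll += v - cur[i]
                if np.log(np.random.random()) < dll + np.log(r):
                    sigp[g] = prop
                    for q in range(lo, hi):
                        i = omega_ind[grp_o_flat[q]]
                        cur[i] = scr[i]
                    accw_p[g] += 1.0
                else:
                    for q in range(lo, hi):
                        e0 = grp_o_flat[q]
                        omega[e0] = sav_o[e0]
        # ---- proposal adaptation (burn-in only) ----------------------
        if it < burn and (it + 1) % batch_size == 0:
            batch += 1
            _adapt(sb, accb, batch, batch_size)
            _adapt(sa, acca, batch, batch_size)
            if use_re:
                _adapt(seps, acce, batch, batch_size)
                _adapt(som, acco, batch, batch_size)
                _adapt(ssphi, accsphi, batch, batch_size)
                _adapt(ssp, accsp, batch, batch_size)
                _adapt(sw_phi, accw_phi, batch, batch_size)
                _adapt(sw_p, accw_p, batch, batch_size)
        # ---- save ----------------------------------------------------
        if it >= burn and (it - burn + 1) % thin == 0 and save_i < nsave:
            for j in range(nb):
                out[save_i, j] = beta[j]
            for j in range(na):
                out[save_i, nb + j] = alpha[j]
            for j in range(nsg):
                out[save_i, nb + na + j] = sigphi[j]
            for j in range(nsp):
                out[save_i, nb + na + nsg + j] = sigp[j]
            save_i += 1
    return out
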