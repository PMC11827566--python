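"""Numba kernels: likelihood forward pass, agent simulation, MH sweeps.

Everything here works on plain arrays so the hot loops of sampling and
simulation stay allocation-free.  Conventions (shared with the rest of the
package):

* first-stage actions ``a1 in {0, 1}``; second-stage states ``s2 in {0, 1}``
  (0 = B, 1 = C); second-stage actions ``a2 in {0, 1}``
* global option index ``n = 2 * s2 + a2`` (B0, B1, C0, C1)
* ``common0`` is the second-stage state reached by action 0 under a common
  transition; action 1's common state is ``1 - common0``
* rewards are already rescaled to [0, 1]
* the full parameter vector follows :data:`twostep.variants.PARAM_NAMES`

Latent state per agent: 2 first-stage model-free values, a 2x2 table of
second-stage values, a 2-vector of habit strengths, a 4-vector of
bandit-counter bitmasks (which *other* options were sampled since this one
was last chosen) and a 4-vector of trials-since-last-sampled counters.
"""

import math

import numpy as np
from numba import njit

_SQRT1_2 = 0.7071067811865476

# neutral fill values, aligned with variants._NEUTRAL / PARAM_NAMES
_NEUTRAL_VEC = np.array([0.5, 0.5, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0])


@njit(cache=True)
def _phi(x):
    """Standard-normal CDF."""
    return 0.5 * math.erfc(-x * _SQRT1_2)


@njit(cache=True)
def _pvec_from_raw(raw_row, free_idx, is_rate, out):
    for i in range(9):
        out[i] = _NEUTRAL_VEC[i]
    for k in range(free_idx.shape[0]):
        v = raw_row[k]
        out[free_idx[k]] = _phi(v) if is_rate[k] else v


@njit(cache=True)
def _popcount4(mask):
    c = 0
    for b in range(4):
        if mask & (1 << b):
            c += 1
    return c


@njit(cache=True)
def _forward(s1, s2, a2, reward, valid, pvec, uses_hop, explo, decay_all,
             p_common, common0, ll_out, p0_out, store):
    """One pass over a subject's trials.

    Returns the summed log-likelihood over valid trials.  When ``store`` is
    true, the per-trial log-likelihood (0 for invalid trials) and the
    conditional probability of choosing first-stage action 0 are written to
    ``ll_out`` / ``p0_out``.
    """
    a1_, a2lr, a3, ahop = pvec[0], pvec[1], pvec[2], pvec[3]
    bmb, bmf, bp, b2, phi = pvec[4], pvec[5], pvec[6], pvec[7], pvec[8]

    qmf1 = np.empty(2)
    q2 = np.empty((2, 2))
    habit = np.zeros(2)
    bmask = np.zeros(4, dtype=np.int64)
    tcount = np.ones(4, dtype=np.int64)
    qmf1[0] = qmf1[1] = 0.5
    q2[0, 0] = q2[0, 1] = q2[1, 0] = q2[1, 1] = 0.5
    prev = -1

    total = 0.0
    T = s1.shape[0]
    for t in range(T):
        # per-state max Q2 and exploration sums
        max0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        max1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        eb0 = 0.0
        eb1 = 0.0
        if explo == 1:
            eb0 = _popcount4(bmask[0]) + _popcount4(bmask[1])
            eb1 = _popcount4(bmask[2]) + _popcount4(bmask[3])
        elif explo == 2:
            for n in range(4):
                v = math.log(tcount[n])
                if v < 0.0:
                    v = 0.0
                if n < 2:
                    eb0 += v
                else:
                    eb1 += v

        u0 = 0.0
        u1 = 0.0
        for a in range(2):
            cs = common0 if a == 0 else 1 - common0
            pB = p_common if cs == 0 else 1.0 - p_common
            qmb = pB * max0 + (1.0 - pB) * max1
            eb = pB * eb0 + (1.0 - pB) * eb1
            if uses_hop:
                pers = habit[a]
            else:
                pers = 1.0 if a == prev else 0.0
            u = bmb * qmb + bmf * qmf1[a] + bp * pers + phi * eb
            if a == 0:
                u0 = u
            else:
                u1 = u

        # log-sum-exp over the two utilities
        m = u0 if u0 >= u1 else u1
        lse = m + math.log(math.exp(u0 - m) + math.exp(u1 - m))
        st = s2[t]
        v0 = b2 * q2[st, 0]
        v1 = b2 * q2[st, 1]
        m2 = v0 if v0 >= v1 else v1
        lse2 = m2 + math.log(math.exp(v0 - m2) + math.exp(v1 - m2))

        ll = 0.0
        if valid[t]:
            u_ch = u0 if s1[t] == 0 else u1
            v_ch = v0 if a2[t] == 0 else v1
            ll = (u_ch - lse) + (v_ch - lse2)
            total += ll
        if store:
            ll_out[t] = ll
            p0_out[t] = math.exp(u0 - lse)

        # --- state update ---
        if valid[t]:
            c1 = s1[t]
            cs2 = s2[t]
            ca2 = a2[t]
            r = reward[t]
            d1 = q2[cs2, ca2] - qmf1[c1]
            qmf1[c1] += a1_ * d1
            d2 = r - q2[cs2, ca2]
            q2[cs2, ca2] += a2lr * d2
            qmf1[c1] += a2lr * d2
            # forgetting of unchosen values
            qmf1[1 - c1] = a3 * qmf1[1 - c1] + (1.0 - a3) * 0.5
            q2[cs2, 1 - ca2] = a3 * q2[cs2, 1 - ca2] + (1.0 - a3) * 0.5
            if decay_all:
                q2[1 - cs2, 0] = a3 * q2[1 - cs2, 0] + (1.0 - a3) * 0.5
                q2[1 - cs2, 1] = a3 * q2[1 - cs2, 1] + (1.0 - a3) * 0.5
            if uses_hop:
                habit[c1] += ahop * (1.0 - habit[c1])
                habit[1 - c1] += ahop * (0.0 - habit[1 - c1])
            prev = c1
        # counters track sampling history even on excluded trials
        n = 2 * s2[t] + a2[t]
        bmask[n] = 0
        tcount[n] = 1
        for mth in range(4):
            if mth != n:
                bmask[mth] |= 1 << n
                tcount[mth] += 1
    return total


@njit(cache=True)
def forward_full(s1, s2, a2, reward, valid, pvec, uses_hop, explo, decay_all,
                 p_common, common0):
    """Pointwise log-likelihood and P(a1 = 0) series for one subject."""
    T = s1.shape[0]
    ll = np.zeros(T)
    p0 = np.empty(T)
    total = _forward(s1, s2, a2, reward, valid, pvec, uses_hop, explo,
                     decay_all, p_common, common0, ll, p0, True)
    return total, ll, p0


@njit(cache=True)
def total_loglik(s1, s2, a2, reward, valid, pvec, uses_hop, explo, decay_all,
                 p_common, common0, scratch_ll, scratch_p0):
    return _forward(s1, s2, a2, reward, valid, pvec, uses_hop, explo,
                    decay_all, p_common, common0, scratch_ll, scratch_p0, False)


@njit(cache=True)
def simulate_trials(outcomes, is_magnitude, uniforms, pvec, uses_hop, explo,
                    decay_all, p_common, common0):
    """Simulate an agent on pre-generated outcome walks.

    ``outcomes`` is (T, 4): reward magnitudes (0-100) for the magnitude
    variant, reward probabilities otherwise.  ``uniforms`` is (T, 4) of iid
    U(0,1) draws consumed as (a1, transition, a2, reward) per trial, so the
    whole simulation is a pure function of its inputs.
    """
    a1_, a2lr, a3, ahop = pvec[0], pvec[1], pvec[2], pvec[3]
    bmb, bmf, bp, b2, phi = pvec[4], pvec[5], pvec[6], pvec[7], pvec[8]

    T = outcomes.shape[0]
    s1 = np.empty(T, dtype=np.int64)
    common = np.empty(T, dtype=np.int64)
    s2 = np.empty(T, dtype=np.int64)
    a2 = np.empty(T, dtype=np.int64)
    reward_raw = np.empty(T)

    qmf1 = np.empty(2)
    q2 = np.empty((2, 2))
    habit = np.zeros(2)
    bmask = np.zeros(4, dtype=np.int64)
    tcount = np.ones(4, dtype=np.int64)
    qmf1[0] = qmf1[1] = 0.5
    q2[0, 0] = q2[0, 1] = q2[1, 0] = q2[1, 1] = 0.5
    prev = -1

    for t in range(T):
        max0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        max1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        eb0 = 0.0
        eb1 = 0.0
        if explo == 1:
            eb0 = _popcount4(bmask[0]) + _popcount4(bmask[1])
            eb1 = _popcount4(bmask[2]) + _popcount4(bmask[3])
        elif explo == 2:
            for n in range(4):
                v = math.log(tcount[n])
                if v < 0.0:
                    v = 0.0
                if n < 2:
                    eb0 += v
                else:
                    eb1 += v

        u0 = 0.0
        u1 = 0.0
        for a in range(2):
            cs = common0 if a == 0 else 1 - common0
            pB = p_common if cs == 0 else 1.0 - p_common
            qmb = pB * max0 + (1.0 - pB) * max1
            eb = pB * eb0 + (1.0 - pB) * eb1
            if uses_hop:
                pers = habit[a]
            else:
                pers = 1.0 if a == prev else 0.0
            u = bmb * qmb + bmf * qmf1[a] + bp * pers + phi * eb
            if a == 0:
                u0 = u
            else:
                u1 = u
        p_a0 = 1.0 / (1.0 + math.exp(u1 - u0))
        c1 = 0 if uniforms[t, 0] < p_a0 else 1

        is_common = 1 if uniforms[t, 1] < p_common else 0
        cs_common = common0 if c1 == 0 else 1 - common0
        cs2 = cs_common if is_common else 1 - cs_common

        p2_a0 = 1.0 / (1.0 + math.exp(b2 * (q2[cs2, 1] - q2[cs2, 0])))
        ca2 = 0 if uniforms[t, 2] < p2_a0 else 1
        n = 2 * cs2 + ca2

        if is_magnitude:
            rraw = outcomes[t, n]
            r = rraw / 100.0
        else:
            rraw = 1.0 if uniforms[t, 3] < outcomes[t, n] else 0.0
            r = rraw

        s1[t] = c1
        common[t] = is_common
        s2[t] = cs2
        a2[t] = ca2
        reward_raw[t] = rraw

        d1 = q2[cs2, ca2] - qmf1[c1]
        qmf1[c1] += a1_ * d1
        d2 = r - q2[cs2, ca2]
        q2[cs2, ca2] += a2lr * d2
        qmf1[c1] += a2lr * d2
        qmf1[1 - c1] = a3 * qmf1[1 - c1] + (1.0 - a3) * 0.5
        q2[cs2, 1 - ca2] = a3 * q2[cs2, 1 - ca2] + (1.0 - a3) * 0.5
        if decay_all:
            q2[1 - cs2, 0] = a3 * q2[1 - cs2, 0] + (1.0 - a3) * 0.5
            q2[1 - cs2, 1] = a3 * q2[1 - cs2, 1] + (1.0 - a3) * 0.5
        if uses_hop:
            habit[c1] += ahop * (1.0 - habit[c1])
            habit[1 - c1] += ahop * (0.0 - habit[1 - c1])
        prev = c1
        bmask[n] = 0
        tcount[n] = 1
        for mth in range(4):
            if mth != n:
                bmask[mth] |= 1 << n
                tcount[mth] += 1

    return s1, common, s2, a2, reward_raw


@njit(cache=True)
def seed_numba(seed):
    # numba maintains its own RNG state, separate from numpy's
    np.random.seed(seed)


@njit(cache=True)
def mh_sweep(raw, ll_cache, mu, sigma, scales, acc, free_idx, is_rate,
             uses_hop, explo, decay_all, p_common, common0,
             s1, s2, a2, reward, valid, offsets, n_scans):
    """Single-site random-walk Metropolis over all subjects' raw parameters.

    ``raw`` (S, K) and ``ll_cache`` (S,) are updated in place; ``acc``
    accumulates acceptance counts for scale adaptation.  Group-level
    parameters (mu, sigma) are held fixed within the sweep; their updates are
    conjugate/slice steps performed by the caller.
    """
    S, K = raw.shape
    pvec = np.empty(9)
    Tmax = 0
    for s in range(S):
        n = offsets[s + 1] - offsets[s]
        if n > Tmax:
            Tmax = n
    scratch_ll = np.empty(Tmax)
    scratch_p0 = np.empty(Tmax)

    for _scan in range(n_scans):
        for s in range(S):
            lo = offsets[s]
            hi = offsets[s + 1]
            for k in range(K):
                old = raw[s, k]
                prop = old + scales[s, k] * np.random.normal()
                raw[s, k] = prop
                _pvec_from_raw(raw[s], free_idx, is_rate, pvec)
                ll_new = _forward(s1[lo:hi], s2[lo:hi], a2[lo:hi],
                                  reward[lo:hi], valid[lo:hi], pvec,
                                  uses_hop, explo, decay_all, p_common,
                                  common0, scratch_ll, scratch_p0, False)
                dprior = ((old - mu[k]) ** 2 - (prop - mu[k]) ** 2) / (2.0 * sigma[k] ** 2)
                log_alpha = (ll_new - ll_cache[s]) + dprior
                if math.log(np.random.random()) < log_alpha:
                    ll_cache[s] = ll_new
                    acc[s, k] += 1
                else:
                    raw[s, k] = old


@njit(cache=True)
def prior_sweep(raw, ll_cache, mu, sigma, free_idx, is_rate, uses_hop,
                explo, decay_all, p_common, common0, s1, s2, a2, reward,
                valid, offsets):
    """Single-site independence proposals from the group prior.

    Proposing theta_sk' ~ N(mu_k, sigma_k) makes prior and proposal terms
    cancel in the acceptance ratio, leaving the likelihood ratio alone.
    For weakly identified parameters (likelihood nearly flat) this accepts
    almost every move and removes their random-walk autocorrelation.
    """
    S, K = raw.shape
    pvec = np.empty(9)
    Tmax = 0
    for s in range(S):
        n = offsets[s + 1] - offsets[s]
        if n > Tmax:
            Tmax = n
    scratch_ll = np.empty(Tmax)
    scratch_p0 = np.empty(Tmax)

    for s in range(S):
        lo = offsets[s]
        hi = offsets[s + 1]
        for k in range(K):
            old = raw[s, k]
            raw[s, k] = mu[k] + sigma[k] * np.random.normal()
            _pvec_from_raw(raw[s], free_idx, is_rate, pvec)
            ll_new = _forward(s1[lo:hi], s2[lo:hi], a2[lo:hi], reward[lo:hi],
                              valid[lo:hi], pvec, uses_hop, explo, decay_all,
                              p_common, common0, scratch_ll, scratch_p0, False)
            if math.log(np.random.random()) < ll_new - ll_cache[s]:
                ll_cache[s] = ll_new
            else:
                raw[s, k] = old


@njit(cache=True)
def block_sweep(raw, ll_cache, mu, sigma, chols, block_acc, n_props,
                free_idx, is_rate, uses_hop, explo, decay_all, p_common,
                common0, s1, s2, a2, reward, valid, offsets):
    """Full-vector Metropolis proposals per subject.

    ``chols`` (S, K, K) holds lower-triangular Cholesky factors of the
    adapted per-subject proposal covariances, which lets the sampler move
    along within-subject parameter correlations (e.g. the second-stage
    learning-rate/inverse-temperature trade-off) that single-site scans
    cannot follow efficiently.
    """
    S, K = raw.shape
    pvec = np.empty(9)
    Tmax = 0
    for s in range(S):
        n = offsets[s + 1] - offsets[s]
        if n > Tmax:
            Tmax = n
    scratch_ll = np.empty(Tmax)
    scratch_p0 = np.empty(Tmax)
    prop = np.empty(K)
    z = np.empty(K)

    for s in range(S):
        lo = offsets[s]
        hi = offsets[s + 1]
        for _p in range(n_props):
            for k in range(K):
                z[k] = np.random.normal()
            for k in range(K):
                acc_v = raw[s, k]
                for j in range(k + 1):
                    acc_v += chols[s, k, j] * z[j]
                prop[k] = acc_v
            _pvec_from_raw(prop, free_idx, is_rate, pvec)
            ll_new = _forward(s1[lo:hi], s2[lo:hi], a2[lo:hi], reward[lo:hi],
                              valid[lo:hi], pvec, uses_hop, explo, decay_all,
                              p_common, common0, scratch_ll, scratch_p0, False)
            dlp = ll_new - ll_cache[s]
            for k in range(K):
                dlp += ((raw[s, k] - mu[k]) ** 2 - (prop[k] - mu[k]) ** 2) / (2.0 * sigma[k] ** 2)
            if math.log(np.random.random()) < dlp:
                for k in range(K):
                    raw[s, k] = prop[k]
                ll_cache[s] = ll_new
                block_acc[s] += 1


@njit(cache=True)
def nc_sweep(raw, ll_cache, mu, sigma, nc_scales, nc_acc, mean_prior_sd,
             sd_upper, free_idx, is_rate, uses_hop, explo, decay_all,
             p_common, common0, s1, s2, a2, reward, valid, offsets,
             move_set):
    """Interweaved non-centered updates of the group-level parameters.

    In the non-centered frame theta_s = mu + sigma * z_s with z fixed, so a
    move of mu (or sigma) translates (or rescales) every subject's raw
    parameter and must be accepted against the joint likelihood.  This
    breaks the funnel coupling that slows the centered Gibbs updates for
    weakly identified parameters.  ``mu``, ``sigma``, ``raw`` and
    ``ll_cache`` are updated in place.
    """
    S, K = raw.shape
    pvec = np.empty(9)
    Tmax = 0
    for s in range(S):
        n = offsets[s + 1] - offsets[s]
        if n > Tmax:
            Tmax = n
    scratch_ll = np.empty(Tmax)
    scratch_p0 = np.empty(Tmax)
    new_ll = np.empty(S)
    new_col = np.empty(S)

    for k in range(K):
        for move in range(2):
            # move 0: random-walk translation mu_k' = mu_k + eps
            # move 1: independence translation mu_k' ~ N(0, prior SD) —
            #         proposal cancels the prior, so weakly identified group
            #         means traverse their whole posterior in one step
            if move != move_set:
                continue
            if move == 0:
                mu_new = mu[k] + nc_scales[k, 0] * np.random.normal()
                dlp = (mu[k] ** 2 - mu_new ** 2) / (2.0 * mean_prior_sd ** 2)
            else:
                mu_new = mean_prior_sd * np.random.normal()
                dlp = 0.0
            eps = mu_new - mu[k]
            for s in range(S):
                old = raw[s, k]
                raw[s, k] = old + eps
                _pvec_from_raw(raw[s], free_idx, is_rate, pvec)
                lo = offsets[s]
                hi = offsets[s + 1]
                new_ll[s] = _forward(s1[lo:hi], s2[lo:hi], a2[lo:hi],
                                     reward[lo:hi], valid[lo:hi], pvec,
                                     uses_hop, explo, decay_all, p_common,
                                     common0, scratch_ll, scratch_p0, False)
                new_col[s] = raw[s, k]
                raw[s, k] = old
                dlp += new_ll[s] - ll_cache[s]
            if math.log(np.random.random()) < dlp:
                mu[k] = mu_new
                for s in range(S):
                    raw[s, k] = new_col[s]
                    ll_cache[s] = new_ll[s]
                if move == 0:
                    nc_acc[k, 0] += 1

        # rescale moves on sigma_k: theta' = mu + (sigma'/sigma)(theta - mu)
        # move 0: random walk on log sigma; move 1: independence draw from
        # the uniform prior (cancels in the ratio -> free traversal when the
        # likelihood is flat in this direction)
        for move in range(2):
            if move != move_set:
                continue
            if move == 0:
                lsig_new = math.log(sigma[k]) + nc_scales[k, 1] * np.random.normal()
                sig_new = math.exp(lsig_new)
                dlp = lsig_new - math.log(sigma[k])  # Jacobian of the log scale
            else:
                sig_new = sd_upper[k] * np.random.random()
                dlp = 0.0
            if sig_new <= 0.0 or sig_new >= sd_upper[k]:
                continue
            ratio = sig_new / sigma[k]
            for s in range(S):
                old = raw[s, k]
                raw[s, k] = mu[k] + ratio * (old - mu[k])
                _pvec_from_raw(raw[s], free_idx, is_rate, pvec)
                lo = offsets[s]
                hi = offsets[s + 1]
                new_ll[s] = _forward(s1[lo:hi], s2[lo:hi], a2[lo:hi],
                                     reward[lo:hi], valid[lo:hi], pvec,
                                     uses_hop, explo, decay_all, p_common,
                                     common0, scratch_ll, scratch_p0, False)
                new_col[s] = raw[s, k]
                raw[s, k] = old
                dlp += new_ll[s] - ll_cache[s]
            if math.log(np.random.random()) < dlp:
                sigma[k] = sig_new
                for s in range(S):
                    raw[s, k] = new_col[s]
                    ll_cache[s] = new_ll[s]
                if move == 0:
                    nc_acc[k, 1] += 1


@njit(cache=True)
def pointwise_for_draws(raws, free_idx, is_rate, uses_hop, explo, decay_all,
                        p_common, common0, s1, s2, a2, reward, valid, offsets):
    """Per-trial log-likelihood matrix (draws x all trials) from raw draws."""
    D = raws.shape[0]
    S = offsets.shape[0] - 1
    Ttot = s1.shape[0]
    out = np.zeros((D, Ttot))
    pvec = np.empty(9)
    p0 = np.empty(Ttot)
    for d in range(D):
        for s in range(S):
            lo = offsets[s]
            hi = offsets[s + 1]
            _pvec_from_raw(raws[d, s], free_idx, is_rate, pvec)
            _forward(s1[lo:hi], s2[lo:hi], a2[lo:hi], reward[lo:hi],
                     valid[lo:hi], pvec, uses_hop, explo, decay_all,
                     p_common, common0, out[d, lo:hi], p0[lo:hi], True)
    return out
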