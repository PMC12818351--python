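"""Compiled Metropolis–Hastings / Gibbs kernel for the joint posterior.

One composite sweep updates, in order: one replica's conformational state,
each observable type's Bayesian uncertainty sigma_B (log-space random walk),
its variance inflator(s) phi (log-space random walk), and its forward-model
coefficients theta (gradient-informed proposal during burn-in, symmetric
random walk afterwards).  Replica states get two kinds of moves: a cheap
uniform-proposal Metropolis move every sweep, and periodically a
rejection-free heat-bath (Gibbs) draw from the replica's full conditional
over all states.  The Gibbs move is what keeps the replica ensemble mixing
once the restraint tightens — with N replicas the data term scales every
single-replica energy change by N, and plain Metropolis proposals freeze.

The experimental restraint is attenuated by an exponent xi in [0, 1] on the
data term, which is what the free-energy score integrates over.

Likelihood codes: 0 = gaussian, 1 = good_bad, 2 = multi-severity.

Everything here is a private implementation detail; the public surface lives
in :mod:`fmbayes.sampler`.  The energy algebra is duplicated from
:mod:`fmbayes.likelihoods` for speed and is cross-checked against it in the
test suite: per-observable width sigma0_j = sqrt(sigma_B^2 + sem_j^2) (or
the sampled sigma_B alone when the width convention excludes the SEM), with
per-observable Heaviside gates at phi_m * sigma0_j.
"""

import numpy as np
from numba import njit

_LOG_2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def _log_weight(k, m, lik, M, phi_lv):
    if lik == 0:
        return 0.0
    if lik == 1:
        if m == 0:
            return np.log(0.5)
        return np.log(0.5) - np.log(phi_lv[k, 1])
    return -np.log(M)





@njit(cache=True)
def _data_energy(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                 count_mode, sem_w, K):
    """Data term of u: gated Gaussian scale mixture per observable.

    count_mode 0 usage ("evidence"): N * sum_j -ln(sum_m w_m N_m);
    count_mode 1 ("restraint"): sum_j -ln(sum_m w_m N_m^N).
    sigma0_j = sqrt(sigma_B[k]^2 + sem_j^2) per observable.
    """
    D = d.shape[0]
    rep = n_rep if count_mode == 1 else 1
    outer = n_rep if count_mode == 0 else 1
    u = 0.0
    for j in range(D):
        k = type_idx[j]
        s0sq = sigma[k] * sigma[k] + sem_w * sem[j] * sem[j]
        s0j = np.sqrt(s0sq)
        r = d[j] - g[j]
        mx = -1.0e308
        for m in range(M):
            lv = phi_lv[k, m]
            if sem[j] - lv * s0j > 0.0:
                continue
            var = lv * lv * s0sq
            la = (_log_weight(k, m, lik, M, phi_lv)
                  - rep * (0.5 * (_LOG_2PI + np.log(var))
                           + r * r / (2.0 * var)))
            if la > mx:
                mx = la
        if mx < -1.0e307:
            return np.inf
        s = 0.0
        for m in range(M):
            lv = phi_lv[k, m]
            if sem[j] - lv * s0j > 0.0:
                continue
            var = lv * lv * s0sq
            la = (_log_weight(k, m, lik, M, phi_lv)
                  - rep * (0.5 * (_LOG_2PI + np.log(var))
                           + r * r / (2.0 * var)))
            s += np.exp(la - mx)
        u -= outer * (mx + np.log(s))
    return u


@njit(cache=True)
def _grad_theta(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                count_mode, sem_w, mb2, mb1, grad, K):
    """du/dtheta per type into grad (K, 3); mb2/mb1 are replica-mean bases."""
    grad[:, :] = 0.0
    D = d.shape[0]
    rep = n_rep if count_mode == 1 else 1
    for j in range(D):
        k = type_idx[j]
        s0sq = sigma[k] * sigma[k] + sem_w * sem[j] * sem[j]
        s0j = np.sqrt(s0sq)
        r = d[j] - g[j]
        mx = -1.0e308
        for m in range(M):
            lv = phi_lv[k, m]
            if sem[j] - lv * s0j > 0.0:
                continue
            var = lv * lv * s0sq
            la = (_log_weight(k, m, lik, M, phi_lv)
                  - rep * (0.5 * (_LOG_2PI + np.log(var))
                           + r * r / (2.0 * var)))
            if la > mx:
                mx = la
        if mx < -1.0e307:
            continue
        num = 0.0
        den = 0.0
        for m in range(M):
            lv = phi_lv[k, m]
            if sem[j] - lv * s0j > 0.0:
                continue
            var = lv * lv * s0sq
            la = (_log_weight(k, m, lik, M, phi_lv)
                  - rep * (0.5 * (_LOG_2PI + np.log(var))
                           + r * r / (2.0 * var)))
            w = np.exp(la - mx)
            num += w / (lv * lv)
            den += w
        pull = -n_rep * (r / s0sq) * (num / den)
        grad[k, 0] += mb2[j] * pull
        grad[k, 1] += mb1[j] * pull
        grad[k, 2] += pull


@njit(cache=True)
def _state_predictions(cosx, c2, theta, type_idx, V):
    """V[s, j] = forward-model prediction of observable j in state s."""
    S, D = V.shape
    for j in range(D):
        k = type_idx[j]
        A = theta[k, 0]
        B = theta[k, 1]
        C = theta[k, 2]
        for s in range(S):
            V[s, j] = A * c2[s, j] + B * cosx[s, j] + C


@njit(cache=True)
def _replica_stats(V, states, g, sumP2, sem):
    """Refresh g, sum of squared per-replica predictions, and SEM."""
    N = states.shape[0]
    D = g.shape[0]
    for j in range(D):
        gs = 0.0
        s2 = 0.0
        for r in range(N):
            p = V[states[r], j]
            gs += p
            s2 += p * p
        g[j] = gs / N
        sumP2[j] = s2
        var = s2 / N - g[j] * g[j]
        if var < 0.0:
            var = 0.0
        sem[j] = np.sqrt(var / N)


@njit(cache=True)
def _basis_means(cosx, c2, states, mb1, mb2):
    N = states.shape[0]
    D = mb1.shape[0]
    for j in range(D):
        s1 = 0.0
        s2 = 0.0
        for r in range(N):
            s1 += cosx[states[r], j]
            s2 += c2[states[r], j]
        mb1[j] = s1 / N
        mb2[j] = s2 / N


@njit(cache=True)
def _gibbs_replica(V, log_pop, states, r_pick, g, sumP2, sem, d, type_idx,
                   sigma, phi_lv, lik, M, n_rep, count_mode, sem_w, K, xi,
                   cand_g, cand_sem, lw):
    """Heat-bath draw of replica r_pick's state from its full conditional.

    Returns the data energy of the chosen configuration (or the current one
    if every candidate is gated out).
    """
    S, D = V.shape
    N = states.shape[0]
    s_cur = states[r_pick]
    for s in range(S):
        if xi > 0.0:
            for j in range(D):
                p_new = V[s, j]
                p_old = V[s_cur, j]
                gj = g[j] + (p_new - p_old) / N
                s2 = sumP2[j] - p_old * p_old + p_new * p_new
                var = s2 / N - gj * gj
                if var < 0.0:
                    var = 0.0
                cand_g[j] = gj
                cand_sem[j] = np.sqrt(var / N)
            u_s = _data_energy(cand_g, cand_sem, d, type_idx, sigma, phi_lv,
                               lik, M, n_rep, count_mode, sem_w, K)
            lw[s] = log_pop[s] - xi * u_s
        else:
            lw[s] = log_pop[s]
    mx = lw[0]
    for s in range(1, S):
        if lw[s] > mx:
            mx = lw[s]
    if mx < -1.0e307:
        return _data_energy(g, sem, d, type_idx, sigma, phi_lv, lik, M,
                            n_rep, count_mode, sem_w, K)
    tot = 0.0
    for s in range(S):
        tot += np.exp(lw[s] - mx)
    target = np.random.random() * tot
    acc = 0.0
    s_new = S - 1
    for s in range(S):
        acc += np.exp(lw[s] - mx)
        if acc >= target:
            s_new = s
            break
    states[r_pick] = s_new
    for j in range(D):
        p_new = V[s_new, j]
        p_old = V[s_cur, j]
        g[j] += (p_new - p_old) / N
        sumP2[j] += p_new * p_new - p_old * p_old
        var = sumP2[j] / N - g[j] * g[j]
        if var < 0.0:
            var = 0.0
        sem[j] = np.sqrt(var / N)
    return _data_energy(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                        count_mode, sem_w, K)


@njit(cache=True)
def _pop_stats(V, w, n_rep, g, sem):
    """Deterministic prior-weighted ensemble average and its SEM proxy.

    g_j = sum_s w_s V[s, j]; sem_j = weighted prediction SD / sqrt(n_rep),
    the finite-sampling error an n_rep-replica average would carry.
    """
    S, D = V.shape
    for j in range(D):
        gs = 0.0
        s2 = 0.0
        for ss in range(S):
            gs += w[ss] * V[ss, j]
            s2 += w[ss] * V[ss, j] * V[ss, j]
        g[j] = gs
        var = s2 - gs * gs
        if var < 0.0:
            var = 0.0
        sem[j] = np.sqrt(var / n_rep)


@njit(cache=True)
def _pop_basis(cosx, c2, w, mb1, mb2):
    S, D = cosx.shape
    for j in range(D):
        s1 = 0.0
        s2 = 0.0
        for ss in range(S):
            s1 += w[ss] * cosx[ss, j]
            s2 += w[ss] * c2[ss, j]
        mb1[j] = s1
        mb2[j] = s2


@njit(cache=True)
def _pop_moments(cosx, c2, w, m11, m22, m12):
    """Population-weighted second moments of the Karplus basis (cos, cos^2).

    Because the prediction is linear in theta, the weighted mean and
    variance of the per-state predictions follow in closed form from these
    moments — no per-state recomputation is needed on theta moves.
    """
    S, D = cosx.shape
    for j in range(D):
        a = 0.0
        b = 0.0
        c = 0.0
        for ss in range(S):
            a += w[ss] * cosx[ss, j] * cosx[ss, j]
            b += w[ss] * c2[ss, j] * c2[ss, j]
            c += w[ss] * cosx[ss, j] * c2[ss, j]
        m11[j] = a
        m22[j] = b
        m12[j] = c


@njit(cache=True)
def _pop_update_type(theta, k, type_idx, mb1, mb2, m11, m22, m12, n_rep,
                     g, sem):
    """Closed-form g and SEM for type k's observables at the current theta."""
    D = g.shape[0]
    A = theta[k, 0]
    B = theta[k, 1]
    C = theta[k, 2]
    for j in range(D):
        if type_idx[j] != k:
            continue
        g[j] = A * mb2[j] + B * mb1[j] + C
        var = (A * A * (m22[j] - mb2[j] * mb2[j])
               + B * B * (m11[j] - mb1[j] * mb1[j])
               + 2.0 * A * B * (m12[j] - mb1[j] * mb2[j]))
        if var < 0.0:
            var = 0.0
        sem[j] = np.sqrt(var / n_rep)


@njit(cache=True)
def _gibbs_nuisance(grid, lo, hi, g, sem, d, type_idx, sigma, phi_lv,
                    lik, M, n_rep, count_mode, sem_w, K, xi, k, which_m,
                    lw_grid):
    """Heat-bath draw of sigma_B[k] (which_m < 0) or phi_lv[k, which_m]
    from its grid conditional; returns the new data energy."""
    G = grid.shape[0]
    for i in range(G):
        v = grid[i]
        if v < lo or v > hi:
            lw_grid[i] = -np.inf
            continue
        if which_m < 0:
            sv = sigma[k]
            sigma[k] = v
            u_i = _data_energy(g, sem, d, type_idx, sigma, phi_lv,
                               lik, M, n_rep, count_mode, sem_w, K)
            sigma[k] = sv
        else:
            pv = phi_lv[k, which_m]
            phi_lv[k, which_m] = v
            u_i = _data_energy(g, sem, d, type_idx, sigma, phi_lv,
                               lik, M, n_rep, count_mode, sem_w, K)
            phi_lv[k, which_m] = pv
        lw_grid[i] = -xi * u_i if xi > 0.0 else 0.0
    mx = -1.0e308
    for i in range(G):
        if lw_grid[i] > mx:
            mx = lw_grid[i]
    if mx < -1.0e307:
        u_keep = _data_energy(g, sem, d, type_idx, sigma, phi_lv,
                              lik, M, n_rep, count_mode, sem_w, K)
        return u_keep, -1
    tot = 0.0
    for i in range(G):
        tot += np.exp(lw_grid[i] - mx)
    target = np.random.random() * tot
    acc = 0.0
    pick = G - 1
    for i in range(G):
        acc += np.exp(lw_grid[i] - mx)
        if acc >= target:
            pick = i
            break
    if which_m < 0:
        sigma[k] = grid[pick]
    else:
        phi_lv[k, which_m] = grid[pick]
    u_new = _data_energy(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                         count_mode, sem_w, K)
    return u_new, pick


@njit(cache=True)
def _wls_theta(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep, count_mode,
               mb2, mb1, k, out):
    """Responsibility-weighted least-squares Karplus fit for type k.

    Solves the 3x3 normal equations of d ~ A <cos^2> + B <cos> + C with
    per-observable weights given by the current mixture responsibilities
    (outliers downweighted by R_j).  Used as a burn-in-only independence
    proposal that jumps theta into the data-supported basin.
    """
    D = d.shape[0]
    rep = n_rep if count_mode == 1 else 1
    ata = np.zeros((3, 3))
    atb = np.zeros(3)
    for j in range(D):
        if type_idx[j] != k:
            continue
        s0sq = sigma[k] * sigma[k] + sem_w * sem[j] * sem[j]
        s0j = np.sqrt(s0sq)
        r = d[j] - g[j]
        mx = -1.0e308
        for m in range(M):
            lv = phi_lv[k, m]
            if sem[j] - lv * s0j > 0.0:
                continue
            var = lv * lv * s0sq
            la = (_log_weight(k, m, lik, M, phi_lv)
                  - rep * (0.5 * (_LOG_2PI + np.log(var))
                           + r * r / (2.0 * var)))
            if la > mx:
                mx = la
        if mx < -1.0e307:
            continue
        num = 0.0
        den = 0.0
        for m in range(M):
            lv = phi_lv[k, m]
            if sem[j] - lv * s0j > 0.0:
                continue
            var = lv * lv * s0sq
            la = (_log_weight(k, m, lik, M, phi_lv)
                  - rep * (0.5 * (_LOG_2PI + np.log(var))
                           + r * r / (2.0 * var)))
            w = np.exp(la - mx)
            num += w / (lv * lv)
            den += w
        wj = (num / den) / s0sq
        b0 = mb2[j]
        b1 = mb1[j]
        ata[0, 0] += wj * b0 * b0
        ata[0, 1] += wj * b0 * b1
        ata[0, 2] += wj * b0
        ata[1, 1] += wj * b1 * b1
        ata[1, 2] += wj * b1
        ata[2, 2] += wj
        atb[0] += wj * b0 * d[j]
        atb[1] += wj * b1 * d[j]
        atb[2] += wj * d[j]
    ata[1, 0] = ata[0, 1]
    ata[2, 0] = ata[0, 2]
    ata[2, 1] = ata[1, 2]
    for i in range(3):
        ata[i, i] += 1e-9
    sol = np.linalg.solve(ata, atb)
    for i in range(3):
        out[i] = sol[i]


@njit(cache=True)
def _wls_system(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep, count_mode,
                sem_w, mb2, mb1, k, ata, atb):
    """Accumulate responsibility-weighted normal equations for type k."""
    D = d.shape[0]
    rep = n_rep if count_mode == 1 else 1
    for i in range(3):
        atb[i] = 0.0
        for jj in range(3):
            ata[i, jj] = 0.0
    for j in range(D):
        if type_idx[j] != k:
            continue
        s0sq = sigma[k] * sigma[k] + sem_w * sem[j] * sem[j]
        s0j = np.sqrt(s0sq)
        r = d[j] - g[j]
        mx = -1.0e308
        for m in range(M):
            lv = phi_lv[k, m]
            if sem[j] - lv * s0j > 0.0:
                continue
            var = lv * lv * s0sq
            la = (_log_weight(k, m, lik, M, phi_lv)
                  - rep * (0.5 * (_LOG_2PI + np.log(var))
                           + r * r / (2.0 * var)))
            if la > mx:
                mx = la
        if mx < -1.0e307:
            continue
        num = 0.0
        den = 0.0
        for m in range(M):
            lv = phi_lv[k, m]
            if sem[j] - lv * s0j > 0.0:
                continue
            var = lv * lv * s0sq
            la = (_log_weight(k, m, lik, M, phi_lv)
                  - rep * (0.5 * (_LOG_2PI + np.log(var))
                           + r * r / (2.0 * var)))
            w = np.exp(la - mx)
            num += w / (lv * lv)
            den += w
        wj = (num / den) / s0sq
        b0 = mb2[j]
        b1 = mb1[j]
        ata[0, 0] += wj * b0 * b0
        ata[0, 1] += wj * b0 * b1
        ata[0, 2] += wj * b0
        ata[1, 1] += wj * b1 * b1
        ata[1, 2] += wj * b1
        ata[2, 2] += wj
        atb[0] += wj * b0 * d[j]
        atb[1] += wj * b1 * d[j]
        atb[2] += wj * d[j]
    ata[1, 0] = ata[0, 1]
    ata[2, 0] = ata[0, 2]
    ata[2, 1] = ata[1, 2]
    for i in range(3):
        ata[i, i] += 1e-9


@njit(cache=True)
def _wls_proposal_params(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                         count_mode, sem_w, mb2, mb1, k, scale):
    """Center c, Cholesky factor L of the proposal covariance, and ln det.

    The proposal is N(c, (2/scale) * H^-1) with H = scale * A^T W A the
    local curvature of the theta conditional (the factor 2 widens it).
    Returns (c, L_cov, ln_det_cov, ok).
    """
    ata = np.empty((3, 3))
    atb = np.empty(3)
    _wls_system(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                count_mode, sem_w, mb2, mb1, k, ata, atb)
    c = np.linalg.solve(ata, atb)
    H = scale * ata / 2.0           # proposal covariance = (2/scale) inv(ata)
    cov = np.linalg.inv(H)
    ok = True
    for i in range(3):
        for jj in range(3):
            if not np.isfinite(cov[i, jj]):
                ok = False
    if not ok:
        return c, cov, 0.0, False
    # hand-rolled 3x3 Cholesky with a failure flag (no exceptions in nopython)
    L = np.zeros((3, 3))
    for i in range(3):
        for jj in range(i + 1):
            acc = cov[i, jj]
            for kk in range(jj):
                acc -= L[i, kk] * L[jj, kk]
            if i == jj:
                if acc <= 0.0:
                    return c, cov, 0.0, False
                L[i, i] = np.sqrt(acc)
            else:
                L[i, jj] = acc / L[jj, jj]
    ln_det = 0.0
    for i in range(3):
        ln_det += 2.0 * np.log(L[i, i])
    return c, L, ln_det, True


@njit(cache=True)
def _ln_gauss3(x, c, L, ln_det):
    """ln N(x; c, LL^T) up to the common (2 pi)^{-3/2} constant."""
    # solve L y = x - c
    y0 = (x[0] - c[0]) / L[0, 0]
    y1 = (x[1] - c[1] - L[1, 0] * y0) / L[1, 1]
    y2 = (x[2] - c[2] - L[2, 0] * y0 - L[2, 1] * y1) / L[2, 2]
    return -0.5 * (y0 * y0 + y1 * y1 + y2 * y2) - 0.5 * ln_det


@njit(cache=True)
def run_chain_kernel(cosx, c2, log_pop, d, type_idx, n_types, lik, M,
                     n_rep, count_mode, xi, pop_mode, pop_w,
                     theta_init, sigma_init, phi_init, states_init,
                     n_burn, n_prod, gibbs_every, nuisance_gibbs_every,
                     sigma_grid, phi_grid,
                     lrate, eta, step_theta, step_sigma, step_phi,
                     sigma_lo, sigma_hi, phi_hi, theta_lo, theta_hi,
                     anneal_burn, wls_jumps, sem_in_width,
                     seed, record_states):
    """Run one chain; returns production traces and acceptance statistics."""
    np.random.seed(seed)
    S, D = cosx.shape
    N = states_init.shape[0]
    K = n_types

    states = states_init.copy()
    theta = theta_init.copy()
    sigma = sigma_init.copy()
    phi_lv = phi_init.copy()
    # Width convention: 1.0 folds the per-observable SEM into the
    # likelihood width (the quadrature sigma0, the default); 0.0 uses the
    # sampled sigma alone with the SEM acting only through the gates —
    # population-mode studies over theta use the latter, because the
    # quadrature's N ln(sigma0) normalizer otherwise rewards flat curves
    # through their smaller prediction spread.  Replica mode always uses
    # the quadrature.
    sem_w = 1.0 if (sem_in_width or not pop_mode) else 0.0

    V = np.empty((S, D))
    _state_predictions(cosx, c2, theta, type_idx, V)
    g = np.empty(D)
    sumP2 = np.empty(D)
    sem = np.empty(D)
    mb1 = np.empty(D)
    mb2 = np.empty(D)
    pm11 = np.empty(D)
    pm22 = np.empty(D)
    pm12 = np.empty(D)
    if pop_mode:
        _pop_stats(V, pop_w, n_rep, g, sem)
        _pop_basis(cosx, c2, pop_w, mb1, mb2)
        _pop_moments(cosx, c2, pop_w, pm11, pm22, pm12)
    else:
        _replica_stats(V, states, g, sumP2, sem)
        _basis_means(cosx, c2, states, mb1, mb2)

    u_data = _data_energy(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                          count_mode, sem_w, K)
    u_prior = 0.0
    if not pop_mode:
        for r in range(N):
            u_prior -= log_pop[states[r]]

    grad = np.zeros((K, 3))

    # sigma and phi live on log-spaced grids; track indices for index-walk
    # proposals (a discretized log-space random walk)
    G_s = sigma_grid.shape[0]
    G_p = phi_grid.shape[0]
    dlog_s = np.log(sigma_grid[1] / sigma_grid[0]) if G_s > 1 else 1.0
    dlog_p = np.log(phi_grid[1] / phi_grid[0]) if G_p > 1 else 1.0
    if dlog_s <= 0.0:
        dlog_s = 1.0e12      # degenerate (pinned) grid: walk stays in place
    if dlog_p <= 0.0:
        dlog_p = 1.0e12
    sig_idx = np.empty(K, dtype=np.int64)
    phi_idx = np.zeros((K, M), dtype=np.int64)
    for k in range(K):
        best = 0
        for i in range(G_s):
            if abs(np.log(sigma_grid[i] / sigma[k])) <= \
               abs(np.log(sigma_grid[best] / sigma[k])):
                best = i
        sig_idx[k] = best
        sigma[k] = sigma_grid[best]
        for m in range(1, M):
            bestp = 0
            for i in range(G_p):
                if abs(np.log(phi_grid[i] / phi_lv[k, m])) <= \
                   abs(np.log(phi_grid[bestp] / phi_lv[k, m])):
                    bestp = i
            phi_idx[k, m] = bestp
            phi_lv[k, m] = phi_grid[bestp]
    u_data = _data_energy(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                          count_mode, sem_w, K)

    theta_tr = np.empty((n_prod, K, 3))
    sigma_tr = np.empty((n_prod, K))
    phi_tr = np.empty((n_prod, K, M))
    u_tr = np.empty(n_prod)
    uprior_tr = np.empty(n_prod)
    udata_tr = np.empty(n_prod)
    grad_tr = np.empty((n_prod, K, 3))
    if record_states:
        states_tr = np.empty((n_prod, N), dtype=np.int32)
    else:
        states_tr = np.empty((0, N), dtype=np.int32)
    # attempts / acceptances for move classes: replica, sigma, phi, theta
    acc = np.zeros((4, 2))

    theta_prop = np.empty(3)
    cand_g = np.empty(D)
    cand_sem = np.empty(D)
    lw = np.empty(S)
    lw_grid = np.empty(max(sigma_grid.shape[0], phi_grid.shape[0]))
    gibbs_replica = 0

    n_total = n_burn + n_prod
    for step in range(n_total):
        in_burn = step < n_burn
        # annealed restraint during early burn-in: ramp the data exponent
        # from 0 to xi over the first half of burn-in so chains from any
        # start funnel into the dominant basin before production
        if anneal_burn and in_burn and n_burn > 1:
            ramp = step / (0.5 * n_burn)
            xi_s = xi * (ramp if ramp < 1.0 else 1.0)
        else:
            xi_s = xi

        # --- replica state moves ------------------------------------------
        if gibbs_every > 0 and step % gibbs_every == 0:
            if not pop_mode:
                u_new = _gibbs_replica(V, log_pop, states, gibbs_replica, g,
                                       sumP2, sem, d, type_idx, sigma, phi_lv,
                                       lik, M, n_rep, count_mode, sem_w, K,
                                       xi_s, cand_g, cand_sem, lw)
                u_prior = 0.0
                for r in range(N):
                    u_prior -= log_pop[states[r]]
                u_data = u_new
                _basis_means(cosx, c2, states, mb1, mb2)
                gibbs_replica = (gibbs_replica + 1) % N
        if nuisance_gibbs_every > 0 and step % nuisance_gibbs_every == 0:
            for k in range(K):
                u_data, pick = _gibbs_nuisance(
                    sigma_grid, sigma_lo, sigma_hi, g, sem, d, type_idx,
                    sigma, phi_lv, lik, M, n_rep, count_mode, sem_w, K,
                    xi_s, k, -1, lw_grid)
                if pick >= 0:
                    sig_idx[k] = pick
                if lik > 0:
                    for m in range(1, M):
                        lo_m = phi_lv[k, m - 1]
                        hi_m = phi_hi if m == M - 1 else phi_lv[k, m + 1]
                        u_data, pick = _gibbs_nuisance(
                            phi_grid, lo_m, hi_m, g, sem, d, type_idx,
                            sigma, phi_lv, lik, M, n_rep, count_mode, sem_w,
                            K, xi_s, k, m, lw_grid)
                        if pick >= 0:
                            phi_idx[k, m] = pick
        r_pick = int(np.random.random() * N)
        s_new = int(np.random.random() * S)
        s_old = states[r_pick]
        if (not pop_mode) and s_new != s_old:
            acc[0, 0] += 1.0
            g_old = g.copy()
            sum_old = sumP2.copy()
            sem_old = sem.copy()
            for j in range(D):
                p_new = V[s_new, j]
                p_old = V[s_old, j]
                g[j] += (p_new - p_old) / N
                sumP2[j] += p_new * p_new - p_old * p_old
                var = sumP2[j] / N - g[j] * g[j]
                if var < 0.0:
                    var = 0.0
                sem[j] = np.sqrt(var / N)
            u_data_new = _data_energy(g, sem, d, type_idx, sigma, phi_lv,
                                      lik, M, n_rep, count_mode, sem_w, K)
            du = -log_pop[s_new] + log_pop[s_old]
            if xi_s > 0.0:
                du += xi_s * (u_data_new - u_data)
            if du <= 0.0 or np.random.random() < np.exp(-du):
                states[r_pick] = s_new
                u_data = u_data_new
                u_prior += -log_pop[s_new] + log_pop[s_old]
                for j in range(D):
                    mb1[j] += (cosx[s_new, j] - cosx[s_old, j]) / N
                    mb2[j] += (c2[s_new, j] - c2[s_old, j]) / N
                acc[0, 1] += 1.0
            else:
                g = g_old
                sumP2 = sum_old
                sem = sem_old

        # --- sigma_B moves (index walk on the log grid; the log-uniform
        # Jeffreys prior is flat over grid points) ---------------------------
        for k in range(K):
            acc[1, 0] += 1.0
            di = int(round(step_sigma / dlog_s * np.random.normal()))
            if di == 0:
                di = 1 if np.random.random() < 0.5 else -1
            jdx = sig_idx[k] + di
            if jdx < 0 or jdx >= G_s:
                continue
            s_save = sigma[k]
            sigma[k] = sigma_grid[jdx]
            u_data_new = _data_energy(g, sem, d, type_idx, sigma, phi_lv,
                                      lik, M, n_rep, count_mode, sem_w, K)
            du = xi_s * (u_data_new - u_data) if xi_s > 0.0 else 0.0
            if du <= 0.0 or np.random.random() < np.exp(-du):
                u_data = u_data_new
                sig_idx[k] = jdx
                acc[1, 1] += 1.0
            else:
                sigma[k] = s_save

        # --- phi moves (index walk on the log grid; skip for gaussian) -----
        if lik > 0:
            for k in range(K):
                for m in range(1, M):
                    acc[2, 0] += 1.0
                    di = int(round(step_phi / dlog_p * np.random.normal()))
                    if di == 0:
                        di = 1 if np.random.random() < 0.5 else -1
                    jdx = phi_idx[k, m] + di
                    if jdx < 0 or jdx >= G_p:
                        continue
                    p_prop = phi_grid[jdx]
                    if p_prop <= phi_lv[k, m - 1]:
                        continue  # keep levels strictly ordered, phi >= 1
                    if m == M - 1:
                        if p_prop > phi_hi:
                            continue
                    elif p_prop >= phi_lv[k, m + 1]:
                        continue
                    p_save = phi_lv[k, m]
                    phi_lv[k, m] = p_prop
                    u_data_new = _data_energy(g, sem, d, type_idx, sigma,
                                              phi_lv, lik, M, n_rep,
                                              count_mode, sem_w, K)
                    du = xi_s * (u_data_new - u_data) if xi_s > 0.0 else 0.0
                    if du <= 0.0 or np.random.random() < np.exp(-du):
                        u_data = u_data_new
                        phi_idx[k, m] = jdx
                        acc[2, 1] += 1.0
                    else:
                        phi_lv[k, m] = p_save

        # --- WLS independence jump for theta (population mode) -------------
        # a Hastings-corrected draw from the local weighted-least-squares
        # Gaussian approximation of theta's conditional; hops between
        # posterior basins that random walks cannot cross
        if wls_jumps and pop_mode and step_theta > 0.0 \
                and step % 20 == 17 and xi_s > 0.05:
            for k in range(K):
                scale = xi_s * n_rep
                # alternate tight draws (efficient local decorrelation) with
                # wide ones (reach across separated posterior basins)
                if (step // 20) % 2 == 1:
                    scale = scale / 30.0
                c_f, L_f, ld_f, ok_f = _wls_proposal_params(
                    g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                    count_mode, sem_w, mb2, mb1, k, scale)
                if not ok_f:
                    continue
                for i in range(3):
                    theta_prop[i] = c_f[i]
                z0 = np.random.normal()
                z1 = np.random.normal()
                z2 = np.random.normal()
                theta_prop[0] += L_f[0, 0] * z0
                theta_prop[1] += L_f[1, 0] * z0 + L_f[1, 1] * z1
                theta_prop[2] += (L_f[2, 0] * z0 + L_f[2, 1] * z1
                                  + L_f[2, 2] * z2)
                ok = True
                for i in range(3):
                    if theta_prop[i] < theta_lo or theta_prop[i] > theta_hi:
                        ok = False
                if not ok:
                    continue
                lq_fwd = _ln_gauss3(theta_prop, c_f, L_f, ld_f)
                theta_save = theta[k].copy()
                g_old = g.copy()
                sem_old = sem.copy()
                for i in range(3):
                    theta[k, i] = theta_prop[i]
                _pop_update_type(theta, k, type_idx, mb1, mb2,
                                 pm11, pm22, pm12, n_rep, g, sem)
                u_data_new = _data_energy(g, sem, d, type_idx, sigma, phi_lv,
                                          lik, M, n_rep, count_mode, sem_w, K)
                c_r, L_r, ld_r, ok_r = _wls_proposal_params(
                    g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                    count_mode, sem_w, mb2, mb1, k, scale)
                accept = False
                if ok_r and np.isfinite(u_data_new):
                    lq_rev = _ln_gauss3(theta_save, c_r, L_r, ld_r)
                    ln_a = -xi_s * (u_data_new - u_data) + lq_rev - lq_fwd
                    if ln_a >= 0.0 or np.random.random() < np.exp(ln_a):
                        accept = True
                if accept:
                    u_data = u_data_new
                else:
                    for i in range(3):
                        theta[k, i] = theta_save[i]
                    g = g_old
                    sem = sem_old

        # --- theta moves ---------------------------------------------------
        use_grad = in_burn and (lrate > 0.0 or eta > 0.0)
        if use_grad:
            _grad_theta(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                        count_mode, sem_w, mb2, mb1, grad, K)
        for k in range(K):
            acc[3, 0] += 1.0
            ok = True
            for i in range(3):
                if use_grad:
                    theta_prop[i] = (theta[k, i] - lrate * xi_s * grad[k, i]
                                     + eta * np.random.normal())
                else:
                    theta_prop[i] = theta[k, i] + step_theta * np.random.normal()
                if theta_prop[i] < theta_lo or theta_prop[i] > theta_hi:
                    ok = False
            if not ok:
                continue
            theta_save = theta[k].copy()
            g_old = g.copy()
            sum_old = sumP2.copy()
            sem_old = sem.copy()
            for i in range(3):
                theta[k, i] = theta_prop[i]
            if pop_mode:
                _pop_update_type(theta, k, type_idx, mb1, mb2,
                                 pm11, pm22, pm12, n_rep, g, sem)
            else:
                for j in range(D):
                    if type_idx[j] != k:
                        continue
                    for s in range(S):
                        V[s, j] = (theta[k, 0] * c2[s, j]
                                   + theta[k, 1] * cosx[s, j] + theta[k, 2])
                    gs = 0.0
                    s2 = 0.0
                    for rr in range(N):
                        p = V[states[rr], j]
                        gs += p
                        s2 += p * p
                    g[j] = gs / N
                    sumP2[j] = s2
                    var = s2 / N - g[j] * g[j]
                    if var < 0.0:
                        var = 0.0
                    sem[j] = np.sqrt(var / N)
            u_data_new = _data_energy(g, sem, d, type_idx, sigma, phi_lv,
                                      lik, M, n_rep, count_mode, sem_w, K)
            du = xi_s * (u_data_new - u_data) if xi_s > 0.0 else 0.0
            if du <= 0.0 or np.random.random() < np.exp(-du):
                u_data = u_data_new
                acc[3, 1] += 1.0
            else:
                for i in range(3):
                    theta[k, i] = theta_save[i]
                if not pop_mode:
                    for j in range(D):
                        if type_idx[j] != k:
                            continue
                        for s in range(S):
                            V[s, j] = (theta[k, 0] * c2[s, j]
                                       + theta[k, 1] * cosx[s, j]
                                       + theta[k, 2])
                g = g_old
                sumP2 = sum_old
                sem = sem_old

        # --- record --------------------------------------------------------
        if not in_burn:
            i_rec = step - n_burn
            for k in range(K):
                for i in range(3):
                    theta_tr[i_rec, k, i] = theta[k, i]
                sigma_tr[i_rec, k] = sigma[k]
                for m in range(M):
                    phi_tr[i_rec, k, m] = phi_lv[k, m]
            if xi > 0.0:
                u_tr[i_rec] = u_prior + xi * u_data
            else:
                u_tr[i_rec] = u_prior
            uprior_tr[i_rec] = u_prior
            udata_tr[i_rec] = u_data
            _grad_theta(g, sem, d, type_idx, sigma, phi_lv, lik, M, n_rep,
                        count_mode, sem_w, mb2, mb1, grad, K)
            for k in range(K):
                for i in range(3):
                    grad_tr[i_rec, k, i] = grad[k, i]
            if record_states:
                for r in range(N):
                    states_tr[i_rec, r] = states[r]

    return (theta_tr, sigma_tr, phi_tr, u_tr, uprior_tr, udata_tr,
            grad_tr, states_tr, acc)
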