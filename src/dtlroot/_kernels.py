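"""Compiled numerical core of the undated DTL reconciliation likelihood.

Everything here operates on flat arrays prepared by :mod:`dtlroot.treeio`:

* the rooted species tree as postorder ``child_left``/``child_right`` arrays
  (branch ``e`` is the edge above node ``e``; the stem branch is the last
  index);
* the unrooted gene tree as a message schedule over directed edges, so the
  likelihood vector of every gene clade is computed exactly once and shared
  by all gene-tree rootings.

Per event opportunity a gene lineage on species branch ``e`` undergoes
duplication (p_D), transfer to a uniformly chosen other branch (p_T), loss
(p_L) or speciation/observation (p_S).  The closure

    P(u, e) = A(u, e) / (1 - 2 p_D E_e - p_T Ebar_-e)

sums the geometric series of unobservable events (a duplication with one
extinct copy, a transfer whose recipient went extinct) on top of the visible
event terms in ``A``.
"""

import numpy as np
from numba import njit

NB_OPTS = dict(cache=True, fastmath=False)


@njit(**NB_OPTS)
def extinction_fixed_point(child_left, child_right, mvec,
                           pD, pT, pL, pS, tol, max_sweeps):
    """Fixed point of the per-branch extinction probabilities E_e.

    Leaf branch of species s:  E = p_L + p_D E^2 + p_T Ebar_-e E + p_S m_s
    Internal branch (kids f,g): E = p_L + p_D E^2 + p_T Ebar_-e E + p_S E_f E_g

    Iterated from all zeros (sweeps use already-updated children, which
    converges to the same fixed point) until the largest absolute change in
    one sweep drops below ``tol``.  Returns (E, n_sweeps, converged).
    """
    B = child_left.size
    E = np.zeros(B)
    for sweep in range(max_sweeps):
        S = 0.0
        for e in range(B):
            S += E[e]
        maxdiff = 0.0
        for e in range(B):
            Em = (S - E[e]) / (B - 1)
            f = child_left[e]
            if f < 0:
                term = pS * mvec[e]
            else:
                term = pS * E[f] * E[child_right[e]]
            newE = pL + pD * E[e] * E[e] + pT * Em * E[e] + term
            if newE > 1.0:
                newE = 1.0
            d = abs(newE - E[e])
            if d > maxdiff:
                maxdiff = d
            E[e] = newE
        if maxdiff < tol:
            return E, sweep + 1, True
    return E, max_sweeps, False


@njit(inline="always", **NB_OPTS)
def _combine(Aev, Pv, Pw, Sv, Sw, child_left, child_right, pD, pT, pS):
    """Event terms A(u, e) for a gene node whose child clades have vectors
    Pv, Pw; written into the ``Aev`` workspace."""
    B = Pv.size
    inv = 1.0 / (B - 1)
    for e in range(B):
        a = pD * Pv[e] * Pw[e] \
            + pT * (Pv[e] * (Sw - Pw[e]) + Pw[e] * (Sv - Pv[e])) * inv
        f = child_left[e]
        if f >= 0:
            g = child_right[e]
            a += pS * (Pv[f] * Pw[g] + Pv[g] * Pw[f])
        Aev[e] = a


@njit(inline="always", **NB_OPTS)
def _sweep_given_sum(P, Aev, child_left, child_right, E, denom, pS, pT, U):
    """One exact triangular pass of the closure given the vector sum U.

    The donor-extinct transfer term p_T E_e (U - P_e)/(B-1) couples every
    branch to the sum; for a *given* U its own -P_e part moves into the
    denominator, and the speciation-loss propagation only references child
    branches, so a single postorder pass resolves P exactly.  Returns the
    resulting sum of P.
    """
    B = Aev.size
    inv = 1.0 / (B - 1)
    S = 0.0
    for e in range(B):
        A = Aev[e]
        f = child_left[e]
        if f >= 0:
            g = child_right[e]
            A += pS * (P[f] * E[g] + P[g] * E[f])
        A += pT * E[e] * U * inv
        P[e] = A / (denom[e] + pT * E[e] * inv)
        S += P[e]
    return S


@njit(inline="always", **NB_OPTS)
def _solve_clade(P, Pprev, Aev, child_left, child_right, E, denom, pS, pT,
                 tol, max_sweeps):
    """Resolve P(u, .) from its event terms, into the ``P`` workspace.

    The fixed point couples each branch to the sum U of the whole vector,
    but P(U) is affine in U, so U* is found exactly from the passes at U = 0
    and U = 1 and one final pass evaluates P(U*).  Falls back to plain
    sweeping in the (unreachable for sub-unit event probabilities) case of a
    non-contractive coupling.
    """
    B = Aev.size
    a = _sweep_given_sum(P, Aev, child_left, child_right, E, denom, pS, pT, 0.0)
    b = _sweep_given_sum(Pprev, Aev, child_left, child_right, E, denom, pS, pT, 1.0) - a
    if b < 1.0 - 1e-12:
        U = a / (1.0 - b)
        _sweep_given_sum(P, Aev, child_left, child_right, E, denom, pS, pT, U)
        return
    U = a
    for _ in range(max_sweeps):
        Unew = _sweep_given_sum(P, Aev, child_left, child_right, E, denom,
                                pS, pT, U)
        if abs(Unew - U) < tol:
            break
        U = Unew


@njit(**NB_OPTS)
def family_loglik_kernel(child_left, child_right, mvec, spbranch,
                         order, leafsp, dep1, dep2, n_edges,
                         pD, pT, pL, pS, include_stem,
                         tol_inner, max_inner, tol_ext, max_ext):
    """Marginal log-likelihood of one gene family on one rooted species tree.

    Sums P(root, e) over all gene-tree rootings (one per gene-tree edge) and
    all origination branches e, divides by the number of origination
    branches, and conditions on non-extinction.  Per-message scaling keeps
    every stored vector O(1), so families of hundreds of leaves stay finite.

    Returns (status, loglik): status 0 = ok (loglik may be -inf for a
    zero-probability family), 1 = extinction non-convergence, 2 = degenerate
    closure denominator.
    """
    B = child_left.size
    E, _, ok = extinction_fixed_point(child_left, child_right, mvec,
                                      pD, pT, pL, pS, tol_ext, max_ext)
    if not ok:
        return 1, np.nan
    SE = 0.0
    for e in range(B):
        SE += E[e]
    denom = np.empty(B)
    for e in range(B):
        Em = (SE - E[e]) / (B - 1)
        d = 1.0 - 2.0 * pD * E[e] - pT * Em
        if d < 1e-9:
            return 2, np.nan
        denom[e] = d

    nmsg = 2 * n_edges
    M = np.zeros((nmsg, B))
    Msum = np.zeros(nmsg)
    Mlog = np.zeros(nmsg)
    Aev = np.empty(B)
    P = np.empty(B)
    Pprev = np.empty(B)
    for oi in range(nmsg):
        m = order[oi]
        if leafsp[m] >= 0:
            for e in range(B):
                Aev[e] = 0.0
            b = spbranch[leafsp[m]]
            Aev[b] = pS * (1.0 - mvec[b])
            logbase = 0.0
        else:
            d1 = dep1[m]
            d2 = dep2[m]
            if np.isinf(Mlog[d1]) or np.isinf(Mlog[d2]):
                Mlog[m] = -np.inf
                continue
            _combine(Aev, M[d1], M[d2], Msum[d1], Msum[d2],
                     child_left, child_right, pD, pT, pS)
            logbase = Mlog[d1] + Mlog[d2]
        _solve_clade(P, Pprev, Aev, child_left, child_right, E, denom, pS, pT,
                     tol_inner, max_inner)
        c = P.max()
        if c <= 0.0:
            Mlog[m] = -np.inf
            continue
        s = 0.0
        for e in range(B):
            v = P[e] / c
            s += v
            M[m, e] = v
        Msum[m] = s
        Mlog[m] = np.log(c) + logbase

    n_orig = B if include_stem else B - 1
    vals = np.full(n_edges, -np.inf)
    for i in range(n_edges):
        m1 = 2 * i
        m2 = 2 * i + 1
        if np.isinf(Mlog[m1]) or np.isinf(Mlog[m2]):
            continue
        _combine(Aev, M[m1], M[m2], Msum[m1], Msum[m2],
                 child_left, child_right, pD, pT, pS)
        _solve_clade(P, Pprev, Aev, child_left, child_right, E, denom, pS, pT,
                     tol_inner, max_inner)
        tot = 0.0
        for e in range(n_orig):
            tot += P[e]
        if tot > 0.0:
            vals[i] = np.log(tot) + Mlog[m1] + Mlog[m2]

    vmax = -np.inf
    for i in range(n_edges):
        if vals[i] > vmax:
            vmax = vals[i]
    if vmax == -np.inf:
        return 0, -np.inf  # infeasible under these rates
    acc = 0.0
    for i in range(n_edges):
        acc += np.exp(vals[i] - vmax)
    loglik = vmax + np.log(acc)

    Ebar = 0.0
    for e in range(n_orig):
        Ebar += E[e]
    Ebar /= n_orig
    if Ebar >= 1.0 - 1e-15:
        return 0, -np.inf
    return 0, loglik - np.log(n_orig) - np.log1p(-Ebar)


# ---------------------------------------------------------------------------
# compiled optimisers (the objective is family_loglik_kernel itself)
# ---------------------------------------------------------------------------


@njit(**NB_OPTS)
def _neg_loglik(x0, x1, x2, lo, hi,
                child_left, child_right, mvec, spbranch,
                order, leafsp, dep1, dep2, n_edges, include_stem,
                tol_inner, max_inner, tol_ext, max_ext):
    """Negative log-likelihood at log10 rates (x0, x1, x2), box-clipped."""
    if x0 < lo:
        x0 = lo
    elif x0 > hi:
        x0 = hi
    if x1 < lo:
        x1 = lo
    elif x1 > hi:
        x1 = hi
    if x2 < lo:
        x2 = lo
    elif x2 > hi:
        x2 = hi
    delta = 10.0 ** x0
    tau = 10.0 ** x1
    lam = 10.0 ** x2
    W = delta + tau + lam + 1.0
    status, ll = family_loglik_kernel(
        child_left, child_right, mvec, spbranch,
        order, leafsp, dep1, dep2, n_edges,
        delta / W, tau / W, lam / W, 1.0 / W, include_stem,
        tol_inner, max_inner, tol_ext, max_ext)
    if status != 0 or np.isnan(ll) or np.isinf(ll):
        return 1e12
    return -ll


@njit(**NB_OPTS)
def nelder_mead_rates(x_init, step, lo, hi, fatol, xatol, maxfev,
                      child_left, child_right, mvec, spbranch,
                      order, leafsp, dep1, dep2, n_edges, include_stem,
                      tol_inner, max_inner, tol_ext, max_ext):
    """Nelder-Mead over log10 (delta, tau, lambda).

    Standard reflection/expansion/contraction/shrink coefficients; the
    simplex starts at ``x_init`` with one vertex displaced by ``step`` per
    coordinate.  Terminates when the function spread is below ``fatol`` and
    the coordinate spread below ``xatol``, or at ``maxfev`` evaluations.
    Returns (x_best, f_best, nfev, converged).
    """
    n = 3
    sim = np.empty((n + 1, n))
    fs = np.empty(n + 1)
    for j in range(n):
        sim[0, j] = x_init[j]
    for i in range(n):
        for j in range(n):
            sim[i + 1, j] = x_init[j]
        sim[i + 1, i] += step
    nfev = 0
    for i in range(n + 1):
        fs[i] = _neg_loglik(sim[i, 0], sim[i, 1], sim[i, 2], lo, hi,
                            child_left, child_right, mvec, spbranch,
                            order, leafsp, dep1, dep2, n_edges, include_stem,
                            tol_inner, max_inner, tol_ext, max_ext)
        nfev += 1
    converged = False
    while nfev < maxfev:
        # order simplex
        idx = np.argsort(fs)
        sim = sim[idx]
        fs = fs[idx]
        fspread = fs[n] - fs[0]
        xspread = 0.0
        for i in range(1, n + 1):
            for j in range(n):
                d = abs(sim[i, j] - sim[0, j])
                if d > xspread:
                    xspread = d
        if fspread <= fatol and xspread <= xatol:
            converged = True
            break
        # centroid of the n best
        cen = np.zeros(n)
        for i in range(n):
            for j in range(n):
                cen[j] += sim[i, j]
        for j in range(n):
            cen[j] /= n
        # reflection
        xr = np.empty(n)
        for j in range(n):
            xr[j] = cen[j] + (cen[j] - sim[n, j])
        fr = _neg_loglik(xr[0], xr[1], xr[2], lo, hi,
                         child_left, child_right, mvec, spbranch,
                         order, leafsp, dep1, dep2, n_edges, include_stem,
                         tol_inner, max_inner, tol_ext, max_ext)
        nfev += 1
        if fr < fs[0]:
            # expansion
            xe = np.empty(n)
            for j in range(n):
                xe[j] = cen[j] + 2.0 * (cen[j] - sim[n, j])
            fe = _neg_loglik(xe[0], xe[1], xe[2], lo, hi,
                             child_left, child_right, mvec, spbranch,
                             order, leafsp, dep1, dep2, n_edges, include_stem,
                             tol_inner, max_inner, tol_ext, max_ext)
            nfev += 1
            if fe < fr:
                sim[n] = xe
                fs[n] = fe
            else:
                sim[n] = xr
                fs[n] = fr
            continue
        if fr < fs[n - 1]:
            sim[n] = xr
            fs[n] = fr
            continue
        # contraction
        xc = np.empty(n)
        if fr < fs[n]:
            for j in range(n):
                xc[j] = cen[j] + 0.5 * (xr[j] - cen[j])
        else:
            for j in range(n):
                xc[j] = cen[j] + 0.5 * (sim[n, j] - cen[j])
        fc = _neg_loglik(xc[0], xc[1], xc[2], lo, hi,
                         child_left, child_right, mvec, spbranch,
                         order, leafsp, dep1, dep2, n_edges, include_stem,
                         tol_inner, max_inner, tol_ext, max_ext)
        nfev += 1
        if fc < min(fr, fs[n]):
            sim[n] = xc
            fs[n] = fc
            continue
        # shrink towards the best vertex
        for i in range(1, n + 1):
            for j in range(n):
                sim[i, j] = sim[0, j] + 0.5 * (sim[i, j] - sim[0, j])
            fs[i] = _neg_loglik(sim[i, 0], sim[i, 1], sim[i, 2], lo, hi,
                                child_left, child_right, mvec, spbranch,
                                order, leafsp, dep1, dep2, n_edges,
                                include_stem,
                                tol_inner, max_inner, tol_ext, max_ext)
            nfev += 1
    ib = np.argmin(fs)
    xb = np.empty(n)
    for j in range(n):
        v = sim[ib, j]
        if v < lo:
            v = lo
        elif v > hi:
            v = hi
        xb[j] = v
    return xb, fs[ib], nfev, converged


@njit(**NB_OPTS)
def golden_loss_rate(logd, logt, lo, hi, xatol, maxfev,
                     child_left, child_right, mvec, spbranch,
                     order, leafsp, dep1, dep2, n_edges, include_stem,
                     tol_inner, max_inner, tol_ext, max_ext):
    """Golden-section profile of the loss rate at fixed duplication/transfer.

    Searches log10 lambda in [lo, hi]; returns (log_lam, f, nfev, converged).
    """
    invphi = 0.6180339887498949
    a = lo
    b = hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _neg_loglik(logd, logt, c, lo, hi,
                     child_left, child_right, mvec, spbranch,
                     order, leafsp, dep1, dep2, n_edges, include_stem,
                     tol_inner, max_inner, tol_ext, max_ext)
    fd = _neg_loglik(logd, logt, d, lo, hi,
                     child_left, child_right, mvec, spbranch,
                     order, leafsp, dep1, dep2, n_edges, include_stem,
                     tol_inner, max_inner, tol_ext, max_ext)
    nfev = 2
    while b - a > xatol and nfev < maxfev:
        if fc < fd:
            b = d
            d = c
            fd = fc
            c = b - invphi * (b - a)
            fc = _neg_loglik(logd, logt, c, lo, hi,
                             child_left, child_right, mvec, spbranch,
                             order, leafsp, dep1, dep2, n_edges, include_stem,
                             tol_inner, max_inner, tol_ext, max_ext)
        else:
            a = c
            c = d
            fc = fd
            d = a + invphi * (b - a)
            fd = _neg_loglik(logd, logt, d, lo, hi,
                             child_left, child_right, mvec, spbranch,
                             order, leafsp, dep1, dep2, n_edges, include_stem,
                             tol_inner, max_inner, tol_ext, max_ext)
        nfev += 1
    x = c if fc < fd else d
    f = fc if fc < fd else fd
    return x, f, nfev, b - a <= xatol
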