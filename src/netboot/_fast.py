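"""Numba kernels for the estimation hot path.

Bootstrap and simulation workloads re-estimate the network tens of
thousands of times, so the three inner loops — two-step polychoric
correlation, the graphical-lasso path, and weighted shortest-path
centrality — are compiled with numba.  Each kernel is cross-checked
against an independent reference (scipy / scikit-learn / brute force)
in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# 16-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W

_SQRT2 = math.sqrt(2.0)
_INV2PI = 1.0 / (2.0 * math.pi)


@njit(cache=True)
def norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True)
def bvn_cdf(h, k, rho, gl_x, gl_w):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the single integral over the correlation parameter:
    Phi2(h, k, rho) = Phi(h) Phi(k) + (2 pi)^-1 int_0^rho
        exp(-(h^2 - 2 r h k + k^2) / (2 (1 - r^2))) / sqrt(1 - r^2) dr,
    evaluated by fixed Gauss-Legendre quadrature.  Accurate to ~1e-10
    for |rho| <= 0.999, which the polychoric optimizer never exceeds.
    """
    if h == np.inf:
        if k == np.inf:
            return 1.0
        return norm_cdf(k)
    if k == np.inf:
        return norm_cdf(h)
    if h == -np.inf or k == -np.inf:
        return 0.0
    acc = 0.0
    for i in range(gl_x.shape[0]):
        r = rho * gl_x[i]
        om = 1.0 - r * r
        acc += gl_w[i] * math.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * om)) / math.sqrt(om)
    return norm_cdf(h) * norm_cdf(k) + rho * _INV2PI * acc


@njit(cache=True)
def _table_loglik(table, tx, ty, kx, ky, rho, gl_x, gl_w):
    """Log-likelihood of a kx x ky contingency table under the bivariate
    normal with fixed thresholds tx (kx-1 finite values) and ty."""
    # CDF at every corner of the threshold grid
    cdf = np.empty((kx + 1, ky + 1))
    for i in range(kx + 1):
        h = -np.inf if i == 0 else (np.inf if i == kx else tx[i - 1])
        for j in range(ky + 1):
            k = -np.inf if j == 0 else (np.inf if j == ky else ty[j - 1])
            cdf[i, j] = bvn_cdf(h, k, rho, gl_x, gl_w)
    ll = 0.0
    for i in range(kx):
        for j in range(ky):
            pij = cdf[i + 1, j + 1] - cdf[i, j + 1] - cdf[i + 1, j] + cdf[i, j]
            if pij < 1e-14:
                pij = 1e-14
            ll += table[i, j] * math.log(pij)
    return ll


@njit(cache=True)
def polychoric_rho(table, tx, ty, kx, ky, rho_max, gl_x, gl_w):
    """Maximize the fixed-threshold likelihood over rho by golden section.

    The profile likelihood in rho is unimodal; 40 golden-section
    iterations shrink the bracket below 1e-8.
    """
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a = -rho_max
    b = rho_max
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _table_loglik(table, tx, ty, kx, ky, c, gl_x, gl_w)
    fd = _table_loglik(table, tx, ty, kx, ky, d, gl_x, gl_w)
    for _ in range(40):
        if fc > fd:
            b = d
            d = c
            fd = fc
            c = b - invphi * (b - a)
            fc = _table_loglik(table, tx, ty, kx, ky, c, gl_x, gl_w)
        else:
            a = c
            c = d
            fc = fd
            d = a + invphi * (b - a)
            fd = _table_loglik(table, tx, ty, kx, ky, d, gl_x, gl_w)
    return 0.5 * (a + b)


@njit(cache=True)
def polychoric_pairs(codes, ncat, thresholds, rho_max, continuity, gl_x, gl_w):
    """All pairwise polychoric correlations of integer-coded data.

    codes: (n, p) int64, category codes 0..ncat[j]-1, -1 = missing
    ncat: (p,) number of observed categories per column
    thresholds: (p, max_k - 1) marginal thresholds, padded with nan
    Returns a (p, p) correlation matrix (unit diagonal); pairs are
    handled pairwise-complete.
    """
    n, p = codes.shape
    out = np.eye(p)
    maxk = int(np.max(ncat))
    for a in range(p):
        for b in range(a + 1, p):
            ka = int(ncat[a])
            kb = int(ncat[b])
            table = np.zeros((maxk, maxk))
            for i in range(n):
                ca = codes[i, a]
                cb = codes[i, b]
                if ca >= 0 and cb >= 0:
                    table[ca, cb] += 1.0
            if continuity:
                has_zero = False
                for i in range(ka):
                    for j in range(kb):
                        if table[i, j] == 0.0:
                            has_zero = True
                if has_zero:
                    for i in range(ka):
                        for j in range(kb):
                            table[i, j] += 0.5
            rho = polychoric_rho(
                table[:ka, :kb], thresholds[a], thresholds[b], ka, kb, rho_max, gl_x, gl_w
            )
            out[a, b] = rho
            out[b, a] = rho
    return out


# ---------------------------------------------------------------------------
# graphical lasso
# ---------------------------------------------------------------------------


@njit(cache=True)
def _glasso_one(S, lam, W, B, max_iter, tol):
    """One graphical-lasso solve (block coordinate descent, Friedman et al.
    algorithm) warm-started from covariance estimate W and per-column lasso
    coefficients B.  Diagonal is not penalized.  Updates W and B in place;
    returns the precision matrix."""
    p = S.shape[0]
    # mean absolute off-diagonal of S sets the convergence scale
    s_off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_off += abs(S[i, j])
    s_off /= p * (p - 1)
    thr = tol * max(s_off, 1e-12)

    idx = np.empty(p - 1, np.int64)
    for it in range(max_iter):
        delta = 0.0
        for j in range(p):
            m = 0
            for i in range(p):
                if i != j:
                    idx[m] = i
                    m += 1
            # lasso: min 0.5 b' W11 b - b' s12 + lam |b|_1
            beta = B[:, j]
            for _inner in range(100):
                d_in = 0.0
                for a in range(p - 1):
                    ia = idx[a]
                    g = S[ia, j]
                    for c in range(p - 1):
                        if c != a:
                            g -= W[ia, idx[c]] * beta[c]
                    if g > lam:
                        bnew = (g - lam) / W[ia, ia]
                    elif g < -lam:
                        bnew = (g + lam) / W[ia, ia]
                    else:
                        bnew = 0.0
                    ch = abs(bnew - beta[a])
                    if ch > d_in:
                        d_in = ch
                    beta[a] = bnew
                if d_in < 1e-3 * thr + 1e-12:
                    break
            for a in range(p - 1):
                ia = idx[a]
                w_new = 0.0
                for c in range(p - 1):
                    w_new += W[ia, idx[c]] * beta[c]
                ch = abs(w_new - W[ia, j])
                if ch > delta:
                    delta = ch
                W[ia, j] = w_new
                W[j, ia] = w_new
        if delta < thr:
            break

    # recover precision from W and B
    K = np.zeros((p, p))
    for j in range(p):
        m = 0
        wb = 0.0
        for i in range(p):
            if i != j:
                idx[m] = i
                m += 1
        for a in range(p - 1):
            wb += W[idx[a], j] * B[a, j]
        kjj = 1.0 / (W[j, j] - wb)
        K[j, j] = kjj
        for a in range(p - 1):
            K[idx[a], j] = -B[a, j] * kjj
    # symmetrize (numerically, the two estimates of k_ij agree to solver tol)
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            # preserve exact zeros from the soft threshold
            if K[i, j] == 0.0 and K[j, i] == 0.0:
                v = 0.0
            K[i, j] = v
            K[j, i] = v
    return K


@njit(cache=True)
def glasso_path(S, lambdas, max_iter, tol):
    """Graphical lasso along a decreasing lambda grid with warm starts.

    Returns (n_lambda, p, p) precision matrices.
    """
    p = S.shape[0]
    nl = lambdas.shape[0]
    out = np.empty((nl, p, p))
    W = S.copy()
    B = np.zeros((p - 1, p))
    for li in range(nl):
        out[li] = _glasso_one(S, lambdas[li], W, B, max_iter, tol)
    return out


# ---------------------------------------------------------------------------
# weighted shortest paths and betweenness
# ---------------------------------------------------------------------------


@njit(cache=True)
def dijkstra_all(lengths):
    """All-pairs shortest-path distances on a dense non-negative length
    matrix (np.inf = no direct edge).  O(p^3) selection-based Dijkstra —
    optimal for the small graphs used here."""
    p = lengths.shape[0]
    dist = np.full((p, p), np.inf)
    for s in range(p):
        d = dist[s]
        d[s] = 0.0
        done = np.zeros(p, np.bool_)
        for _ in range(p):
            u = -1
            best = np.inf
            for v in range(p):
                if not done[v] and d[v] < best:
                    best = d[v]
                    u = v
            if u < 0:
                break
            done[u] = True
            for v in range(p):
                if not done[v] and lengths[u, v] < np.inf:
                    nd = d[u] + lengths[u, v]
                    if nd < d[v] - 1e-12:
                        d[v] = nd
    return dist


@njit(cache=True)
def betweenness(lengths):
    """Brandes betweenness on a dense weighted graph: for each node the sum
    over ordered source/target pairs of the fraction of shortest paths
    through it, halved to count unordered pairs.  Endpoints excluded; ties
    get fractional credit."""
    p = lengths.shape[0]
    bc = np.zeros(p)
    rtol = 1e-9
    for s in range(p):
        d = np.full(p, np.inf)
        sigma = np.zeros(p)
        d[s] = 0.0
        sigma[s] = 1.0
        done = np.zeros(p, np.bool_)
        order = np.empty(p, np.int64)
        cnt = 0
        for _ in range(p):
            u = -1
            best = np.inf
            for v in range(p):
                if not done[v] and d[v] < best:
                    best = d[v]
                    u = v
            if u < 0:
                break
            done[u] = True
            order[cnt] = u
            cnt += 1
            for v in range(p):
                if done[v] or lengths[u, v] == np.inf:
                    continue
                nd = d[u] + lengths[u, v]
                if nd < d[v] * (1.0 - rtol) - 1e-300:
                    d[v] = nd
                    sigma[v] = sigma[u]
                elif abs(nd - d[v]) <= rtol * d[v]:
                    sigma[v] += sigma[u]
        # accumulate dependencies in reverse order of settlement
        delta = np.zeros(p)
        for i in range(cnt - 1, -1, -1):
            w = order[i]
            if w == s:
                continue
            # predecessors of w: u with d[u] + len(u,w) == d[w]
            for u in range(p):
                if u == w or lengths[u, w] == np.inf:
                    continue
                if abs(d[u] + lengths[u, w] - d[w]) <= rtol * max(d[w], 1.0):
                    delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
        for v in range(p):
            if v != s:
                bc[v] += delta[v]
    return bc / 2.0
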