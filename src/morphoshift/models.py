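"""Fully multivariate evolutionary model fitting and stochastic character mapping.

Models for a species-by-traits matrix on a time-calibrated tree:

* BM  - single-rate Brownian motion with a full symmetric rate matrix R.
* EB  - early burst: BM with rates decaying e^{r t}, r <= 0.
* OU1 - single-optimum Ornstein-Uhlenbeck with symmetric selection matrix A
        and symmetric R (root state at the optimum).
* OUM - multi-peak OU on a regime painting (from a shift configuration or a
        stochastic character map); default structure is per-trait diagonal A
        and R with a separately estimated root state, a full symmetric
        structure is available.

Model support is compared with small-sample corrected AICc using
n = (number of tips) x (number of traits).  Discrete regimes (diet,
echolocation emission type) are reconstructed by stochastic character
mapping under an Mk model, and painting-distribution models are summarized
as median (min, max) over maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, expm
from scipy.optimize import minimize, minimize_scalar

from .regimes import RegimePainting
from .trees import PhyloTree

__all__ = ["ModelFit", "MkModel", "aicc", "fit_bm", "fit_ou1", "fit_eb",
           "fit_oum", "simmap", "fit_mk", "mk_node_marginals", "compare_models"]


@dataclass
class ModelFit:
    kind: str
    k: int
    loglik: float
    aicc: float
    n_obs: int
    n_regimes: int = 1
    params: dict = field(default_factory=dict)
    painting_source: str | None = None


def aicc(logL: float, k: int, n_obs: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n_obs <= k + 1:
        raise ValueError("n_obs must exceed k + 1")
    return float(-2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1))


# ------------------------------------------------------------- BM / EB fits

def _safe_aicc(ll: float, k: int, n_obs: int) -> float:
    """AICc, or NaN on fixtures too small for the correction term."""
    return aicc(ll, k, n_obs) if n_obs > k + 1 else float("nan")


def _prep(tree: PhyloTree, traits: np.ndarray, species):
    X = np.asarray(traits, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    species = list(species or tree.tip_labels)
    idx_in = {l: i for i, l in enumerate(species)}
    X = X[[idx_in[l] for l in tree.tip_labels]]
    return X


def _matrix_normal_ml(C: np.ndarray, X: np.ndarray):
    """ML root a and rate matrix R for X ~ MN(1a', C, R); returns (a, R, logL)."""
    n, p = X.shape
    cf = cho_factor(C, lower=True)
    logdetC = 2.0 * np.log(np.diag(cf[0])).sum()
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    a = (X.T @ Ci1) / (one @ Ci1)
    Xc = X - a
    R = Xc.T @ cho_solve(cf, Xc) / n
    R = 0.5 * (R + R.T)
    sign, logdetR = np.linalg.slogdet(R + 1e-300 * np.eye(p))
    ll = -0.5 * (n * p * np.log(2 * np.pi) + p * logdetC + n * logdetR + n * p)
    return a, R, float(ll)


def fit_bm(tree: PhyloTree, traits: np.ndarray,
           species: list[str] | None = None) -> ModelFit:
    """Single-rate multivariate Brownian motion (closed-form ML).

    k = p (root states) + p(p+1)/2 (symmetric rate matrix)."""
    X = _prep(tree, traits, species)
    n, p = X.shape
    a, R, ll = _matrix_normal_ml(tree.vcv, X)
    k = p + p * (p + 1) // 2
    return ModelFit(kind="BM", k=k, loglik=ll, aicc=_safe_aicc(ll, k, n * p),
                    n_obs=n * p, params={"root": a, "rate_matrix": R})


def _eb_vcv(tree: PhyloTree, r: float) -> np.ndarray:
    """BM covariance with branch segments scaled by e^{r t} integrated in time."""
    branches = tree.branch_nodes
    depths = tree.depths
    t0 = depths[tree.parent[branches]]
    t1 = depths[branches]
    if abs(r) < 1e-12:
        w = t1 - t0
    else:
        w = (np.exp(r * t1) - np.exp(r * t0)) / r
    m = tree.tip_masks[branches].astype(float)
    return np.einsum("b,bi,bj->ij", w, m, m)


def fit_eb(tree: PhyloTree, traits: np.ndarray,
           species: list[str] | None = None) -> ModelFit:
    """Early burst: exponentially decaying Brownian rate, decay r in [-10/T, 0].

    k = p + p(p+1)/2 + 1."""
    X = _prep(tree, traits, species)
    n, p = X.shape
    T = tree.depth

    def nll(r: float) -> float:
        return -_matrix_normal_ml(_eb_vcv(tree, r), X)[2]

    res = minimize_scalar(nll, bounds=(-10.0 / T, 0.0), method="bounded",
                          options={"xatol": 1e-8})
    r = float(res.x)
    if nll(0.0) <= res.fun:   # r = 0 nests BM exactly
        r = 0.0
    a, R, ll = _matrix_normal_ml(_eb_vcv(tree, r), X)
    k = p + p * (p + 1) // 2 + 1
    return ModelFit(kind="EB", k=k, loglik=ll, aicc=_safe_aicc(ll, k, n * p),
                    n_obs=n * p, params={"root": a, "rate_matrix": R, "r": r})


# ----------------------------------------------------- multivariate OU tools

def _chol_from_params(v: np.ndarray, p: int) -> np.ndarray:
    """Lower-triangular factor with softplus-free log-diagonal parameterization."""
    L = np.zeros((p, p))
    idx = 0
    for i in range(p):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(v[idx])
            else:
                L[i, j] = v[idx]
            idx += 1
    return L


def _params_from_spd(M: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(M)
    out = []
    for i in range(M.shape[0]):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def _ou_sigma_full(tree: PhyloTree, A: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Full np x np OU tip covariance for symmetric A (root state fixed).

    Block(i,j) = e^{-A(T-t_ij)} [int_0^{t_ij} e^{-A v} R e^{-A v} dv] e^{-A(T-t_ij)}
    with t_ij the MRCA depth, computed in the eigenbasis of A.
    """
    lam, Q = np.linalg.eigh(A)
    Rt = Q.T @ R @ Q
    S = lam[:, None] + lam[None, :]
    t = tree.vcv
    T = tree.depth
    n, p = t.shape[0], len(lam)
    Ssafe = np.where(np.abs(S) < 1e-12, 1.0, S)
    tt = t[:, :, None, None]
    integ = np.where(np.abs(S)[None, None] < 1e-12, tt,
                     (1.0 - np.exp(-Ssafe[None, None] * tt)) / Ssafe[None, None])
    blocks = Rt[None, None] * integ * np.exp(-S[None, None] * (T - tt))
    blocks = np.einsum("ak,ijkl,bl->ijab", Q, blocks, Q)
    return blocks.transpose(0, 2, 1, 3).reshape(n * p, n * p)


def _gls_blocks(Sigma: np.ndarray, D: np.ndarray, y: np.ndarray):
    """GLS estimate and Gaussian loglik for y ~ N(D theta, Sigma)."""
    cf = cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    SiD = cho_solve(cf, D)
    M = D.T @ SiD
    theta = np.linalg.solve(M, SiD.T @ y)
    r = y - D @ theta
    quad = float(r @ cho_solve(cf, r))
    ll = -0.5 * (len(y) * np.log(2 * np.pi) + logdet + quad)
    return theta, float(ll)


def fit_ou1(tree: PhyloTree, traits: np.ndarray,
            species: list[str] | None = None,
            n_restarts: int = 3, maxiter: int = 500) -> ModelFit:
    """Single-optimum multivariate OU with symmetric A and symmetric R.

    The root state equals the optimum, so the mean is the optimum vector for
    every tip.  k = p + p(p+1)/2 + p(p+1)/2.  BM is the A -> 0 boundary; the
    fit never reports a lower likelihood than BM (a near-zero-A candidate is
    always evaluated).
    """
    X = _prep(tree, traits, species)
    n, p = X.shape
    y = X.reshape(-1)
    D = np.tile(np.eye(p), (n, 1))
    T = tree.depth
    bm = fit_bm(tree, traits, species)
    R0 = bm.params["rate_matrix"] + 1e-8 * np.trace(bm.params["rate_matrix"]) / p * np.eye(p)
    nh = p * (p + 1) // 2

    def unpack(v):
        La = _chol_from_params(v[:nh], p)
        Lr = _chol_from_params(v[nh:], p)
        return La @ La.T, Lr @ Lr.T

    def nll(v):
        A, R = unpack(v)
        if np.max(np.linalg.eigvalsh(A)) > 100.0 / T:
            return 1e12
        try:
            Sigma = _ou_sigma_full(tree, A, R)
            _, ll = _gls_blocks(Sigma + 1e-10 * np.trace(Sigma) / len(Sigma) * np.eye(len(Sigma)), D, y)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    starts = []
    for scale in (1e-4, 1.0, 8.0, 0.25, 32.0)[:n_restarts]:
        A0 = (scale / T) * np.eye(p)
        starts.append(np.concatenate([_params_from_spd(A0), _params_from_spd(R0)]))
    best_v, best_f = None, np.inf
    for v0 in starts:
        res = minimize(nll, v0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "fatol": 1e-8, "xatol": 1e-6,
                                "adaptive": True})
        if res.fun < best_f:
            best_v, best_f = res.x, res.fun
    A, R = unpack(best_v)
    Sigma = _ou_sigma_full(tree, A, R)
    theta, ll = _gls_blocks(Sigma + 1e-10 * np.trace(Sigma) / len(Sigma) * np.eye(len(Sigma)), D, y)
    if ll < bm.loglik:   # BM boundary dominates
        ll = bm.loglik
        A = 1e-9 * np.eye(p)
        R = bm.params["rate_matrix"]
        theta = bm.params["root"]
    k = p + p * (p + 1)
    return ModelFit(kind="OU1", k=k, loglik=float(ll), aicc=_safe_aicc(ll, k, n * p),
                    n_obs=n * p,
                    params={"optimum": np.asarray(theta), "alpha_matrix": A,
                            "rate_matrix": R})


# -------------------------------------------------------------- OUM fitting

def _painting_branch_segments(tree: PhyloTree, painting: RegimePainting):
    segs = []
    for b in tree.branch_nodes:
        for (t0, t1, s) in painting.segments[int(b)]:
            segs.append((int(b), float(t0), float(t1), s))
    return segs


def _oum_design_univariate(tree: PhyloTree, painting: RegimePainting,
                           states: list[str], a: float) -> np.ndarray:
    """Tips x (1 + regimes) design: root-state column e^{-aT}, then per-regime
    segment weights e^{-a(T-t1)} - e^{-a(T-t0)} accumulated along each path."""
    T = tree.depth
    n = tree.n_tips
    col = {s: i + 1 for i, s in enumerate(states)}
    Dm = np.zeros((n, 1 + len(states)))
    Dm[:, 0] = np.exp(-a * T)
    for b, t0, t1, s in _painting_branch_segments(tree, painting):
        w = np.exp(-a * (T - t1)) - np.exp(-a * (T - t0))
        Dm[tree.tip_masks[b], col[s]] += w
    return Dm


def _fit_oum_diagonal(tree: PhyloTree, X: np.ndarray, painting: RegimePainting):
    """Per-trait independent OU over the painting; root state estimated freely."""
    from .shifts import ALPHA_MAX_FACTOR, _ou_corr

    states = sorted({s for segs in painting.segments.values() for _, _, s in segs}
                    | {painting.root_state})
    n, p = X.shape
    covered = np.zeros(len(states), dtype=bool)
    for b, _, _, s in _painting_branch_segments(tree, painting):
        if not tree.children[b]:
            covered[states.index(s)] = True
    if not covered.all():
        import warnings
        empty = [s for s, c in zip(states, covered) if not c]
        warnings.warn(f"regimes with no descendant tips (optima unidentifiable): {empty}")
    T = tree.depth

    def profile(a: float, y: np.ndarray):
        V0 = _ou_corr(tree, a)
        cf = cho_factor(V0, lower=True)
        logdetV0 = 2.0 * np.log(np.diag(cf[0])).sum()
        Dm = _oum_design_univariate(tree, painting, states, a)
        SiD = cho_solve(cf, Dm)
        M = Dm.T @ SiD
        coef, *_ = np.linalg.lstsq(M, SiD.T @ y, rcond=None)
        r = y - Dm @ coef
        rss = float(r @ cho_solve(cf, r))
        s2 = max(rss / n, 1e-300)
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdetV0 + n)
        return ll, s2, coef

    total = 0.0
    alpha = np.empty(p)
    sigma2 = np.empty(p)
    optima = np.empty((len(states), p))
    roots = np.empty(p)
    for j in range(p):
        y = X[:, j]
        grid = np.exp(np.linspace(np.log(1e-6), np.log(ALPHA_MAX_FACTOR / T), 12))
        lls = [profile(a, y)[0] for a in grid]
        i = int(np.argmax(lls))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(lambda la: -profile(np.exp(la), y)[0],
                              bounds=(np.log(lo), np.log(hi)), method="bounded",
                              options={"xatol": 1e-4})
        a_best = float(np.exp(res.x)) if -res.fun >= lls[i] else float(grid[i])
        ll, s2, coef = profile(a_best, y)
        total += ll
        alpha[j], sigma2[j] = a_best, s2
        roots[j] = coef[0]
        optima[:, j] = coef[1:]
    k = len(states) * p + 3 * p
    return total, k, {"states": states, "optima": optima, "alpha": alpha,
                      "sigma2": sigma2, "root_state_value": roots}


def _fit_oum_symmetric(tree: PhyloTree, X: np.ndarray, painting: RegimePainting,
                       n_restarts: int = 2, maxiter: int = 500):
    """Full symmetric A and R; per-regime optimum vectors, root at its regime
    optimum.  k = regimes*p + p(p+1)."""
    states = sorted({s for segs in painting.segments.values() for _, _, s in segs}
                    | {painting.root_state})
    n, p = X.shape
    y = X.reshape(-1)
    T = tree.depth
    root_idx = states.index(painting.root_state)
    segs = _painting_branch_segments(tree, painting)
    bm = fit_bm(tree, X)
    R0 = bm.params["rate_matrix"] + 1e-8 * np.trace(bm.params["rate_matrix"]) / p * np.eye(p)
    nh = p * (p + 1) // 2

    def design(A):
        lam, Q = np.linalg.eigh(A)
        W = np.zeros((n, len(states), p, p))
        for b, t0, t1, s in segs:
            w = np.exp(-lam * (T - t1)) - np.exp(-lam * (T - t0))
            E = (Q * w) @ Q.T
            W[tree.tip_masks[b], states.index(s)] += E
        Eroot = (Q * np.exp(-lam * T)) @ Q.T
        W[:, root_idx] += Eroot
        return W.transpose(0, 2, 1, 3).reshape(n * p, len(states) * p)

    def unpack(v):
        La = _chol_from_params(v[:nh], p)
        Lr = _chol_from_params(v[nh:], p)
        return La @ La.T, Lr @ Lr.T

    def nll(v):
        A, R = unpack(v)
        if np.max(np.linalg.eigvalsh(A)) > 100.0 / T:
            return 1e12
        try:
            Sigma = _ou_sigma_full(tree, A, R)
            Sigma += 1e-10 * np.trace(Sigma) / len(Sigma) * np.eye(len(Sigma))
            _, ll = _gls_blocks(Sigma, design(A), y)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    best_v, best_f = None, np.inf
    for scale in (1.0, 8.0, 0.25)[:n_restarts]:
        v0 = np.concatenate([_params_from_spd((scale / T) * np.eye(p)),
                             _params_from_spd(R0)])
        res = minimize(nll, v0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "fatol": 1e-8,
                                "xatol": 1e-6, "adaptive": True})
        if res.fun < best_f:
            best_v, best_f = res.x, res.fun
    A, R = unpack(best_v)
    Sigma = _ou_sigma_full(tree, A, R)
    Sigma += 1e-10 * np.trace(Sigma) / len(Sigma) * np.eye(len(Sigma))
    theta, ll = _gls_blocks(Sigma, design(A), y)
    k = len(states) * p + p * (p + 1)
    return float(ll), k, {"states": states,
                          "optima": np.asarray(theta).reshape(len(states), p),
                          "alpha_matrix": A, "rate_matrix": R}


def fit_oum(tree: PhyloTree, traits: np.ndarray, painting: RegimePainting,
            species: list[str] | None = None,
            structure: str = "diagonal") -> ModelFit:
    """Multi-peak OU on a regime painting.

    ``structure='diagonal'`` (default): per-trait independent alpha and
    sigma^2 plus a free root state, k = regimes*p + 3p.
    ``structure='symmetric'``: full symmetric A and R with the root state at
    its regime's optimum, k = regimes*p + p(p+1).
    """
    X = _prep(tree, traits, species)
    painting.validate(tree)
    n, p = X.shape
    if structure == "diagonal":
        ll, k, params = _fit_oum_diagonal(tree, X, painting)
    elif structure == "symmetric":
        ll, k, params = _fit_oum_symmetric(tree, X, painting)
    else:
        raise ValueError("structure must be 'diagonal' or 'symmetric'")
    return ModelFit(kind="OUM", k=k, loglik=float(ll), aicc=_safe_aicc(ll, k, n * p),
                    n_obs=n * p, n_regimes=len(params["states"]), params=params,
                    painting_source=painting.source)


# ------------------------------------------------------------------ Mk model

@dataclass
class MkModel:
    states: list[str]
    Q: np.ndarray
    root_prior: np.ndarray
    loglik: float

    def __post_init__(self):
        if np.abs(self.Q.sum(axis=1)).max() > 1e-10:
            raise ValueError("Q rows must sum to 0")


def _build_q(rates: np.ndarray, ns: int, model: str) -> np.ndarray:
    Q = np.zeros((ns, ns))
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        iu = np.triu_indices(ns, k=1)
        Q[iu] = rates
        Q[(iu[1], iu[0])] = rates
    elif model == "ARD":
        mask = ~np.eye(ns, dtype=bool)
        Q[mask] = rates
    else:
        raise ValueError("model must be ER, SYM or ARD")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _stationary(Q: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eig(Q.T)
    pi = np.real(V[:, np.argmin(np.abs(w))])
    pi = np.abs(pi)
    return pi / pi.sum()


def _mk_partials(tree: PhyloTree, obs: np.ndarray, Q: np.ndarray):
    """Felsenstein pruning partial likelihoods and per-branch transition matrices."""
    ns = Q.shape[0]
    P = {}
    for b in tree.branch_nodes:
        P[int(b)] = expm(Q * tree.length[b])
    L = np.zeros((tree.n_nodes, ns))
    for r, t in enumerate(tree.tips):
        L[t] = obs[r]
    for nd in tree.postorder:
        if tree.children[nd]:
            L[nd] = 1.0
            for c in tree.children[nd]:
                L[nd] *= P[int(c)] @ L[c]
    return L, P


def fit_mk(tree: PhyloTree, tip_states: dict[str, str], model: str = "ER",
           states: list[str] | None = None) -> MkModel:
    """ML Mk transition-rate matrix; root prior = stationary distribution."""
    states = states or sorted(set(tip_states.values()))
    for s in states:
        if s not in set(tip_states.values()):
            raise ValueError(f"state {s!r} observed at no tip")
    ns = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    obs = np.zeros((tree.n_tips, ns))
    for r, l in enumerate(tree.tip_labels):
        obs[r, sidx[tip_states[l]]] = 1.0
    n_par = {"ER": 1, "SYM": ns * (ns - 1) // 2, "ARD": ns * (ns - 1)}[model]

    def nll(logr):
        Q = _build_q(np.exp(logr), ns, model)
        L, _ = _mk_partials(tree, obs, Q)
        lik = float(_stationary(Q) @ L[tree.root])
        return -np.log(max(lik, 1e-300))

    x0 = np.full(n_par, np.log(1.0 / tree.depth))
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "fatol": 1e-9, "xatol": 1e-7})
    Q = _build_q(np.exp(res.x), ns, model)
    return MkModel(states=states, Q=Q, root_prior=_stationary(Q),
                   loglik=float(-res.fun))


def mk_node_marginals(tree: PhyloTree, tip_states: dict[str, str],
                      mk: MkModel) -> np.ndarray:
    """Marginal posterior state probabilities at every node (pruning up-down)."""
    sidx = {s: i for i, s in enumerate(mk.states)}
    obs = np.zeros((tree.n_tips, len(mk.states)))
    for r, l in enumerate(tree.tip_labels):
        obs[r, sidx[tip_states[l]]] = 1.0
    L, P = _mk_partials(tree, obs, mk.Q)
    down = np.zeros_like(L)
    down[tree.root] = mk.root_prior
    for nd in tree.preorder:
        for c in tree.children[nd]:
            sib = down[nd].copy()
            for c2 in tree.children[nd]:
                if c2 != c:
                    sib = sib * (P[int(c2)] @ L[c2])
            down[c] = sib @ P[int(c)]
    marg = L * down
    marg /= marg.sum(axis=1, keepdims=True)
    return marg


def _sample_branch_history(Q, P_pows, a, b, t0, t1, rng, state_names,
                           P_branch=None):
    """Uniformization bridge: CTMC path on [t0, t1] conditioned on endpoints."""
    t = t1 - t0
    mu = float(-Q.diagonal().min())
    if mu <= 0 or t <= 0:
        return [(t0, t1, state_names[a])]
    Pd = np.eye(Q.shape[0]) + Q / mu
    target = (P_branch if P_branch is not None else expm(Q * t))[a, b]
    u = rng.random() * max(target, 1e-300)
    acc, n_jumps = 0.0, 0
    pois = np.exp(-mu * t)
    while True:
        while len(P_pows) <= n_jumps:
            P_pows.append(P_pows[-1] @ Pd)
        acc += pois * P_pows[n_jumps][a, b]
        if acc >= u or n_jumps > 10000:
            break
        n_jumps += 1
        pois *= mu * t / n_jumps
    seq = [a]
    for i in range(1, n_jumps + 1):
        prev = seq[-1]
        probs = Pd[prev] * P_pows[n_jumps - i][:, b]
        ssum = probs.sum()
        probs = probs / ssum if ssum > 0 else np.full(len(probs), 1.0 / len(probs))
        seq.append(int(rng.choice(len(probs), p=probs)))
    times = np.sort(rng.random(n_jumps)) * t + t0
    segs = []
    cur_state, cur_t = seq[0], t0
    for i in range(1, len(seq)):
        if seq[i] != cur_state:   # drop virtual jumps
            segs.append((cur_t, float(times[i - 1]), state_names[cur_state]))
            cur_state, cur_t = seq[i], float(times[i - 1])
    segs.append((cur_t, t1, state_names[cur_state]))
    return segs


def simmap(tree: PhyloTree, tip_states: dict[str, str], model: str = "ER",
           n_maps: int = 100, seed: int = 0,
           states: list[str] | None = None,
           mk: MkModel | None = None) -> list[RegimePainting]:
    """Stochastic character mapping under an ML Mk model.

    Fits Q (unless a fitted :class:`MkModel` is supplied), samples joint node
    states conditional on the tips (conditional sampling from the pruning
    partials), and fills within-branch transition histories by
    uniformization.  Returns ``n_maps`` regime paintings.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    missing = [l for l in tree.tip_labels if l not in tip_states]
    if missing:
        raise ValueError(f"tips without states: {missing}")
    if mk is None:
        mk = fit_mk(tree, tip_states, model=model, states=states)
    ns = len(mk.states)
    sidx = {s: i for i, s in enumerate(mk.states)}
    obs = np.zeros((tree.n_tips, ns))
    for r, l in enumerate(tree.tip_labels):
        obs[r, sidx[tip_states[l]]] = 1.0
    L, P = _mk_partials(tree, obs, mk.Q)
    rng = np.random.default_rng(seed)
    depths = tree.depths
    P_pows = [np.eye(ns)]
    maps = []
    for _ in range(n_maps):
        node_state = np.zeros(tree.n_nodes, dtype=int)
        pr = mk.root_prior * L[tree.root]
        node_state[tree.root] = int(rng.choice(ns, p=pr / pr.sum()))
        segments = {}
        for nd in tree.preorder:
            if nd == tree.root:
                continue
            ps = node_state[tree.parent[nd]]
            pc = P[int(nd)][ps] * L[nd]
            node_state[nd] = int(rng.choice(ns, p=pc / pc.sum()))
            segments[int(nd)] = _sample_branch_history(
                mk.Q, P_pows, ps, node_state[nd],
                float(depths[tree.parent[nd]]), float(depths[nd]), rng, mk.states,
                P_branch=P[int(nd)])
        maps.append(RegimePainting(segments=segments, states=mk.states,
                                   root_state=mk.states[node_state[tree.root]],
                                   source="simmap"))
    return maps


# ------------------------------------------------------------- comparison

def compare_models(fits: dict[str, "ModelFit | list[ModelFit]"]) -> pd.DataFrame:
    """Comparison table: kind, regimes, k, logL, AICc, dAICc vs the best model.

    Entries may be single fits or lists of fits over a painting distribution;
    the latter are summarized as median (min, max) across maps, following the
    convention for stochastic-character-map ensembles.
    """
    rows = []
    n_obs = None
    for name, fit in fits.items():
        group = fit if isinstance(fit, list) else [fit]
        for f in group:
            if n_obs is None:
                n_obs = f.n_obs
            elif f.n_obs != n_obs:
                raise ValueError("all fits must be on identical data")
        lls = np.array([f.loglik for f in group])
        ais = np.array([f.aicc for f in group])
        rows.append({"model": name, "kind": group[0].kind,
                     "regimes": group[0].n_regimes, "k": group[0].k,
                     "loglik": float(np.median(lls)),
                     "loglik_min": float(lls.min()), "loglik_max": float(lls.max()),
                     "aicc": float(np.median(ais)),
                     "aicc_min": float(ais.min()), "aicc_max": float(ais.max()),
                     "n_maps": len(group)})
    df = pd.DataFrame(rows)
    best = df["aicc"].min()
    df["delta_aicc"] = df["aicc"] - best
    df["delta_aicc_min"] = df["aicc_min"] - best
    df["delta_aicc_max"] = df["aicc_max"] - best
    return df.sort_values("aicc").reset_index(drop=True)
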