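"""Adaptive-zone shift detection on a phylogeny via multi-peak OU modeling.

Each trait (typically a principal-component axis, pre-scaled x100) evolves
under an independent Ornstein-Uhlenbeck process with per-trait selection
strength alpha and rate sigma^2; shifts move the optimum on a branch and all
its descendants.  The search is two-phase: a group-lasso path over a
phylogenetically whitened linear model of branch optimum changes proposes
sparse candidate shift sets sharing support across traits, then each
candidate is refit by maximum likelihood and scored with pBIC (a BIC variant
charging each shift a placement term on the 2n-3 possible branches plus the
log-determinant of the GLS information of its design), with plain BIC as a
fallback criterion.  Support for the selected shifts comes from a parametric
bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar
from sklearn.linear_model import lasso_path

from .regimes import RegimePainting
from .trees import PhyloTree

log = logging.getLogger(__name__)

__all__ = ["OUParams", "ShiftConfiguration", "SearchSettings", "ou_loglik",
           "shift_design_matrix", "detect_shifts", "pbic_score", "bic_score",
           "bootstrap_support", "config_to_painting", "painting_to_shifts"]

ALPHA_MIN = 1e-6
ALPHA_MAX_FACTOR = 50.0   # upper bound 50/T: regimes effectively instantaneous


@dataclass
class OUParams:
    alpha: np.ndarray         # per-trait selection strength, > 0
    sigma2: np.ndarray        # per-trait rate, > 0
    root_optima: np.ndarray   # optimum (= root state) per trait

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.root_optima = np.atleast_1d(np.asarray(self.root_optima, dtype=float))
        if np.any(self.alpha <= 0) or np.any(self.sigma2 <= 0):
            raise ValueError("alpha and sigma2 must be positive")


@dataclass
class ShiftConfiguration:
    shift_branches: list[int]
    beta: np.ndarray               # (n_shifts, p) per-trait optimum changes
    params: OUParams
    loglik: float | None = None
    score: float | None = None
    criterion: str = "pbic"
    support: dict[int, float] = field(default_factory=dict)
    # traits whose alpha collapsed to the BM limit have unidentifiable optima;
    # their optimum changes are pinned at 0 and they carry no shift information
    active_traits: np.ndarray | None = None

    @property
    def n_shifts(self) -> int:
        return len(self.shift_branches)


@dataclass
class SearchSettings:
    max_shifts: int = 50          # 50 full-tree / 20 subclade conventions
    n_lambda: int = 50
    lambda_decades: float = 4.0
    criterion: str = "pbic"
    n_bootstrap: int = 0
    seed: int = 0


# ---------------------------------------------------------------- OU algebra

def _tree_arrays(tree: PhyloTree):
    cache = tree._cache
    if "ou_arrays" not in cache:
        branches = tree.branch_nodes
        depths = tree.depths
        cache["ou_arrays"] = {
            "branches": branches,
            "t_start": depths[tree.parent[branches]],
            "t_end": depths[branches],
            "masks": tree.tip_masks[branches],   # (n_branches, n_tips)
            "T": tree.depth,
            "t_mrca": tree.vcv,
            "d_patristic": tree.patristic,
        }
    return cache["ou_arrays"]


def _ou_corr(tree: PhyloTree, alpha: float) -> np.ndarray:
    """OU tip covariance at sigma^2 = 1 (root state fixed at the root optimum)."""
    arr = _tree_arrays(tree)
    return np.exp(-alpha * arr["d_patristic"]) * \
        (1.0 - np.exp(-2.0 * alpha * arr["t_mrca"])) / (2.0 * alpha)


def shift_design_matrix(tree: PhyloTree, alpha_j: float) -> np.ndarray:
    """Tips x branches weights of branch optima in the OU mean.

    Entry (i, b) is e^{-a(T - t_end(b))} - e^{-a(T - t_start(b))} when branch
    b lies on the root-to-tip-i path, else 0; the OU tip mean is this matrix
    times the per-branch optima plus e^{-aT} times the root state.
    """
    if alpha_j <= 0:
        raise ValueError("alpha must be positive")
    arr = _tree_arrays(tree)
    T = arr["T"]
    w = np.exp(-alpha_j * (T - arr["t_end"])) - np.exp(-alpha_j * (T - arr["t_start"]))
    return (arr["masks"] * w[:, None]).T


def _shift_predictors(tree: PhyloTree, alpha_j: float,
                      branches: np.ndarray) -> np.ndarray:
    """Tips x shifts cumulative design: column b = 1 - e^{-a(T-t_start(b))} on
    tips descending from b (the telescoped sum of shift_design_matrix columns
    at and below b along each path)."""
    arr = _tree_arrays(tree)
    T = arr["T"]
    all_b = arr["branches"]
    pos = {int(b): i for i, b in enumerate(all_b)}
    idx = np.array([pos[int(b)] for b in branches], dtype=int)
    w = 1.0 - np.exp(-alpha_j * (T - arr["t_start"][idx]))
    return (arr["masks"][idx] * w[:, None]).T


def ou_loglik(tree: PhyloTree, traits: np.ndarray,
              config: ShiftConfiguration) -> float:
    """Exact Gaussian log-likelihood of a shifted multi-peak OU model.

    Traits are independent given the shared shift set; each contributes a
    multivariate normal with OU covariance and a mean determined by the
    regime painting induced by the shifts.
    """
    if not tree.is_ultrametric(rel_tol=1e-6):
        raise ValueError("ou_loglik requires an ultrametric tree")
    Y = np.atleast_2d(np.asarray(traits, dtype=float))
    if Y.shape[0] == 1 and tree.n_tips > 1:
        Y = Y.T
    if not np.isfinite(Y).all():
        raise ValueError("traits must be finite")
    p = Y.shape[1]
    branches = np.asarray(config.shift_branches, dtype=int)
    total = 0.0
    n = tree.n_tips
    for j in range(p):
        a, s2 = float(config.params.alpha[j]), float(config.params.sigma2[j])
        V = s2 * _ou_corr(tree, a)
        mean = np.full(n, config.params.root_optima[j])
        if len(branches):
            U = _shift_predictors(tree, a, branches)
            mean = mean + U @ config.beta[:, j]
        r = Y[:, j] - mean
        cf = cho_factor(V, lower=True)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        total += -0.5 * (n * np.log(2 * np.pi) + logdet + r @ cho_solve(cf, r))
    return float(total)


# ------------------------------------------------------------ per-trait fits

def _ou_factor_cached(tree: PhyloTree, alpha: float):
    """Cholesky of the unit-sigma^2 OU covariance plus the full predictor
    matrix at this alpha, memoized on the tree (the profile search revisits
    the same alpha grid for every candidate support)."""
    cache = tree._cache.setdefault("ou_factor", {})
    key = float(alpha)
    if key not in cache:
        if len(cache) > 512:
            cache.clear()
        V0 = _ou_corr(tree, alpha)
        cf = cho_factor(V0, lower=True)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        arr = _tree_arrays(tree)
        w = 1.0 - np.exp(-alpha * (arr["T"] - arr["t_start"]))
        W = (arr["masks"] * w[:, None]).T     # tips x all branches
        pos = {int(b): i for i, b in enumerate(arr["branches"])}
        cache[key] = (cf, logdet, W, pos)
    return cache[key]


def _profile_trait(tree: PhyloTree, y: np.ndarray, branches: np.ndarray,
                   alpha: float):
    """GLS refit of one trait at fixed alpha: profile out optima and sigma^2.

    Returns (loglik, sigma2_hat, theta0_hat, beta_hat)."""
    n = len(y)
    cf, logdetV0, W, pos = _ou_factor_cached(tree, alpha)
    X = np.ones((n, 1 + len(branches)))
    if len(branches):
        X[:, 1:] = W[:, [pos[int(b)] for b in branches]]
    Vi_X = cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    XtViy = Vi_X.T @ y
    try:
        coef = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan, None
    r = y - X @ coef
    rss = float(r @ cho_solve(cf, r))
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV0 + n)
    return loglik, sigma2, float(coef[0]), coef[1:]


def _fit_trait(tree: PhyloTree, y: np.ndarray, branches: np.ndarray):
    """Maximize the per-trait profile likelihood over alpha (bounded search)."""
    T = tree.depth
    lo, hi = ALPHA_MIN, ALPHA_MAX_FACTOR / T
    grid = np.exp(np.linspace(np.log(max(lo, 1e-6)), np.log(hi), 9))
    vals = [_profile_trait(tree, y, branches, a)[0] for a in grid]
    i = int(np.argmax(vals))
    bl = grid[max(i - 1, 0)]
    bh = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda la: -_profile_trait(tree, y, branches, np.exp(la))[0],
                          bounds=(np.log(bl), np.log(bh)), method="bounded",
                          options={"xatol": 1e-2, "maxiter": 20})
    a_best = float(np.exp(res.x))
    if -res.fun < vals[i]:
        a_best = float(grid[i])
    ll, s2, th0, beta = _profile_trait(tree, y, branches, a_best)
    return a_best, ll, s2, th0, beta


def _refit(tree: PhyloTree, Y: np.ndarray, branches: np.ndarray) -> ShiftConfiguration:
    p = Y.shape[1]
    T = tree.depth
    alpha = np.empty(p)
    sigma2 = np.empty(p)
    theta0 = np.empty(p)
    beta = np.zeros((len(branches), p))
    active = np.ones(p, dtype=bool)
    total = 0.0
    for j in range(p):
        a, ll, s2, th0, b = _fit_trait(tree, Y[:, j], branches)
        if len(branches) and a * T < 5e-3:
            # BM limit: shift optima unidentifiable for this trait; pin its
            # optimum changes at zero and refit it shift-free
            a, ll, s2, th0, b = _fit_trait(tree, Y[:, j], np.array([], dtype=int))
            active[j] = False
            b = np.zeros(len(branches))
        if not np.isfinite(ll):
            raise np.linalg.LinAlgError("singular design in refit")
        alpha[j], sigma2[j], theta0[j] = a, s2, th0
        if len(branches):
            beta[:, j] = b
        total += ll
    cfg = ShiftConfiguration(shift_branches=[int(b) for b in branches], beta=beta,
                             params=OUParams(alpha, np.maximum(sigma2, 1e-300),
                                             theta0),
                             loglik=float(total), active_traits=active)
    return cfg


# -------------------------------------------------------------- scoring

def _information_logdets(tree: PhyloTree, config: ShiftConfiguration) -> float:
    branches = np.asarray(config.shift_branches, dtype=int)
    if len(branches) == 0:
        return 0.0
    active = (config.active_traits if config.active_traits is not None
              else np.ones(len(config.params.alpha), dtype=bool))
    if not active.any():
        return np.inf   # shifts with no responding trait are meaningless
    total = 0.0
    for j in np.where(active)[0]:
        a = float(config.params.alpha[j])
        U = _shift_predictors(tree, a, branches)
        cf = cho_factor(_ou_corr(tree, a), lower=True)
        # GLS information of the optimum changes measured in stationary-SD
        # units (sigma^2 cancels): scale-invariant, as model ranking must be
        info = U.T @ cho_solve(cf, U) / (2.0 * a)
        eig = np.linalg.eigvalsh(info)
        if eig.min() < 1.0:
            # below unit information the shift magnitude cannot be estimated
            # to one stationary SD: unidentifiable placement, discard
            log.debug("weakly identified shift design for trait %d; discarded", j)
            return np.inf
        total += float(np.log(eig).sum())
    return total


def pbic_score(tree: PhyloTree, traits: np.ndarray,
               config: ShiftConfiguration) -> float:
    """Phylogenetic BIC of a (ML-refit) shift configuration.

    pBIC = -2 logL + 3p log n + 2K log(2n-3) + sum_j logdet(U' V_j^-1 U):
    3p covers alpha, sigma^2 and the root optimum per trait; each of the K
    shifts is charged a placement term over the 2n-3 candidate branches; the
    optimum-change magnitudes are charged their per-trait GLS information.
    """
    Y = np.atleast_2d(np.asarray(traits, dtype=float))
    if Y.shape[0] == 1 and tree.n_tips > 1:
        Y = Y.T
    n, p = tree.n_tips, Y.shape[1]
    K = config.n_shifts
    ll = config.loglik if config.loglik is not None else ou_loglik(tree, Y, config)
    pen = 3 * p * np.log(n) + 2 * K * np.log(2 * n - 3)
    pen += _information_logdets(tree, config)
    return float(-2.0 * ll + pen)


def bic_score(tree: PhyloTree, traits: np.ndarray,
              config: ShiftConfiguration) -> float:
    """Plain BIC: each shift costs (1 + p) log n (placement + coefficients)."""
    Y = np.atleast_2d(np.asarray(traits, dtype=float))
    if Y.shape[0] == 1 and tree.n_tips > 1:
        Y = Y.T
    n, p = tree.n_tips, Y.shape[1]
    ll = config.loglik if config.loglik is not None else ou_loglik(tree, Y, config)
    df = 3 * p + config.n_shifts * (1 + p)
    return float(-2.0 * ll + df * np.log(n))


# -------------------------------------------------------------- lasso search

def _prune_sisters(tree: PhyloTree, support: list[int]) -> list[int]:
    """Drop the higher-id member of any sister pair (unidentifiable jointly
    with a root-state change)."""
    sset = set(support)
    out = []
    for b in sorted(support):
        sisters = [c for c in tree.children[tree.parent[b]] if c != b]
        if any(s in sset and s < b for s in sisters):
            sset.discard(b)
            continue
        out.append(b)
    return out


def _candidate_supports(tree: PhyloTree, Y: np.ndarray,
                        settings: SearchSettings) -> list[list[int]]:
    n, p = Y.shape
    alpha0 = np.empty(p)
    for j in range(p):
        alpha0[j] = _fit_trait(tree, Y[:, j], np.array([], dtype=int))[0]
    a_bar = float(np.exp(np.mean(np.log(alpha0))))
    V0 = _ou_corr(tree, a_bar)
    L = np.linalg.cholesky(V0)
    branches = _tree_arrays(tree)["branches"]
    U = _shift_predictors(tree, a_bar, branches)
    Xw = solve_triangular(L, U, lower=True)
    Yw = solve_triangular(L, Y, lower=True)
    one_w = solve_triangular(L, np.ones((n, 1)), lower=True)
    q = one_w / np.linalg.norm(one_w)
    Xw = Xw - q @ (q.T @ Xw)       # project out the (whitened) intercept
    Yw = Yw - q @ (q.T @ Yw)
    eps = 10.0 ** (-settings.lambda_decades)
    import warnings as _warnings
    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        _, coefs, _ = lasso_path(Xw, Yw, eps=eps, alphas=settings.n_lambda,
                                 max_iter=3000)
    if coefs.ndim == 2:   # single trait
        coefs = coefs[None, :, :]
    supports: list[list[int]] = [[]]
    seen = {()}
    on_path: set[int] = set()
    for a_idx in range(coefs.shape[2]):
        nz = np.where(np.abs(coefs[:, :, a_idx]).sum(axis=0) > 0)[0]
        if len(nz) == 0:
            continue
        on_path.update(int(branches[i]) for i in nz)
        if len(nz) > settings.max_shifts:
            continue
        supp = _prune_sisters(tree, [int(branches[i]) for i in nz])
        key = tuple(sorted(supp))
        if key not in seen:
            seen.add(key)
            supports.append(sorted(supp))
    # the path often bundles spurious branches with real ones; every branch it
    # ever touched is also proposed on its own
    for b in sorted(on_path):
        if (b,) not in seen:
            seen.add((b,))
            supports.append([b])
    return supports


def detect_shifts(tree: PhyloTree, scores: np.ndarray,
                  settings: SearchSettings | None = None,
                  species: list[str] | None = None) -> ShiftConfiguration:
    """Two-phase lasso + information-criterion search for optimum shifts.

    Phase 1 whitens each trait by the OU covariance at an initial shared
    alpha estimate and runs a multi-task lasso path over the branch shift
    design, collecting candidate supports of up to ``max_shifts`` branches.
    Phase 2 refits every candidate by maximum likelihood (per-trait alpha and
    sigma^2, GLS optima) and returns the configuration minimizing the chosen
    criterion, ties broken toward fewer shifts.  The search is deterministic
    given data and settings.
    """
    settings = settings or SearchSettings()
    Y = np.atleast_2d(np.asarray(scores, dtype=float))
    if Y.shape[0] != tree.n_tips:
        Y = Y.T
    if Y.shape[0] != tree.n_tips:
        raise ValueError("scores must have one row per tip")
    if species is not None:
        idx_in = {l: i for i, l in enumerate(species)}
        Y = Y[[idx_in[l] for l in tree.tip_labels]]
    supports = _candidate_supports(tree, Y, settings)
    scorer = pbic_score if settings.criterion == "pbic" else bic_score

    memo: dict[tuple, ShiftConfiguration | None] = {}

    def evaluate(supp: list[int]):
        key = tuple(sorted(supp))
        if key in memo:
            return memo[key]
        try:
            cfg = _refit(tree, Y, np.asarray(supp, dtype=int))
        except np.linalg.LinAlgError:
            memo[key] = None
            return None
        s = scorer(tree, Y, cfg)
        if not np.isfinite(s):
            memo[key] = None
            return None
        cfg.score = s
        cfg.criterion = settings.criterion
        memo[key] = cfg
        return cfg

    best = None
    best_key = (np.inf, np.inf)
    for supp in supports:
        cfg = evaluate(supp)
        if cfg is not None:
            key = (round(cfg.score, 9), len(supp))
            if key < best_key:
                best, best_key = cfg, key
    if best is None:
        raise RuntimeError("no candidate configuration could be scored")
    # backward elimination from the current best: dropping a shift must not
    # worsen the criterion, otherwise the smaller configuration wins
    improved = True
    while improved and best.n_shifts > 0:
        improved = False
        for drop in list(best.shift_branches):
            sub = [b for b in best.shift_branches if b != drop]
            cfg = evaluate(sub)
            if cfg is not None and (round(cfg.score, 9), len(sub)) < \
                    (round(best.score, 9), best.n_shifts):
                best = cfg
                improved = True
    return best


# ------------------------------------------------------------- bootstrap

def bootstrap_support(tree: PhyloTree, scores: np.ndarray,
                      configuration: ShiftConfiguration, n_bootstrap: int = 100,
                      seed: int = 0,
                      settings: SearchSettings | None = None) -> dict[int, float]:
    """Parametric-bootstrap support for each selected shift branch.

    Simulates from the fitted shifted-OU model, reruns the full search, and
    reports the fraction of replicates whose selected configuration contains
    each branch.  Shifts at or above 0.7 support are conventionally
    "well-supported".
    """
    from .synthetic import simulate_shifted_ou_traits

    if n_bootstrap < 20:
        raise ValueError("n_bootstrap must be >= 20")
    settings = settings or SearchSettings()
    rng = np.random.default_rng(seed)
    shifts = [(b, configuration.beta[i])
              for i, b in enumerate(configuration.shift_branches)]
    counts = {int(b): 0 for b in configuration.shift_branches}
    for _ in range(n_bootstrap):
        Yb = simulate_shifted_ou_traits(
            tree, configuration.params.alpha, configuration.params.sigma2,
            configuration.params.root_optima, shifts,
            seed=int(rng.integers(2 ** 31)))
        try:
            picked = detect_shifts(tree, Yb, settings)
        except RuntimeError:
            continue
        for b in picked.shift_branches:
            if b in counts:
                counts[b] += 1
    support = {b: c / n_bootstrap for b, c in counts.items()}
    configuration.support = support
    return support


# ---------------------------------------------------------- regime painting

def config_to_painting(tree: PhyloTree, config: ShiftConfiguration) -> RegimePainting:
    """Paint each branch with its nearest ancestral (inclusive) shift, or root."""
    depths = tree.depths
    state = {tree.root: "root"}
    shift_set = set(int(b) for b in config.shift_branches)
    segs = {}
    for nd in tree.preorder:
        if nd == tree.root:
            continue
        s = f"shift_{nd}" if nd in shift_set else state[tree.parent[nd]]
        state[nd] = s
        segs[int(nd)] = [(float(depths[tree.parent[nd]]), float(depths[nd]), s)]
    states = sorted({s for s in state.values()})
    return RegimePainting(segments=segs, states=states, root_state="root",
                          source="shift_configuration")


def painting_to_shifts(tree: PhyloTree, painting: RegimePainting) -> list[int]:
    """Branches whose (initial) state differs from their parent's final state."""
    out = []
    for b in tree.branch_nodes:
        parent = tree.parent[b]
        parent_state = (painting.root_state if parent == tree.root
                        else painting.segments[int(parent)][-1][2])
        if painting.segments[int(b)][0][2] != parent_state:
            out.append(int(b))
    return sorted(out)
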