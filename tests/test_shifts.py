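import numpy as np
import pytest
from scipy.stats import multivariate_normal

from morphoshift import (OUParams, PhyloTree, SearchSettings,
                         ShiftConfiguration, bootstrap_support,
                         config_to_painting, detect_shifts, ou_loglik,
                         painting_to_shifts, shift_design_matrix,
                         simulate_shifted_ou_traits, simulate_tree)
from morphoshift.shifts import bic_score, pbic_score

ALPHA = np.array([3.0, 3.0])
SIGMA2 = np.array([1.0, 1.0])
STAT_SD = np.sqrt(SIGMA2 / (2 * ALPHA))


def plant_branch(tree, lo=6, hi=16):
    """Earliest-starting branch subtending lo..hi tips (a shift with time to
    express before the present)."""
    depths = tree.depths
    best = None
    for b in tree.branch_nodes:
        if lo <= tree.tip_masks[b].sum() <= hi:
            ts = depths[tree.parent[b]]
            if best is None or ts < best[1]:
                best = (int(b), float(ts))
    return best[0]


def _config(tree, branches, beta, alpha=ALPHA, sigma2=SIGMA2, root=None):
    p = len(alpha)
    return ShiftConfiguration(
        shift_branches=list(branches),
        beta=np.asarray(beta, float).reshape(len(branches), p),
        params=OUParams(alpha, sigma2, root if root is not None else np.zeros(p)))


# ------------------------------------------------------------- design matrix

def test_design_matrix_alpha_limits(medium_tree):
    W_fast = shift_design_matrix(medium_tree, 1e4)
    depths = medium_tree.depths
    for r, t in enumerate(medium_tree.tips):
        row = W_fast[r]
        terminal = np.where(medium_tree.branch_nodes == t)[0][0]
        assert row[terminal] == pytest.approx(1.0, abs=1e-6)
        others = np.delete(row, terminal)
        assert np.all(np.abs(others) < 1e-4)
    W_slow = shift_design_matrix(medium_tree, 1e-9)
    assert np.abs(W_slow).max() < 1e-8


def test_design_matrix_matches_numerical_ode(three_tip_tree):
    """Tip expectation from forward integration of dm/dt = a(theta - m) with
    theta = 1 on one branch and 0 elsewhere equals the design-matrix entry."""
    alpha = 1.0
    tree = three_tip_tree
    W = shift_design_matrix(tree, alpha)
    branches = tree.branch_nodes
    depths = tree.depths
    for bi, b in enumerate(branches):
        for r, t in enumerate(tree.tips):
            # integrate along the root-to-tip path with dt steps
            path = []
            node = t
            while node != tree.root:
                path.append(node)
                node = tree.parent[node]
            m = 0.0
            for node in reversed(path):
                t0, t1 = depths[tree.parent[node]], depths[node]
                theta = 1.0 if node == b else 0.0
                for _ in range(2000):
                    dt = (t1 - t0) / 2000
                    m += alpha * (theta - m) * dt
            assert W[r, bi] == pytest.approx(m, abs=1e-3)


# ------------------------------------------------------------- log-likelihood

def test_ou_loglik_bm_limit(three_tip_tree):
    rng = np.random.default_rng(0)
    Y = rng.standard_normal((3, 2))
    sig = np.array([0.8, 1.2])
    root = np.array([0.1, -0.2])
    cfg = _config(three_tip_tree, [], np.zeros((0, 2)),
                  alpha=np.array([1e-9, 1e-9]), sigma2=sig, root=root)
    ll = ou_loglik(three_tip_tree, Y, cfg)
    C = three_tip_tree.vcv
    ll_bm = sum(multivariate_normal.logpdf(Y[:, j], mean=np.full(3, root[j]),
                                           cov=sig[j] * C)
                for j in range(2))
    assert ll == pytest.approx(ll_bm, abs=1e-4)


def test_ou_loglik_two_tip_closed_form():
    t = 1.0
    tree = PhyloTree([-1, 0, 0], [0.0, t, t], {1: "A", 2: "B"})
    a, s2, th = 1.5, 0.6, 0.4
    y = np.array([[0.9], [-0.3]])
    cfg = _config(tree, [], np.zeros((0, 1)), alpha=np.array([a]),
                  sigma2=np.array([s2]), root=np.array([th]))
    v = s2 / (2 * a) * (1 - np.exp(-2 * a * t))
    ll_hand = multivariate_normal.logpdf(y[:, 0], mean=[th, th],
                                         cov=np.eye(2) * v)
    assert ou_loglik(tree, y, cfg) == pytest.approx(ll_hand, abs=1e-10)


def test_ou_loglik_null_shift_is_invisible(medium_tree):
    rng = np.random.default_rng(1)
    Y = rng.standard_normal((medium_tree.n_tips, 2))
    base = _config(medium_tree, [], np.zeros((0, 2)))
    b = int(medium_tree.branch_nodes[5])
    with_null = _config(medium_tree, [b], np.zeros((1, 2)))
    assert ou_loglik(medium_tree, Y, base) == pytest.approx(
        ou_loglik(medium_tree, Y, with_null), abs=1e-10)


def test_ou_loglik_rejects_bad_input(medium_tree):
    Y = np.zeros((medium_tree.n_tips, 1))
    with pytest.raises(ValueError):
        _config(medium_tree, [], np.zeros((0, 1)), alpha=np.array([-1.0]),
                sigma2=np.array([1.0]), root=np.zeros(1))
    bad_tree = PhyloTree.from_newick("(A:1,(B:0.2,C:0.5):0.5);")
    with pytest.raises(ValueError):
        ou_loglik(bad_tree, np.zeros((3, 1)),
                  _config(bad_tree, [], np.zeros((0, 1)),
                          alpha=np.array([1.0]), sigma2=np.array([1.0]),
                          root=np.zeros(1)))


# ------------------------------------------------------------------ scoring

def test_pbic_exceeds_minus_two_loglik(medium_tree):
    Y = simulate_shifted_ou_traits(medium_tree, ALPHA, SIGMA2, [0.0, 0.0], [],
                                   seed=2)
    cfg = _config(medium_tree, [], np.zeros((0, 2)))
    cfg.loglik = ou_loglik(medium_tree, Y, cfg)
    assert pbic_score(medium_tree, Y, cfg) > -2 * cfg.loglik


def test_pbic_monotone_in_nested_configurations(medium_tree):
    Y = simulate_shifted_ou_traits(medium_tree, ALPHA, SIGMA2, [0.0, 0.0], [],
                                   seed=3)
    b = plant_branch(medium_tree)
    base = _config(medium_tree, [], np.zeros((0, 2)))
    base.loglik = ou_loglik(medium_tree, Y, base)
    bigger = _config(medium_tree, [b], np.zeros((1, 2)))
    bigger.loglik = ou_loglik(medium_tree, Y, bigger)
    assert bigger.loglik == pytest.approx(base.loglik, abs=1e-10)
    assert pbic_score(medium_tree, Y, bigger) > pbic_score(medium_tree, Y, base)
    assert bic_score(medium_tree, Y, bigger) > bic_score(medium_tree, Y, base)


def test_pbic_not_less_conservative_than_bic():
    """Across null replicates, pBIC never selects more shifts than BIC more
    often than the reverse."""
    sparser, denser = 0, 0
    for r in range(20):
        tree = simulate_tree(48, seed=500 + r)
        Y = simulate_shifted_ou_traits(tree, ALPHA, SIGMA2, [0.0, 0.0], [],
                                       seed=700 + r)
        kp = detect_shifts(tree, Y, SearchSettings(criterion="pbic")).n_shifts
        kb = detect_shifts(tree, Y, SearchSettings(criterion="bic")).n_shifts
        sparser += kp < kb
        denser += kp > kb
    assert sparser >= denser


# ------------------------------------------------------------------ search

def test_detect_shifts_deterministic():
    tree = simulate_tree(48, seed=4)
    b = plant_branch(tree)
    Y = simulate_shifted_ou_traits(tree, ALPHA, SIGMA2, [0.0, 0.0],
                                   [(b, 4 * STAT_SD)], seed=5)
    a = detect_shifts(tree, Y)
    c = detect_shifts(tree, Y)
    assert a.shift_branches == c.shift_branches
    assert a.score == c.score
    np.testing.assert_array_equal(a.beta, c.beta)


def test_detect_shifts_recovers_planted_branch():
    tree = simulate_tree(64, seed=6)
    b = plant_branch(tree)
    Y = simulate_shifted_ou_traits(tree, ALPHA, SIGMA2, [0.0, 0.0],
                                   [(b, 4 * STAT_SD)], seed=7)
    cfg = detect_shifts(tree, Y)
    neighborhood = {b, int(tree.parent[b])} | set(tree.children[b])
    assert set(cfg.shift_branches) & neighborhood
    # recovered optimum change has the planted sign and order of magnitude
    i = cfg.shift_branches.index(sorted(set(cfg.shift_branches) & neighborhood)[0])
    assert np.all(cfg.beta[i] > 0)
    assert cfg.loglik >= detect_shifts(
        tree, Y, SearchSettings(max_shifts=0)).loglik - 1e-6


def test_detect_shifts_max_shifts_cap():
    tree = simulate_tree(32, seed=8)
    Y = simulate_shifted_ou_traits(tree, ALPHA, SIGMA2, [0.0, 0.0], [], seed=9)
    for cap in (0, 1, 20, 50):
        cfg = detect_shifts(tree, Y, SearchSettings(max_shifts=cap))
        assert cfg.n_shifts <= cap
    assert SearchSettings().max_shifts == 50


def test_regime_painting_round_trip(medium_tree):
    branches = [plant_branch(medium_tree), int(medium_tree.branch_nodes[2])]
    branches = sorted(set(branches))
    cfg = _config(medium_tree, branches, np.ones((len(branches), 2)))
    painting = config_to_painting(medium_tree, cfg)
    painting.validate(medium_tree)
    assert painting_to_shifts(medium_tree, painting) == branches


def test_bootstrap_support_contract():
    tree = simulate_tree(48, seed=10)
    b = plant_branch(tree)
    Y = simulate_shifted_ou_traits(tree, ALPHA, SIGMA2, [0.0, 0.0],
                                   [(b, 6 * STAT_SD)], seed=11)
    cfg = detect_shifts(tree, Y)
    with pytest.raises(ValueError):
        bootstrap_support(tree, Y, cfg, n_bootstrap=10, seed=0)
    support = bootstrap_support(tree, Y, cfg, n_bootstrap=20, seed=0)
    assert set(support) == set(cfg.shift_branches)
    assert all(0.0 <= v <= 1.0 for v in support.values())
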