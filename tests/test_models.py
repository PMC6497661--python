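import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import multivariate_normal

from morphoshift import (MkModel, PhyloTree, RegimePainting, aicc,
                         compare_models, fit_bm, fit_eb, fit_mk, fit_ou1,
                         fit_oum, mk_node_marginals, simmap,
                         simulate_bm_traits, simulate_discrete_history,
                         simulate_shifted_ou_traits, simulate_tree)
from morphoshift.models import _eb_vcv
from morphoshift.shifts import (OUParams, ShiftConfiguration,
                                config_to_painting)


# ------------------------------------------------------------------- AICc

@pytest.mark.parametrize("logL,k,n,expected", [
    (-1476.06, 9, 606, 2970.42),     # cranium BM
    (-1333.007, 45, 606, 2763.41),   # cranium 12-regime shift model
    (-1456.83, 10, 606, 2934.03),    # cranium EB
    (-1626.32, 24, 764, 3302.26),    # mandible OU1
])
def test_aicc_reproduces_published_values(logL, k, n, expected):
    assert aicc(logL, k, n) == pytest.approx(expected, abs=0.01)


def test_aicc_requires_enough_observations():
    with pytest.raises(ValueError):
        aicc(-10.0, 9, 10)


# ------------------------------------------------------------ closed forms

def test_bm_two_tip_closed_form():
    t = 0.8
    tree = PhyloTree([-1, 0, 0], [0.0, t, t], {1: "A", 2: "B"})
    y = np.array([[1.1], [-0.5]])
    fit = fit_bm(tree, y)
    a = y.mean()
    s2 = ((y - a) ** 2).sum() / (2 * t)
    ll_hand = multivariate_normal.logpdf(y[:, 0], mean=[a, a],
                                         cov=s2 * t * np.eye(2))
    assert fit.loglik == pytest.approx(ll_hand, abs=1e-8)


def test_parameter_counts_p3():
    tree = simulate_tree(24, seed=0)
    Y = simulate_bm_traits(tree, 0.2 * np.eye(3), np.zeros(3), seed=1)
    assert fit_bm(tree, Y).k == 9
    assert fit_eb(tree, Y).k == 10
    assert fit_ou1(tree, Y, n_restarts=1, maxiter=60).k == 15


def test_parameter_counts_p4():
    tree = simulate_tree(24, seed=2)
    Y = simulate_bm_traits(tree, 0.2 * np.eye(4), np.zeros(4), seed=3)
    assert fit_bm(tree, Y).k == 14
    assert fit_eb(tree, Y).k == 15
    assert fit_ou1(tree, Y, n_restarts=1, maxiter=60).k == 24


def test_oum_twelve_regime_parameter_count_is_45():
    tree = simulate_tree(64, seed=4)
    Y = simulate_bm_traits(tree, 0.2 * np.eye(3), np.zeros(3), seed=5)
    branches = [int(b) for b in tree.branch_nodes
                if tree.tip_masks[b].sum() >= 3][:11]
    assert len(branches) == 11
    cfg = ShiftConfiguration(
        shift_branches=branches, beta=np.zeros((11, 3)),
        params=OUParams(np.ones(3), np.ones(3), np.zeros(3)))
    painting = config_to_painting(tree, cfg)
    assert painting.n_regimes() == 12
    fit = fit_oum(tree, Y, painting, structure="diagonal")
    assert fit.k == 45
    assert fit.n_regimes == 12


def test_eb_r_zero_equals_bm(medium_tree):
    Y = simulate_bm_traits(medium_tree, 0.3 * np.eye(2), np.zeros(2), seed=6)
    bm, eb = fit_bm(medium_tree, Y), fit_eb(medium_tree, Y)
    assert eb.loglik >= bm.loglik - 1e-8
    if eb.params["r"] == 0.0:
        assert eb.loglik == pytest.approx(bm.loglik, abs=1e-8)


def test_eb_recovery_prefers_eb_over_bm():
    hits = 0
    for r in range(50):
        tree = simulate_tree(128, seed=900 + r)
        C = _eb_vcv(tree, -3.0)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
        rng = np.random.default_rng(1200 + r)
        Y = L @ rng.standard_normal((128, 2))
        hits += fit_eb(tree, Y).aicc < fit_bm(tree, Y).aicc
    assert hits >= 40


def test_ou1_nests_bm(medium_tree):
    Y = simulate_bm_traits(medium_tree, 0.3 * np.eye(2), np.zeros(2), seed=7)
    assert fit_ou1(medium_tree, Y, n_restarts=2, maxiter=200).loglik >= \
        fit_bm(medium_tree, Y).loglik - 1e-6


def test_ou1_alpha_recovery_univariate():
    a_true = 8.0
    hits = 0
    for r in range(25):
        tree = simulate_tree(64, seed=1500 + r)
        Y = simulate_shifted_ou_traits(tree, [a_true], [1.0], [0.0], [],
                                       seed=1600 + r)
        fit = fit_ou1(tree, Y, n_restarts=2, maxiter=200)
        a_hat = float(np.linalg.eigvalsh(fit.params["alpha_matrix"]).max())
        hits += a_true / 2 <= a_hat <= a_true * 2
    assert hits >= 17   # >= 70%


def test_oum_single_state_equals_ou1():
    tree = simulate_tree(20, seed=8)
    Y = simulate_shifted_ou_traits(tree, [2.0, 2.0], [0.5, 0.5], [0.0, 0.0],
                                   [], seed=9)
    ou1 = fit_ou1(tree, Y)
    oum = fit_oum(tree, Y, RegimePainting.single_state(tree),
                  structure="symmetric")
    assert oum.loglik == pytest.approx(ou1.loglik, abs=1e-3)


def test_oum_recovers_planted_regime_optima():
    hits = 0
    for r in range(25):
        tree = simulate_tree(48, seed=2000 + r)
        b = next(int(x) for x in tree.branch_nodes
                 if 8 <= tree.tip_masks[x].sum() <= 20)
        alpha, sig = np.array([3.0, 3.0]), np.array([1.0, 1.0])
        sd = np.sqrt(sig / (2 * alpha))
        beta = 4 * sd
        Y = simulate_shifted_ou_traits(tree, alpha, sig, [0.0, 0.0],
                                       [(b, beta)], seed=2100 + r)
        cfg = ShiftConfiguration(shift_branches=[b], beta=beta[None, :],
                                 params=OUParams(alpha, sig, np.zeros(2)))
        fit = fit_oum(tree, Y, config_to_painting(tree, cfg))
        states = fit.params["states"]
        opt = fit.params["optima"]
        shift_state = f"shift_{b}"
        diff = opt[states.index(shift_state)] - opt[states.index("root")]
        hits += np.all(np.abs(diff - beta) < 2 * sd)
    assert hits >= 20   # >= 80%


# --------------------------------------------------------------------- Mk

def test_simmap_constant_character_stays_constant(medium_tree):
    tips = {l: "x" for l in medium_tree.tip_labels}
    mk = MkModel(states=["x"], Q=np.zeros((1, 1)), root_prior=np.ones(1),
                 loglik=0.0)
    maps = simmap(medium_tree, tips, n_maps=3, seed=0, mk=mk)
    for painting in maps:
        assert painting.n_regimes() == 1
        painting.validate(medium_tree)


def test_simmap_marginals_match_pruning_posteriors(four_tip_tree):
    """Node-state frequencies over many maps match the exact pruning-algorithm
    marginal posteriors within Monte-Carlo error."""
    Q = np.array([[-0.8, 0.8], [1.4, -1.4]])
    mk = MkModel(states=["a", "b"], Q=Q,
                 root_prior=np.array([1.4, 0.8]) / 2.2, loglik=0.0)
    tips = {"A": "a", "B": "b", "C": "b", "D": "a"}
    n_maps = 6000
    maps = simmap(four_tip_tree, tips, n_maps=n_maps, seed=1, mk=mk)
    marg = mk_node_marginals(four_tip_tree, tips, mk)
    freq = np.zeros_like(marg)
    for painting in maps:
        for b in four_tip_tree.branch_nodes:
            s = painting.segments[int(b)][-1][2]
            freq[b, mk.states.index(s)] += 1
        freq[four_tip_tree.root, mk.states.index(painting.root_state)] += 1
    freq /= n_maps
    se = np.sqrt(np.clip(marg * (1 - marg), 1e-9, None) / n_maps)
    assert np.all(np.abs(freq - marg) < 4 * se + 1e-9)


def test_simmap_default_map_count_and_errors(four_tip_tree):
    import inspect
    assert inspect.signature(simmap).parameters["n_maps"].default == 100
    with pytest.raises(ValueError):
        simmap(four_tip_tree, {"A": "a"}, n_maps=5)
    with pytest.raises(ValueError):
        fit_mk(four_tip_tree, {"A": "a", "B": "a", "C": "a", "D": "a"},
               states=["a", "ghost"])


def test_mk_fit_recovers_plausible_rates(medium_tree):
    Q = np.array([[-2.0, 2.0], [2.0, -2.0]])
    hist = simulate_discrete_history(medium_tree, Q, seed=3, states=["a", "b"])
    if len(set(hist["tip_states"].values())) < 2:
        pytest.skip("degenerate character draw")
    mk = fit_mk(medium_tree, hist["tip_states"], model="ER")
    assert 0.05 < mk.Q[0, 1] < 50.0
    np.testing.assert_allclose(mk.Q.sum(axis=1), 0.0, atol=1e-10)


def test_simmap_newick_serialization(four_tip_tree):
    Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
    mk = MkModel(states=["a", "b"], Q=Q, root_prior=np.array([0.5, 0.5]),
                 loglik=0.0)
    tips = {"A": "a", "B": "b", "C": "b", "D": "a"}
    painting = simmap(four_tip_tree, tips, n_maps=1, seed=5, mk=mk)[0]
    text = painting.to_simmap_newick(four_tip_tree)
    assert text.endswith(";") and text.count("{") == len(
        four_tip_tree.branch_nodes)
    # per-branch annotated durations sum to the branch length
    import re
    for annot, length in re.findall(r"\{([^}]*)\}([0-9.eE+-]+)", text):
        total = sum(float(seg.split(":")[1]) for seg in annot.split(","))
        assert total == pytest.approx(float(length), abs=1e-6)


def test_mk_transition_matrix_is_proper(four_tip_tree):
    Q = np.array([[-1.0, 1.0], [0.5, -0.5]])
    P = expm(Q * 0.7)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


# -------------------------------------------------------------- comparison

def test_compare_models_best_has_zero_delta(medium_tree):
    Y = simulate_bm_traits(medium_tree, 0.2 * np.eye(2), np.zeros(2), seed=10)
    table = compare_models({"BM": fit_bm(medium_tree, Y),
                            "EB": fit_eb(medium_tree, Y)})
    assert table["delta_aicc"].iloc[0] == 0.0
    assert table["delta_aicc"].is_monotonic_increasing


def test_compare_models_generating_family_wins():
    """Data generated under a multi-regime OU is best fit by that model."""
    tree = simulate_tree(64, seed=11)
    alpha, sig = np.array([4.0, 4.0]), np.array([1.0, 1.0])
    sd = np.sqrt(sig / (2 * alpha))
    branches = [int(b) for b in tree.branch_nodes
                if tree.tip_masks[b].sum() >= 4][:5]
    rng = np.random.default_rng(12)
    shifts = [(b, (4 + 2 * rng.random()) * sd * rng.choice([-1, 1], 2))
              for b in branches]
    Y = simulate_shifted_ou_traits(tree, alpha, sig, [0.0, 0.0], shifts,
                                   seed=13)
    cfg = ShiftConfiguration(
        shift_branches=branches,
        beta=np.stack([s[1] for s in shifts]),
        params=OUParams(alpha, sig, np.zeros(2)))
    fits = {"shift_model": fit_oum(tree, Y, config_to_painting(tree, cfg)),
            "BM": fit_bm(tree, Y), "EB": fit_eb(tree, Y),
            "OU1": fit_ou1(tree, Y, n_restarts=2, maxiter=300)}
    table = compare_models(fits)
    assert table["model"].iloc[0] == "shift_model"


def test_compare_models_distribution_summaries(medium_tree):
    Y = simulate_bm_traits(medium_tree, 0.2 * np.eye(2), np.zeros(2), seed=14)
    group = [fit_bm(medium_tree, Y + eps)
             for eps in (0.0, 0.001, -0.001)]
    table = compare_models({"BM_maps": group, "EB": fit_eb(medium_tree, Y)})
    row = table[table["model"] == "BM_maps"].iloc[0]
    assert row["aicc_min"] <= row["aicc"] <= row["aicc_max"]
    assert row["n_maps"] == 3


def test_compare_models_rejects_mixed_data(medium_tree):
    Y2 = simulate_bm_traits(medium_tree, 0.2 * np.eye(2), np.zeros(2), seed=15)
    Y3 = simulate_bm_traits(medium_tree, 0.2 * np.eye(3), np.zeros(3), seed=16)
    with pytest.raises(ValueError):
        compare_models({"a": fit_bm(medium_tree, Y2),
                        "b": fit_bm(medium_tree, Y3)})
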