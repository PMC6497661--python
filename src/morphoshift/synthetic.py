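"""Synthetic trees, traits, landmark datasets and discrete characters.

Every generator takes an explicit integer seed and is deterministic given its
arguments, so downstream stages (superimposition, morphospaces, disparity,
shift detection, model comparison) can be tested against known ground truth.
Trees are pure-birth and rescaled to unit depth, matching the relative-time
axis used by disparity-through-time analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import LandmarkDataset, symmetrize
from .trees import PhyloTree

__all__ = [
    "SimulatedDataset", "simulate_tree", "simulate_bm_traits",
    "simulate_shifted_ou_traits", "simulate_landmark_dataset",
    "simulate_discrete_history", "make_template",
]


@dataclass
class SimulatedDataset:
    """A simulation bundle with ground truth for downstream testing."""

    tree: PhyloTree
    seed: int
    landmarks: LandmarkDataset | None = None
    traits: np.ndarray | None = None
    true_shifts: list[tuple[int, np.ndarray]] = field(default_factory=list)
    true_history: dict | None = None

    def __post_init__(self):
        if not self.tree.is_ultrametric(rel_tol=1e-8):
            raise ValueError("simulated tree must be ultrametric")
        branch_ids = set(self.tree.branch_nodes.tolist())
        for b, _ in self.true_shifts:
            if b not in branch_ids:
                raise ValueError(f"true shift on unknown branch {b}")
        if self.traits is not None and self.traits.shape[0] != self.tree.n_tips:
            raise ValueError("trait rows must follow the tree tip order")


# ------------------------------------------------------------------- trees

def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Simulate a pure-birth (Yule) ultrametric tree rescaled to unit depth.

    Tips are labelled ``sp_0001 .. sp_{n}``; the same seed always yields the
    same tree.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    parent = [-1]
    length = [0.0]
    # active lineages: (parent node id, birth time)
    active: list[tuple[int, float]] = [(0, 0.0), (0, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        j = int(rng.integers(len(active)))
        pnode, birth = active.pop(j)
        node = len(parent)
        parent.append(pnode)
        length.append(t - birth)
        active.insert(j, (node, t))
        active.insert(j + 1, (node, t))
    T = t + rng.exponential(1.0 / (birth_rate * len(active)))
    labels = {}
    for i, (pnode, birth) in enumerate(active):
        node = len(parent)
        parent.append(pnode)
        length.append(T - birth)
        labels[node] = f"sp_{i + 1:04d}"
    tree = PhyloTree(parent, length, labels)
    return tree.rescaled(1.0)


# ---------------------------------------------------------------- BM traits

def _psd_factor(rate_matrix: np.ndarray) -> np.ndarray:
    R = np.asarray(rate_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("rate matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("rate matrix must be symmetric")
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-10 * max(abs(w).max(), 1.0):
        raise ValueError("rate matrix must be positive semi-definite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_bm_traits(tree: PhyloTree, rate_matrix: np.ndarray,
                       root_state: np.ndarray, seed: int = 0) -> np.ndarray:
    """Multivariate Brownian motion tip values, rows in tip-label order.

    Per-branch increments are mean-zero multivariate normal with covariance
    (branch length x rate matrix); a tip's value is the root state plus the
    increments along its root-to-tip path.
    """
    A = _psd_factor(rate_matrix)
    root = np.atleast_1d(np.asarray(root_state, dtype=float))
    rng = np.random.default_rng(seed)
    branches = tree.branch_nodes
    Z = rng.standard_normal((len(branches), len(root))) @ A.T
    Z *= np.sqrt(tree.length[branches])[:, None]
    masks = tree.tip_masks[branches].astype(float)  # (branches, tips)
    return root[None, :] + masks.T @ Z


# --------------------------------------------------------- shifted OU traits

def _branch_optima(tree: PhyloTree, root_optima: np.ndarray,
                   shifts: list[tuple[int, np.ndarray]]) -> np.ndarray:
    """Per-node optimum vectors: root optimum plus ancestral (inclusive) shift changes."""
    p = len(root_optima)
    delta = np.zeros((tree.n_nodes, p))
    branch_ids = set(tree.branch_nodes.tolist())
    for b, change in shifts:
        if b not in branch_ids:
            raise ValueError(f"shift branch {b} does not exist")
        delta[b] += np.asarray(change, dtype=float)
    theta = np.tile(np.asarray(root_optima, dtype=float), (tree.n_nodes, 1))
    for nd in tree.preorder:
        if nd == tree.root:
            continue
        theta[nd] = theta[tree.parent[nd]] + delta[nd]
    return theta


def simulate_shifted_ou_traits(tree: PhyloTree, alpha, sigma2, root_optima,
                               shifts: list[tuple[int, np.ndarray]] | None = None,
                               seed: int = 0) -> np.ndarray:
    """Per-trait independent OU with optimum shifts on known branches.

    The optimum along a branch is the root optimum plus the summed optimum
    changes on ancestral shift branches, including the shift branch itself.
    The root state equals the root optimum.  Exact transition sampling along
    each branch: x_child = theta + (x_parent - theta) e^{-a L} + N(0, s2 (1 -
    e^{-2 a L}) / (2 a)).
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    root_optima = np.atleast_1d(np.asarray(root_optima, dtype=float))
    if np.any(alpha <= 0) or np.any(sigma2 <= 0):
        raise ValueError("alpha and sigma2 must be positive")
    theta = _branch_optima(tree, root_optima, shifts or [])
    rng = np.random.default_rng(seed)
    x = np.zeros((tree.n_nodes, len(root_optima)))
    x[tree.root] = root_optima
    for nd in tree.preorder:
        if nd == tree.root:
            continue
        L = tree.length[nd]
        decay = np.exp(-alpha * L)
        var = sigma2 * (1.0 - np.exp(-2.0 * alpha * L)) / (2.0 * alpha)
        mean = theta[nd] + (x[tree.parent[nd]] - theta[nd]) * decay
        x[nd] = mean + np.sqrt(var) * rng.standard_normal(len(root_optima))
    return x[tree.tips]


def shifted_ou_expectation(tree: PhyloTree, alpha, root_optima,
                           shifts: list[tuple[int, np.ndarray]] | None = None
                           ) -> np.ndarray:
    """Deterministic tip expectation of the shifted-OU process (no noise)."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    root_optima = np.atleast_1d(np.asarray(root_optima, dtype=float))
    theta = _branch_optima(tree, root_optima, shifts or [])
    m = np.zeros((tree.n_nodes, len(root_optima)))
    m[tree.root] = root_optima
    for nd in tree.preorder:
        if nd == tree.root:
            continue
        decay = np.exp(-alpha * tree.length[nd])
        m[nd] = theta[nd] + (m[tree.parent[nd]] - theta[nd]) * decay
    return m[tree.tips]


# ------------------------------------------------------------ landmark data

def make_template(n_semis: int = 7):
    """A bilaterally symmetric template configuration with curves.

    Three midline anchors with a midline curve between the first two, plus
    three bilaterally paired fixed landmarks and a paired curve on each side.
    Returns (template (k, 3), curves, pairs, midline) with k = 9 + 3*n_semis.
    """
    pts: list[np.ndarray] = []

    def add(p):
        pts.append(np.asarray(p, dtype=float))
        return len(pts) - 1

    m0 = add([0.0, 0.0, 0.0])
    m1 = add([2.0, 0.0, 0.0])
    m2 = add([1.0, 0.0, 0.8])
    mid_curve = [m0]
    for j in range(1, n_semis + 1):
        u = j / (n_semis + 1)
        mid_curve.append(add([2.0 * u, 0.0, 0.45 * np.sin(np.pi * u)]))
    mid_curve.append(m1)
    left_fixed = [add([0.5, 0.6, 0.2]), add([1.5, 0.7, 0.1]), add([1.0, 0.9, 0.5])]
    right_fixed = [add(pts[i] * [1, -1, 1]) for i in left_fixed]
    lc = [left_fixed[0]]
    left_ids = []
    for j in range(1, n_semis + 1):
        u = j / (n_semis + 1)
        a, b = pts[left_fixed[0]], pts[left_fixed[1]]
        left_ids.append(add(a + u * (b - a) + [0.0, 0.25 * np.sin(np.pi * u), 0.0]))
    lc += left_ids + [left_fixed[1]]
    rc = [right_fixed[0]]
    right_ids = [add(pts[i] * [1, -1, 1]) for i in left_ids]
    rc += right_ids + [right_fixed[1]]
    template = np.array(pts)
    curves = [{"ids": mid_curve, "fixed_ends": True},
              {"ids": lc, "fixed_ends": True},
              {"ids": rc, "fixed_ends": True}]
    pairs = list(zip(left_fixed, right_fixed)) + list(zip(left_ids, right_ids))
    midline = [m0, m1, m2] + mid_curve[1:-1]
    return template, curves, pairs, midline


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def simulate_landmark_dataset(tree: PhyloTree, template_shape: np.ndarray | None = None,
                              rate: float = 0.001, missing_fraction: float = 0.0,
                              bilateral_pairs=None, seed: int = 0,
                              curves=None, midline=None,
                              n_specimens_per_species: int = 1,
                              within_species_sd: float = 0.0,
                              asymmetry: float = 0.2,
                              trait_shifts: dict | None = None) -> LandmarkDataset:
    """Landmark configurations evolving by Brownian motion on a template.

    Species shapes are the template plus BM deviations over the tree (rate x
    identity over all 3k coordinates); deviations are predominantly bilateral
    (an ``asymmetry`` fraction of the raw deviation is left unsymmetrized,
    emulating near-symmetric organisms).  Each specimen is then arbitrarily
    rotated, translated and log-normally scaled, and ``missing_fraction`` of
    landmark slots is masked, never both members of a bilateral pair in the
    same specimen.  Ground-truth (pre-masking, pre-transform) coordinates are
    retained in ``true_coordinates``.

    ``trait_shifts`` optionally superimposes shifted-OU trait deviations on
    the BM background so adaptive-zone shifts are expressed in the shapes:
    ``{"shifts": [(branch, per-trait change vector)], "alpha": [...],
    "sigma2": [...]}``; each trait deforms the template along a fixed,
    seed-deterministic orthonormal direction in coordinate space.
    """
    if not 0.0 <= missing_fraction < 0.2:
        raise ValueError("missing_fraction must be in [0, 0.2); observed real-data "
                         "missingness is <= 5.5%")
    if template_shape is None:
        template_shape, curves, bilateral_pairs, midline = make_template()
    template_shape = np.asarray(template_shape, dtype=float)
    k = template_shape.shape[0]
    if k < 4 or np.linalg.matrix_rank(template_shape - template_shape.mean(0)) < 3:
        raise ValueError("template needs >= 4 non-coplanar landmarks")
    bilateral_pairs = [tuple(p) for p in (bilateral_pairs or [])]
    midline = list(midline or [])
    curves = list(curves or [])
    rng = np.random.default_rng(seed)
    if rate > 0:
        dev = simulate_bm_traits(tree, rate * np.eye(3 * k), np.zeros(3 * k),
                                 seed=int(rng.integers(2 ** 31)))
    else:
        dev = np.zeros((tree.n_tips, 3 * k))
    species_shapes = template_shape[None] + dev.reshape(tree.n_tips, k, 3)
    if trait_shifts is not None:
        ts_alpha = np.atleast_1d(np.asarray(trait_shifts.get("alpha", 3.0), float))
        ts_sig = np.atleast_1d(np.asarray(trait_shifts.get("sigma2", 1e-4), float))
        shift_list = [(int(b), np.atleast_1d(np.asarray(v, float)))
                      for b, v in trait_shifts["shifts"]]
        q = len(shift_list[0][1])
        if len(ts_alpha) == 1:
            ts_alpha = np.repeat(ts_alpha, q)
        if len(ts_sig) == 1:
            ts_sig = np.repeat(ts_sig, q)
        traits = simulate_shifted_ou_traits(tree, ts_alpha, ts_sig,
                                            np.zeros(q), shift_list,
                                            seed=int(rng.integers(2 ** 31)))
        dirs = np.linalg.qr(
            np.random.default_rng(seed + 911).standard_normal((3 * k, q)))[0]
        species_shapes += (traits @ dirs.T).reshape(tree.n_tips, k, 3)
    if bilateral_pairs and len(midline) >= 3:
        for i in range(tree.n_tips):
            sym = symmetrize(species_shapes[i], bilateral_pairs, midline)
            species_shapes[i] = (1 - asymmetry) * sym + asymmetry * species_shapes[i]
    ids, species_map, coords, truth = [], {}, [], []
    for i, sp in enumerate(tree.tip_labels):
        for j in range(n_specimens_per_species):
            sid = f"{sp}_s{j + 1}"
            shape = species_shapes[i].copy()
            if within_species_sd > 0:
                shape = shape + within_species_sd * rng.standard_normal(shape.shape)
            truth.append(shape.copy())
            R = _random_rotation(rng)
            scale = float(np.exp(rng.normal(0.0, 0.1)))
            shift = rng.normal(0.0, 1.0, size=3)
            coords.append(scale * shape @ R.T + shift)
            ids.append(sid)
            species_map[sid] = sp
    coords = np.array(coords)
    truth = np.array(truth)
    missing = rng.random((len(ids), k)) < missing_fraction
    paired_right = {r: l for l, r in bilateral_pairs}
    for l, r in bilateral_pairs:
        both = missing[:, l] & missing[:, r]
        missing[both, r] = False  # keep one member of each pair
    coords[missing] = np.nan
    return LandmarkDataset(ids, species_map, coords, missing, curves=curves,
                           bilateral_pairs=bilateral_pairs, midline=midline,
                           true_coordinates=truth)


# ------------------------------------------------------- discrete characters

def simulate_discrete_history(tree: PhyloTree, Q: np.ndarray, seed: int = 0,
                              states: list[str] | None = None,
                              root_state: int | None = None) -> dict:
    """Evolve a discrete character under an Mk model with rate matrix Q.

    Returns a dict with ``tip_states`` (label -> state name), ``node_states``
    and ``segments``: per-branch lists of (t_start, t_end, state) giving the
    full character history (a regime painting).
    """
    Q = np.asarray(Q, dtype=float)
    ns = Q.shape[0]
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
        raise ValueError("Q rows must sum to 0")
    states = states or [str(i) for i in range(ns)]
    rng = np.random.default_rng(seed)
    if root_state is None:
        w, V = np.linalg.eig(Q.T)
        pi = np.real(V[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        root_state = int(rng.choice(ns, p=pi))
    node_state = np.zeros(tree.n_nodes, dtype=int)
    node_state[tree.root] = root_state
    segments: dict[int, list[tuple[float, float, str]]] = {}
    depths = tree.depths
    for nd in tree.preorder:
        if nd == tree.root:
            continue
        s = node_state[tree.parent[nd]]
        t0, t1 = depths[tree.parent[nd]], depths[nd]
        t = t0
        segs = []
        while True:
            rate = -Q[s, s]
            wait = np.inf if rate <= 0 else rng.exponential(1.0 / rate)
            if t + wait >= t1:
                segs.append((t, t1, states[s]))
                break
            segs.append((t, t + wait, states[s]))
            t += wait
            probs = Q[s].clip(0.0)
            probs[s] = 0.0
            s = int(rng.choice(ns, p=probs / probs.sum()))
        node_state[nd] = s
        segments[nd] = segs
    tip_states = {tree.tip_labels[r]: states[node_state[t]]
                  for r, t in enumerate(tree.tips)}
    return {"tip_states": tip_states, "node_states": node_state,
            "segments": segments, "states": states}
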