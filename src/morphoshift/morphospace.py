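"""Morphospaces: standard and phylogenetically corrected principal components.

The phylogenetic PCA (pPCA) eigendecomposes the evolutionary covariance
matrix, i.e. the trait covariance after generalized-least-squares removal of
the Brownian-motion tip covariance implied by the tree; scores are computed
about the GLS root estimate.  Because pPCA eigenvalues no longer sum to the
raw variance, per-axis absolute shape variation is attributed by a sequential
(type-I) multiple regression of the full coordinate matrix on the axis
scores; axis retention uses Horn's parallel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import PhyloTree

__all__ = ["Morphospace", "pca", "ppca", "parallel_analysis",
           "axis_variance_r2", "scale_scores"]


@dataclass
class Morphospace:
    scores: np.ndarray          # (n_species, p)
    loadings: np.ndarray        # (n_traits, p), orthonormal columns
    eigenvalues: np.ndarray     # (p,)
    correction: str             # "phylogenetic" or "none"
    species: list[str] = field(default_factory=list)
    ancestral_mean: np.ndarray | None = None
    r2: np.ndarray | None = None
    n_critical: int | None = None


def _sign_convention(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def pca(mean_shapes: np.ndarray, species: list[str] | None = None) -> Morphospace:
    """Ordinary covariance PCA on mean-centered data."""
    X = np.asarray(mean_shapes, dtype=float)
    X = X.reshape(X.shape[0], -1)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 species")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), _sign_convention(V[:, order])
    return Morphospace(scores=Xc @ V, loadings=V, eigenvalues=w,
                       correction="none", species=list(species or []))


def _gls_root(X: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    one = np.ones(X.shape[0])
    return (one @ Cinv @ X) / (one @ Cinv @ one)


def ppca(mean_shapes: np.ndarray, tree: PhyloTree,
         species: list[str] | None = None) -> Morphospace:
    """Phylogenetic PCA under a Brownian-motion model.

    With C the BM tip covariance from the tree, the ancestral mean is the GLS
    root estimate a = (1'C^-1 1)^-1 1'C^-1 X, the evolutionary covariance is
    R = (X-1a')' C^-1 (X-1a')/(n-1), and scores are (X-1a') V for eigenvectors
    V of R.  Rows of ``mean_shapes`` must follow ``species`` (defaults to the
    tree's tip order).
    """
    X = np.asarray(mean_shapes, dtype=float)
    X = X.reshape(X.shape[0], -1)
    species = list(species or tree.tip_labels)
    if sorted(species) != sorted(tree.tip_labels):
        extra = sorted(set(species) ^ set(tree.tip_labels))
        raise ValueError(f"species/tip mismatch: {extra}")
    if X.shape[0] != tree.n_tips:
        raise ValueError("one row per tree tip required")
    idx = tree.reorder_index(species)  # position of each requested label in tree order
    C = tree.vcv[np.ix_(idx, idx)]
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc
    a = _gls_root(X, Cinv)
    Xc = X - a
    R = Xc.T @ Cinv @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), _sign_convention(V[:, order])
    return Morphospace(scores=Xc @ V, loadings=V, eigenvalues=w,
                       correction="phylogenetic", species=species,
                       ancestral_mean=a)


def _whiten(X: np.ndarray, tree: PhyloTree, species: list[str] | None) -> np.ndarray:
    species = list(species or tree.tip_labels)
    idx = tree.reorder_index(species)
    C = tree.vcv[np.ix_(idx, idx)]
    w, U = np.linalg.eigh(C)
    if w.min() <= 0:
        raise ValueError("singular phylogenetic covariance matrix")
    Cmhalf = (U / np.sqrt(w)) @ U.T
    Cinv = (U / w) @ U.T
    a = _gls_root(X, Cinv)
    return Cmhalf @ (X - a)


def parallel_analysis(data: np.ndarray, tree: PhyloTree | None = None,
                      n_perm: int = 500, quantile: float = 0.95,
                      seed: int = 0, species: list[str] | None = None) -> int:
    """Horn's parallel analysis as an axis-retention stopping rule.

    Columns of the (GLS-whitened, when a tree is given) data are permuted
    independently ``n_perm`` times; axes are retained while the observed
    eigenvalue exceeds the chosen quantile of permuted eigenvalues at the same
    rank, stopping at the first failure.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    X = np.asarray(data, dtype=float)
    X = X.reshape(X.shape[0], -1)
    if tree is not None:
        X = _whiten(X, tree, species)
    Xc = X - X.mean(axis=0)
    n, m = Xc.shape
    obs = np.sort(np.linalg.svd(Xc, compute_uv=False) ** 2)[::-1] / (n - 1)
    rng = np.random.default_rng(seed)
    r = min(n, m)
    perm_eigs = np.empty((n_perm, r))
    Z = Xc.copy()
    for b in range(n_perm):
        for j in range(m):
            Z[:, j] = Xc[rng.permutation(n), j]
        s = np.linalg.svd(Z - Z.mean(axis=0), compute_uv=False)
        perm_eigs[b] = np.sort(s ** 2)[::-1][:r] / (n - 1)
    thresh = np.quantile(perm_eigs, quantile, axis=0)
    n_critical = 0
    for j in range(r):
        if obs[j] > thresh[j]:
            n_critical += 1
        else:
            break
    return n_critical


def axis_variance_r2(aligned_shapes: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Per-axis absolute shape variation by sequential (type-I) regression R^2.

    Regresses the full coordinate matrix on the score columns in order; each
    axis's R^2 is its sequential sum of squares over the total sum of squares
    (computed over all coordinates).  For standard-PCA scores this equals
    eigenvalue/trace.
    """
    Y = np.asarray(aligned_shapes, dtype=float)
    Y = Y.reshape(Y.shape[0], -1)
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[0] != Y.shape[0]:
        raise ValueError("scores not row-matched to shapes")
    Sc = S - S.mean(axis=0)
    if np.linalg.matrix_rank(Sc) < Sc.shape[1]:
        raise ValueError("rank-deficient scores")
    Yc = Y - Y.mean(axis=0)
    tss = (Yc ** 2).sum()
    Q, _ = np.linalg.qr(Sc)
    ss = ((Q.T @ Yc) ** 2).sum(axis=1)
    return ss / tss


def scale_scores(scores: np.ndarray, factor: float) -> np.ndarray:
    """Elementwise rescaling of axis scores (e.g. x100 before OU model fitting).

    Rescaling only changes the scale of fitted evolutionary parameters, not
    relative model fit.
    """
    if factor == 0:
        raise ValueError("factor must be nonzero")
    return np.asarray(scores, dtype=float) * factor
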