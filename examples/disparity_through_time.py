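"""Disparity-through-time and the morphological disparity index (MDI).

Compares the observed decline of average subclade disparity (mean pairwise
Procrustes distance) against Brownian-motion simulations; a negative MDI with
a small p indicates disparity established early, between old lineages.
"""

import numpy as np

from morphoshift import mdi_test, simulate_tree
from morphoshift.models import _eb_vcv
from morphoshift.synthetic import make_template

template, *_ = make_template()
k = template.shape[0]
tree = simulate_tree(64, seed=6)

# early-burst shapes: Brownian deviations whose rate decays as e^{-5t}
C = _eb_vcv(tree, -5.0)
L = np.linalg.cholesky(C + 1e-12 * np.eye(64))
rng = np.random.default_rng(7)
dev = L @ rng.standard_normal((64, 3 * k)) * np.sqrt(0.005)
shapes = template[None] + dev.reshape(64, k, 3)

res = mdi_test(tree, shapes, n_sim=200, seed=8)
print(f"MDI = {res.mdi:.4f}, one-sided p = {res.p_value:.3f} "
      f"({res.n_sim} BM simulations)")
mid = len(res.times) // 2
print(f"observed relative disparity at t={res.times[mid]:.2f}: "
      f"{res.observed[mid]:.3f} vs BM median {res.median_curve[mid]:.3f}")
# A negative MDI means the observed curve runs below the BM median: subclades
# are morphologically homogeneous relative to the whole radiation, i.e.
# disparity was partitioned among lineages early in the clade's history.
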