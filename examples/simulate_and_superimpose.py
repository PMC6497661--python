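"""Simulate a landmark dataset, complete missing landmarks, and superimpose.

Generates 40 species of 30-landmark skull-like configurations evolving by
Brownian motion on a birth-death tree, masks 5% of landmarks, fills them by
reflected relabeling + low-rank imputation, and runs generalized Procrustes
analysis with semilandmark sliding.
"""

import numpy as np

from morphoshift import (estimate_missing, gpa_align, simulate_landmark_dataset,
                         simulate_tree, species_consensus)

tree = simulate_tree(40, seed=1)
dataset = simulate_landmark_dataset(tree, missing_fraction=0.05, seed=2)
print(f"{dataset.n_specimens} specimens x {dataset.n_landmarks} landmarks; "
      f"{int(dataset.missing.sum())} cells missing "
      f"({100 * dataset.missing.mean():.1f}%)")

filled = estimate_missing(dataset)
by_method = {}
for v in filled.fill_provenance.values():
    if isinstance(v, str):
        by_method[v] = by_method.get(v, 0) + 1
print(f"filled by reflection: {by_method.get('reflection', 0)}, "
      f"by low-rank imputation: {by_method.get('bpca', 0)}")

alignment = gpa_align(filled, slide=True)
print(f"GPA converged in {alignment.iterations} iterations "
      f"(consensus change < 1e-8)")

names, consensus = species_consensus(alignment, filled.species,
                                     filled.bilateral_pairs, filled.midline)
rms = np.sqrt(((consensus - consensus.mean(axis=0)) ** 2).mean())
print(f"{len(names)} species consensus shapes; RMS shape deviation from the "
      f"grand mean = {rms:.4f} (Procrustes units)")
# The RMS deviation is the raw morphological disparity the downstream
# analyses (morphospaces, disparity-through-time) decompose.
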