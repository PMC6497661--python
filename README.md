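# morphoshift

Macroevolutionary analysis of 3D shape on time-calibrated phylogenies, built
for the kind of question a comparative morphologist asks of a large
geometric-morphometric dataset — for example, cranium and mandible landmarks
across a mammalian radiation: **was morphological diversity produced by an
early burst of evolution, or by discrete shifts between Simpsonian adaptive
zones, and do those shifts track ecology?**

The package covers the full path from raw landmark configurations to fitted
evolutionary models:

1. **Landmarks** — long-format CSV / TPS input, arc-length curve resampling,
   missing-landmark completion (reflected relabeling across the midsagittal
   plane, then iterative low-rank PCA imputation), generalized Procrustes
   analysis with Procrustes-distance sliding of semilandmarks, bilaterally
   symmetrized species consensus shapes.
2. **Morphospaces** — phylogenetic PCA (eigendecomposition of the
   evolutionary covariance `R = (X-1a')' C⁻¹ (X-1a')/(n-1)` about the GLS
   root `a`, with `C` the Brownian tip covariance) and standard PCA; Horn's
   parallel analysis as the axis-retention rule; per-axis absolute shape
   variation by sequential Procrustes multiple regression R².
3. **Disparity through time** — relative subclade disparity (mean pairwise
   Procrustes distance) through relative time, and the morphological
   disparity index `MDI = ∫ (D_obs − D̃_BM) dt` with a one-sided
   simulation p-value under multivariate Brownian motion.
4. **Tanglegrams** — UPGMA on Procrustes distances, co-rotation against the
   phylogeny, and the tip-displacement statistic (mean |rank difference|)
   tested against a Brownian null.
5. **Adaptive-zone shifts** — multi-peak Ornstein–Uhlenbeck shift detection:
   a multi-task lasso path over the phylogenetically whitened branch design
   proposes sparse shift sets shared across trait axes, candidates are refit
   by maximum likelihood and ranked by pBIC (placement term
   `2K log(2n−3)` plus the per-trait log-determinant of the GLS information
   of the shift design), with parametric-bootstrap support per shift.
6. **Model comparison** — fully multivariate BM, single-optimum OU, early
   burst and multi-peak OU (on shift configurations or stochastic character
   maps of discrete ecology), ranked by `AICc = −2logL + 2k +
   2k(k+1)/(n−k−1)` with `n = tips × traits`; SIMMAP stochastic character
   mapping under ML Mk models, ensembles summarized as median (min, max).

A seeded synthetic-data generator (pure-birth trees, multivariate BM
landmark evolution, shifted-OU trait axes, Mk characters, realistic
missingness with bilateral structure) makes every stage testable against
known ground truth.

## Worked example

`examples/detect_adaptive_shifts.py` plants a single optimum shift of four
stationary standard deviations on an early branch of a 64-tip tree and runs
the full search:

```
planted shift on branch 6 (9 descendant tips)
selected 1 shift(s) on branches [6]; pBIC = 136.19
  branch 6: optimum change [1.53 1.79] (planted [1.63 1.63])
  bootstrap support for branch 6: 0.93 (well-supported)
```

The search recovered exactly the planted branch; the estimated per-axis
optimum changes (1.53, 1.79) bracket the planted 1.63, and the shift appears
in 93% of parametric-bootstrap replicates — above the 0.7 convention for a
well-supported shift. The other scripts in `examples/` walk through
superimposition, morphospace construction, disparity-through-time
(`MDI = -0.213, p = 0.000` on early-burst data), the tanglegram test, and
the model-comparison table (the generating shift model wins with
ΔAICc ≥ 38 over BM/OU1/EB).

The `morphoshift` command wraps the same library for shell use:
`morphoshift simulate`, `morphoshift run --config config.yaml`,
`morphoshift shifts --scores S.csv --tree T.nwk`.

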