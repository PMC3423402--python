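# Methods

`connmod` implements a resting-state functional-connectivity analysis of a
two-group (control vs patient) cohort, centred on the mid-scale community
structure of correlation networks. This note describes the models, the
numerical choices, and what the synthetic cohort generator does and does
not emulate.

## Pipeline model

Each subject contributes a T x N matrix of regional activity (N regions of
a bilateral parcellation, T time points). The analysis proceeds:

1. **Connectivity.** Zero-lag Pearson correlation of all region pairs gives
   a symmetric N x N matrix with unit diagonal.
2. **Distance penalty.** Resting-state correlations decay roughly
   logarithmically with inter-regional distance. Per subject, ordinary
   least squares fits r(i,j) = a + b·log d(i,j) over all unordered pairs
   (d = Euclidean distance between region centroids, mm) and the fitted
   trend is subtracted, leaving a signed residual matrix that emphasises
   connections that are strong relative to their spatial proximity
   (homotopic pairs in particular). The penalty operates on raw
   correlations, not Fisher-z values, and includes homotopic pairs in the
   fit. Residual scale is compared between groups (Welch t on subject-wise
   residual SD) as a sanity check that the correction behaves identically
   in both groups.
3. **Community structure** is found on the FULL signed residual matrix —
   no thresholding — with the asymmetric signed modularity

       Q* = Q+ − (v⁻/(v⁺+v⁻)) Q−,
       Q± = (1/v±) Σ_ij (w±_ij − s±_i s±_j / v±) δ(m_i, m_j),

   where w⁺/w⁻ are the positive/negative weight parts, s± node strengths
   and v± total weights. Positive weights are rewarded inside modules at
   full strength; negative weights are penalised with the down-weighting
   v⁻/(v⁺+v⁻), so negative edges delineate module boundaries without
   dominating. The optimiser is a multi-level Louvain-style greedy
   agglomeration (random node order per pass, seed-controlled) with random
   restarts; the module count follows from the objective's own stopping
   behaviour. Resolution is fixed at 1.
4. **Thresholding** renders the residual matrix sparse for all other graph
   metrics: the weakest positive edges are discarded until
   round(density·N(N−1)/2) edges remain, never removing an edge whose loss
   would disconnect the graph, and never retaining negative or zero
   weights. This greedy ascending-removal/bridge-skip rule is implemented
   as maximum-spanning-tree retention plus strongest-edge fill, which is
   provably the same set (spanning-tree cycle/cut properties); ties are
   broken deterministically by index. The default density is 12%; when the
   exact target is unreachable (below spanning-tree density, or too few
   positive edges) the minimal connected graph is returned and flagged.
5. **Graph metrics** on the thresholded weighted graph use edge lengths
   1/weight for all shortest-path quantities: characteristic path length
   (PL), global efficiency (GE, nodal and whole-graph), Latora–Marchiori
   local efficiency (LE) on each node's neighbourhood subgraph, Onnela
   geometric-mean weighted clustering (CC), and unnormalised betweenness
   centrality (BC). PL and CC are normalised against degree-preserving
   random references (double-edge swaps carrying weights, swaps that
   disconnect rejected; default 20 references, 10 swaps per edge) and the
   small-world index is SWI = (CC/CC_rand)/(PL/PL_rand). Whole-brain
   metrics are swept over proportional thresholds 10–35% in 1% steps and
   pooled per subject as the trapezoidal area under the metric-vs-threshold
   curve.
6. **Participation.** Under a partition, PI_i = 1 − Σ_m (s_im/s_i)² with
   strengths taken from the thresholded (nonnegative) graph; PI is 0 for a
   node whose connections stay within its own module and approaches 1 for
   an even connector. Within each subject PI is rank-ordered ascending
   (ties averaged), removing inter-subject scale.
7. **Group statistics.** The group comparison uses one consensus partition
   for all subjects so that differences reflect node-to-structure
   relations, not differences between decompositions: per-subject best
   partitions are combined into a node x node co-assignment matrix weighted
   by each subject's (nonnegative) Q, the centred consensus matrix is
   re-partitioned from several restarts, and the loop repeats until the
   best partition is stable across two iterations (Lancichinetti–Fortunato
   style), finally constrained to exactly K modules (default 5). Node-wise
   PI ranks are compared with Welch t-tests; multiplicity is controlled by
   permutation (global label permutation preserving node dependence, null
   |t| pooled across nodes and permutations) followed by Benjamini–Hochberg
   step-up at q = 0.05. Pooling the null across nodes is what gives the
   permutation p-values enough resolution for step-up control at
   conventional permutation counts. The temporal SD of the global (region-
   mean) signal is compared between groups as a confound check.
8. **Classification** uses each subject's own best 5-module decomposition
   (so no group information enters the features). Features are the 8
   node-wise metrics (PI, degree, strength, BC, CC, LE, GE, LE/GE) for
   every region — 760 columns at N=95. Each of 1000 bagging iterations
   draws a random half/half train/test split (resampled until both class
   shares of the training set lie in [0.4, 0.6]), ranks features by mRMR
   on the training half only, standardizes by training statistics, trains
   a linear SVM (C=1) on the top k features (default 6) and records
   selectivity (specificity on controls) and sensitivity (recall on
   patients). Controls: `pre_shuffle` permutes all labels before selection
   and training; `post_shuffle` trains on true labels and scores the test
   half against permuted test labels. Both should land at chance on any
   data if and only if no information leaks from test to train — feature
   selection nested inside each split is therefore essential, and is
   verified by the pre-shuffle null landing in [0.45, 0.55].

   mRMR is the mutual-information-difference variant: features are
   discretized into 3 levels at mean ± SD, the first feature maximises
   I(f; y), and each next feature maximises relevance minus mean mutual
   information with the already-selected set. Recursive feature
   elimination (linear-SVM weight magnitude, one feature per round) is
   provided for comparison.

## Synthetic cohort generator

No patient data ships with the package; the generator provides cohorts
with known ground truth so every stage is testable. Defaults are the
emulated study conditions: 22 controls + 21 patients, 95 regions (45
mirrored left/right homologue pairs + 5 midline regions), T = 483 samples
at TR 1.25 s, K = 5 bilateral planted modules, and 20 nodes with lowered
plus 9 with raised participation in the patient group.

A group-level correlation template combines:

- baseline r(d) = a + b·log d, defaults a = 0.55, b = −0.08 per log-mm,
  clipped to [−0.9, 0.9] — an approximately logarithmic distance decay;
- planted structure: +0.10 within modules, −0.04 between (`within_boost`,
  `between_drop`);
- a shared Gaussian edge-noise field (SD 0.08), identical across groups,
  so that with `effect_size = 0` the two groups are exchangeable by
  construction.

The within/between offsets and the noise SD are chosen so that the 12%
strongest distance-corrected edges form a realistic mixture of ~70%
within-module and ~30% between-module connections, giving graded,
non-degenerate participation values; much stronger module contrast makes
the thresholded graph purely intra-modular and collapses PI to zero for
every node, which no resting-state dataset shows.

The patient effect reallocates, for each affected node, a fraction
`effect_size` (default 0.35) of its between-module covariance into its own
module (lowering true participation) or the reverse (raising it), applied
symmetrically via per-node multiplicative factors combined as geometric
means. The template is repaired to positive semidefinite (eigenvalue clip
at 1e-6, rescale to unit diagonal), and subjects are independent zero-mean
multivariate-normal draws of length T. The default effect size is a
calibration choice — the emulated study reports rank differences only —
sized so the default cohort is separable by the classifier, and is exposed
as a tunable. Subject i uses seed `seed + 1 + i`, so cohorts are exactly
reproducible.

**Not modelled:** temporal autocorrelation or any spectral structure
(downstream stages consume only correlations), hemodynamics, head motion,
scanner noise, voxel-level data. Passing tests therefore demonstrate
correctness of the statistical machinery on correlation-faithful data, not
robustness to fMRI artefacts.

## Numerical choices and degeneracies

- Eigenvalue clip 1e-6 for PSD repair; correlation entries clipped to
  [−0.9, 0.9] before repair.
- Louvain move gains use a 1e-12 improvement threshold; module labels are
  canonicalised by first appearance, making runs bit-reproducible for a
  given seed.
- K-constraint repair: among restarts the best partition with exactly K
  modules wins; otherwise the overall best is repaired by least-Q-cost
  greedy merges (K too high) or re-optimisation/leading-eigenvector
  bisection of the largest module (K too low).
- Consensus uses one shared derived seed for all subjects' partitions,
  keeping the result equivariant under subject reordering.
- Zero-variance columns, all-equal distances, disconnected positive parts,
  isolated nodes and degenerate reference ensembles raise typed errors
  rather than propagating NaNs; nodes with zero variance in both groups
  get t = 0, p = 1.
- Welch (unequal-variance) t-tests throughout; two-sided p-values.
- Edge-count rounding is half-away-from-zero; a one-edge discrepancy is
  tolerated and flagged.

## Problem sizes used by the test suite

Unit tests run on 8–20-node graphs and 8–10-subject cohorts. The
end-to-end validation uses the full default cohort (43 subjects, 95
regions) for planted-structure recovery, detection power and the
classifier controls; the 200-replicate null study of false-discovery
control uses 12+12-subject, 48-region, 160-sample cohorts with 500
permutations each — FDR control under the complete null is invariant to
these sizes, and the reduced cohorts keep the replicate count high where
it matters (the number of independent null cohorts).

## Known limitations

- The distance-penalty model is the package's own log-linear OLS stand-in
  for a generically "distance-corrected" connectivity matrix; it is
  isolated behind `connmod.connectivity` so an alternative correction can
  be swapped in.
- The consensus procedure is likewise one reasonable member of the
  co-assignment-clustering family, isolated behind
  `group_consensus_partition`.
- Permutation FDR pools the null across nodes; under strong between-node
  heteroscedasticity of the rank statistics this pooling is approximate
  (exchangeability holds under the generator's null).
- With ranks as the node-wise statistic, planted effects at some nodes
  necessarily shift the ranks of unaffected nodes (ranks sum to a
  constant), so "false" positives adjacent to true effects are expected on
  effect cohorts; FDR control is exact only under the complete null.
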