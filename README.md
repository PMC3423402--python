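# connmod

Community-structure analysis of resting-state functional connectivity for
two-group (control vs patient) neuroimaging cohorts.

Whole-brain graph metrics often fail to separate clinical groups in milder
disorders; the mid-scale *modular* organisation of the connectivity
network can be more sensitive. `connmod` implements that analysis end to
end: pairwise Pearson correlation of regional time series, removal of the
distance-dependent correlation background, signed-modularity community
detection on the full (unthresholded) matrix, participation indices on
connectivity-preserving thresholded graphs, node-wise group statistics
with permutation-based FDR control, and minimum-redundancy/maximum-
relevance feature selection feeding a bagged linear SVM with
label-shuffle controls. A synthetic cohort generator with planted
community structure and known participation effects makes every stage
testable without patient data.

## The core quantities

For a partition of the N regions into modules, the signed modularity

    Q* = Q⁺ − (v⁻/(v⁺+v⁻)) Q⁻,   Q± = (1/v±) Σᵢⱼ (w±ᵢⱼ − s±ᵢ s±ⱼ/v±) δ(mᵢ, mⱼ)

rewards positive weights inside modules at full strength and penalises
negative within-module weights with the asymmetric factor v⁻/(v⁺+v⁻), so
negative edges set module boundaries. It is optimised by restarted
signed Louvain; no thresholding is needed.

The participation index of node i under a partition,

    PIᵢ = 1 − Σₘ (sᵢₘ / sᵢ)²,

is 0 when all of a node's (thresholded, nonnegative) strength stays in
its own module and approaches 1 for an even inter-module connector. PI is
rank-ordered within each subject, and ranks are compared between groups
with Welch t-tests, corrected by permutation p-values (null pooled across
nodes) with Benjamini–Hochberg step-up.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from connmod.cohort import CohortConfig, simulate_cohort
from connmod.connectivity import compute_correlation, penalize
from connmod.graph_metrics import threshold_graph
from connmod.modularity import best_partition, participation_index

cohort = simulate_cohort(CohortConfig(
    n_control=2, n_patient=2, n_regions=30, n_timepoints=200, k_modules=3,
    n_affected_down=4, n_affected_up=2, seed=3,
))
pen, _ = penalize(compute_correlation(cohort.subjects[0]), cohort.parcellation)
part = best_partition(pen.weights, n_restarts=20, seed=1)
print(part.K, round(part.Q, 3),
      adjusted_rand_score(cohort.ground_truth.planted_partition, part.assignment))
graph = threshold_graph(pen, density=0.12)
pv = participation_index(graph, part)
```

This prints `3 0.424 1.0`: the optimiser recovers exactly the 3 planted
modules with goodness of fit Q = 0.424, and `pv.pi` holds graded
participation values (here min 0.00, median 0.31, max 0.62 — embedded
nodes through inter-module connectors) on the 12%-density graph of 52
retained edges.

The `examples/` directory walks through each capability — cohort
simulation, distance correction, modularity and participation, the
group-statistics workflow, and classification with shuffle controls.
Running `examples/05_classification.py` prints a per-condition table; on
its reduced 20-subject cohort the true-label classifier reaches ~0.99
training and ~0.75 test selectivity while both shuffle controls sit at
~0.49–0.53 test performance, i.e. chance, confirming the split is
leakage-free. A thin CLI wraps the two workflows:

```bash
connmod simulate --outdir cohort/ --seed 1
connmod group-analysis --config pipeline.yaml --outdir results/
connmod classify --config pipeline.yaml --outdir results/
```

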