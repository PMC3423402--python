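"""End-to-end workflows: group-wise analysis and SVM classification.

Both workflows share the identical correlation -> distance-penalty ->
thresholding -> metric code paths; they differ only in how the modular
decomposition is chosen (one consensus partition for the group comparison,
each subject's own best K-module partition for classification, so no
group-level information leaks into the classifier's features).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from connmod import classification as clf
from connmod import connectivity as conn_mod
from connmod import graph_metrics as gm
from connmod import group_stats as gs
from connmod import modularity as mod
from connmod.cohort import Cohort, CohortConfig, load_cohort, simulate_cohort
from connmod.exceptions import ConfigError

log = logging.getLogger("connmod.pipeline")


@dataclass
class PipelineConfig:
    """Study-level knobs shared by both workflows.

    ``cohort`` is either a :class:`CohortConfig` (simulate) or a path to a
    manifest CSV (load). All randomness flows from ``seed``.
    """

    cohort: CohortConfig | str | Path = field(default_factory=CohortConfig)
    density: float = 0.12
    thresholds: tuple[float, ...] = gm.DEFAULT_THRESHOLDS
    k_target: int = 5
    n_perm: int = 1000
    q: float = 0.05
    n_iterations: int = 1000
    n_features: int = 6
    conditions: tuple[str, ...] = clf.CONDITIONS
    balance_band: tuple[float, float] = (0.4, 0.6)
    n_restarts: int = 20  # modularity restarts per subject
    consensus_restarts: int = 10
    n_random_refs: int = 20
    n_swaps_per_edge: int = 10
    run_global_sweep: bool = True
    feature_curve_k: tuple[int, ...] | None = None
    seed: int = 0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        if not 0 < self.density <= 1:
            raise ConfigError("density must lie in (0, 1]")
        if any(not 0 < t <= 1 for t in self.thresholds):
            raise ConfigError("thresholds must lie in (0, 1]")
        if self.k_target < 2:
            raise ConfigError("k_target must be >= 2")
        for name in ("n_perm", "n_iterations", "n_features", "n_restarts"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.q < 1:
            raise ConfigError("q must lie in (0, 1)")


def _get_cohort(config: PipelineConfig) -> Cohort:
    if isinstance(config.cohort, (str, Path)):
        subjects, parc = load_cohort(config.cohort)
        if parc is None:
            raise ConfigError("manifest directory must contain parcellation.csv")
        return Cohort(tuple(subjects), parc, ground_truth=None, config=None)  # type: ignore[arg-type]
    cfg = dataclasses.replace(config.cohort)
    return simulate_cohort(cfg)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-24s %.2fs", name, t1 - t0)
    return t1


def _penalized_matrices(cohort: Cohort):
    """Shared front end: correlations and per-subject distance penalties."""
    raws = [conn_mod.compute_correlation(s) for s in cohort.subjects]
    pen, models = zip(
        *(conn_mod.penalize(r, cohort.parcellation) for r in raws)
    )
    return list(pen), list(models)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def run_group_analysis(config: PipelineConfig) -> dict:
    """Consensus-partition PI group comparison with resampling FDR.

    Executes: correlation -> distance penalty -> group consensus partition
    (K modules) -> proportional thresholding -> participation ranks ->
    node-wise Welch tests with permutation FDR -> global-signal check ->
    (optionally) the global-metric threshold sweep with AUC pooling.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s_consensus, s_fdr, s_sweep = rng.integers(0, 2**31 - 1, size=3)
    t0 = time.perf_counter()
    cohort = _get_cohort(config)
    labels = cohort.labels
    names = list(cohort.parcellation.region_names)
    t0 = _stage("cohort", t0)

    pen, models = _penalized_matrices(cohort)
    ctrl_models = [m for m, l in zip(models, labels) if l == "control"]
    pat_models = [m for m, l in zip(models, labels) if l == "patient"]
    resid_t, resid_p = conn_mod.compare_residual_errors(ctrl_models, pat_models)
    t0 = _stage("connectivity", t0)

    consensus, diagnostics = mod.group_consensus_partition(
        [p.weights for p in pen],
        k_target=config.k_target,
        seed=int(s_consensus),
        n_restarts=config.consensus_restarts,
    )
    t0 = _stage("consensus", t0)

    graphs = [gm.threshold_graph(p, config.density) for p in pen]
    ranks = np.vstack(
        [mod.participation_index(g, consensus).rank for g in graphs]
    )
    t0 = _stage("participation", t0)

    nodewise = gs.resampling_fdr(
        ranks, labels, n_perm=config.n_perm, q=config.q, seed=int(s_fdr)
    )
    nodewise.insert(1, "region_name", names)
    gsig_t, gsig_p = gs.compare_global_signal(list(cohort.subjects), labels)
    t0 = _stage("statistics", t0)

    sweep_tests = None
    curves = None
    if config.run_global_sweep:
        per_subject = []
        for i, p in enumerate(pen):
            curve = gm.metric_threshold_curve(
                p,
                thresholds=config.thresholds,
                n_refs=config.n_random_refs,
                n_swaps_per_edge=config.n_swaps_per_edge,
                seed=int(s_sweep) + 131 * i,
            )
            per_subject.append(curve)
        curves = {
            metric: np.array(
                [[getattr(pt, metric) for pt in curve] for curve in per_subject]
            )
            for metric in ("PL", "CC", "SWI", "GE", "LE", "PLn", "CCn")
        }
        sweep_tests = gs.global_metric_tests(
            {m: curves[m] for m in ("PLn", "CCn", "SWI")},
            labels,
            np.asarray(config.thresholds),
        )
        t0 = _stage("global sweep", t0)

    summary = {
        "n_significant": int(nodewise["significant"].sum()),
        "n_significant_up": int(
            (nodewise["significant"] & (nodewise["direction"] == "up")).sum()
        ),
        "n_significant_down": int(
            (nodewise["significant"] & (nodewise["direction"] == "down")).sum()
        ),
        "consensus_K": consensus.K,
        "consensus_diagnostics": diagnostics,
        "residual_error_test": {"t": resid_t, "p": resid_p},
        "global_signal_test": {"t": gsig_t, "p": gsig_p},
    }
    bundle = {
        "cohort": cohort,
        "penalized": pen,
        "distance_models": models,
        "consensus": consensus,
        "graphs": graphs,
        "pi_ranks": ranks,
        "nodewise": nodewise,
        "sweep_tests": sweep_tests,
        "curves": curves,
        "summary": summary,
    }
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        nodewise.to_csv(outdir / "nodewise_pi_tests.csv", index=False)
        pd.DataFrame(
            {"node": names, "module": consensus.assignment}
        ).to_csv(outdir / "consensus_partition.csv", index=False)
        _write_json(outdir / "group_summary.json", summary)
        if sweep_tests is not None:
            for metric, tab in sweep_tests.items():
                tab.to_csv(outdir / f"sweep_{metric}.csv", index=False)
        _write_json(outdir / "run_manifest.json", _manifest(config))
    return bundle


def run_classification(config: PipelineConfig) -> dict:
    """Individual-partition feature extraction and bagged SVM classification.

    Executes: correlation -> distance penalty -> per-subject best K-module
    partition -> thresholded-graph node metrics + PI -> feature matrix ->
    descriptive mRMR (and RFE) ranking -> bagged linear SVM under the
    configured shuffle conditions, and optionally the feature-count curve.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s_partition, s_bag, s_curve = rng.integers(0, 2**31 - 1, size=3)
    t0 = time.perf_counter()
    cohort = _get_cohort(config)
    labels = cohort.labels
    names = list(cohort.parcellation.region_names)
    t0 = _stage("cohort", t0)

    pen, _models = _penalized_matrices(cohort)
    t0 = _stage("connectivity", t0)

    partitions = [
        mod.best_partition(
            p.weights,
            n_restarts=config.n_restarts,
            seed=int(s_partition) + i,
            k_target=config.k_target,
        )
        for i, p in enumerate(pen)
    ]
    t0 = _stage("partitions", t0)

    graphs = [gm.threshold_graph(p, config.density) for p in pen]
    tables = [gm.node_metric_table(g, names) for g in graphs]
    pis = [
        mod.participation_index(g, part).pi
        for g, part in zip(graphs, partitions)
    ]
    features, y = clf.build_feature_matrix(tables, pis, labels, names)
    t0 = _stage("features", t0)

    ranked = clf.mrmr_rank(features, y, n_select=min(25, features.shape[1]))
    ranked_tab = _ranked_table(ranked, cohort, features.columns)
    rfe_order = clf.rfe_rank(features, y)
    pi_share = clf.metric_share(ranked, n_nodes=len(names), metric="PI", top=25)
    t0 = _stage("feature ranking", t0)

    reports = {}
    for k, condition in enumerate(config.conditions):
        reports[condition] = clf.bagged_classification(
            features,
            y,
            n_features=config.n_features,
            n_iterations=config.n_iterations,
            condition=condition,
            seed=int(s_bag) + 7919 * k,
            balance_band=config.balance_band,
        )
    t0 = _stage("bagged SVM", t0)

    curve = None
    if config.feature_curve_k:
        curve = clf.feature_count_curve(
            features,
            y,
            k_values=list(config.feature_curve_k),
            n_iterations=config.n_iterations,
            seed=int(s_curve),
            balance_band=config.balance_band,
        )
        t0 = _stage("feature curve", t0)

    summary = {
        "conditions": {c: reports[c].means for c in reports},
        "n_features": config.n_features,
        "n_iterations": config.n_iterations,
        "pi_share_top25": pi_share,
        "rfe_top10_overlap": len(set(ranked[:10]) & set(rfe_order[:10])),
        "subject_K": [p.K for p in partitions],
        "subject_Q": [p.Q for p in partitions],
    }
    bundle = {
        "cohort": cohort,
        "features": features,
        "labels": y,
        "partitions": partitions,
        "ranked_features": ranked_tab,
        "rfe_order": rfe_order,
        "reports": reports,
        "feature_curve": curve,
        "summary": summary,
    }
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        features.to_csv(outdir / "feature_matrix.csv", index=False)
        ranked_tab.to_csv(outdir / "ranked_features.csv", index=False)
        _write_json(outdir / "classification_summary.json", summary)
        if curve is not None:
            curve.to_csv(outdir / "feature_count_curve.csv", index=False)
        _write_json(outdir / "run_manifest.json", _manifest(config))
    return bundle


def run_all(config: PipelineConfig) -> dict:
    """Both workflows on the same configuration."""
    group = run_group_analysis(config)
    cls = run_classification(config)
    return {"group": group, "classification": cls}


def _ranked_table(ranked, cohort: Cohort, columns) -> pd.DataFrame:
    hemis = dict(
        zip(cohort.parcellation.region_names, cohort.parcellation.hemispheres)
    )
    rows = []
    for rank, idx in enumerate(ranked, start=1):
        metric, region = str(columns[idx]).split(":", 1)
        rows.append(
            {
                "rank": rank,
                "metric": metric,
                "region": region,
                "hemisphere": hemis.get(region, ""),
            }
        )
    return pd.DataFrame(rows)


def _manifest(config: PipelineConfig) -> dict:
    import connmod

    cfg = dataclasses.asdict(config)
    return {"package_version": connmod.__version__, "config": cfg}
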