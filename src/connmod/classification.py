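"""mRMR feature ranking and bagged linear-SVM group classification.

Each bagging iteration draws a balanced random half/half train/test split,
ranks features by minimum-redundancy-maximum-relevance (mutual-information
difference on 3-bin discretized features) using ONLY the training half,
standardizes by training statistics, trains a linear SVM (C = 1) on the top
k features and records test/train selectivity (specificity on controls) and
sensitivity (true-positive rate on patients). Label-shuffle controls either
permute all labels before selection/training ("pre") or only the test
labels after training ("post"), giving empirical chance-level baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from connmod.exceptions import (
    CompletenessError,
    ConfigError,
    InvalidArgumentError,
)

#: Column ordering of the feature matrix is metric-major, node-index minor.
FEATURE_METRICS = ("PI", "degree", "strength", "BC", "CC", "LE", "GE", "LEGE")

CONDITIONS = ("actual", "pre_shuffle", "post_shuffle")


def build_feature_matrix(
    node_tables: list[pd.DataFrame],
    pi_vectors: list[np.ndarray],
    labels: np.ndarray,
    region_names: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble subjects x (metric, node) features from per-subject tables.

    ``node_tables`` come from :func:`connmod.graph_metrics.node_metric_table`
    (one per subject); ``pi_vectors`` are the matching per-subject
    participation values (each subject's own best 5-module decomposition).
    Columns are named ``"<metric>:<region>"``.
    """
    if len(node_tables) != len(pi_vectors) or len(node_tables) != len(labels):
        raise CompletenessError("subjects, tables and PI vectors must align")
    n_nodes = len(node_tables[0])
    if region_names is None:
        region_names = [str(i) for i in range(n_nodes)]
    rows = []
    for tab, pi in zip(node_tables, pi_vectors):
        if len(tab) != n_nodes or len(pi) != n_nodes:
            raise CompletenessError("inconsistent node sets across subjects")
        parts = []
        for metric in FEATURE_METRICS:
            if metric == "PI":
                parts.append(np.asarray(pi, dtype=float))
            else:
                if metric not in tab.columns:
                    raise CompletenessError(f"metric {metric!r} missing for a subject")
                parts.append(tab[metric].to_numpy(dtype=float))
        rows.append(np.concatenate(parts))
    columns = [f"{m}:{r}" for m in FEATURE_METRICS for r in region_names]
    x = pd.DataFrame(np.vstack(rows), columns=columns)
    return x, np.asarray(labels)


def _discretize(x: np.ndarray) -> np.ndarray:
    """Three-level discretization at mean +- SD, per column."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    return (x > mu - sd).astype(np.int8) + (x > mu + sd).astype(np.int8)


def _mi_with_labels(disc: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Plug-in mutual information of each discretized column with the labels."""
    n = disc.shape[0]
    mi = np.zeros(disc.shape[1])
    for b in range(3):
        mask_b = disc == b
        p_b = mask_b.mean(axis=0)
        for c in (0, 1):
            p_bc = mask_b[y01 == c].sum(axis=0) / n
            p_c = (y01 == c).mean()
            valid = p_bc > 0
            mi[valid] += p_bc[valid] * np.log(p_bc[valid] / (p_b[valid] * p_c))
    return mi


def _mi_with_feature(disc: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Mutual information of one discretized column with every column."""
    n = disc.shape[0]
    mi = np.zeros(disc.shape[1])
    for b in range(3):
        mask_b = disc == b
        p_b = mask_b.mean(axis=0)
        for c in range(3):
            sel = col == c
            p_c = sel.mean()
            if p_c == 0:
                continue
            p_bc = mask_b[sel].sum(axis=0) / n
            valid = (p_bc > 0) & (p_b > 0)
            mi[valid] += p_bc[valid] * np.log(p_bc[valid] / (p_b[valid] * p_c))
    return mi


def mrmr_rank(
    features: pd.DataFrame | np.ndarray, labels: np.ndarray, n_select: int
) -> list[int]:
    """Greedy mutual-information-difference (relevance minus mean redundancy).

    The first feature maximises relevance to the class label; each further
    feature maximises relevance minus its mean mutual information with the
    features already chosen. Returns column indices in selection order.
    """
    x = np.asarray(features, dtype=float)
    if n_select > x.shape[1]:
        raise InvalidArgumentError("n_select exceeds the number of features")
    y01 = _binary_labels(labels)
    disc = _discretize(x)
    relevance = _mi_with_labels(disc, y01)

    selected = [int(np.argmax(relevance))]
    red_sum = np.zeros(x.shape[1])
    while len(selected) < n_select:
        red_sum += _mi_with_feature(disc, disc[:, selected[-1]])
        score = relevance - red_sum / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


def rfe_rank(features: pd.DataFrame | np.ndarray, labels: np.ndarray) -> list[int]:
    """Recursive feature elimination by linear-SVM weight magnitude.

    Features are standardized, an SVM is fitted, and the smallest-|w| feature
    is dropped each round; the returned order lists the survivors first.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[1] < 2:
        raise InvalidArgumentError("RFE needs at least 2 features")
    y01 = _binary_labels(labels)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    remaining = list(range(x.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > 1:
        svm = SVC(kernel="linear", C=1.0)
        svm.fit(x[:, remaining], y01)
        w = np.abs(svm.coef_.ravel())
        worst = int(np.argmin(w))
        eliminated.append(remaining.pop(worst))
    return remaining + eliminated[::-1]


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub":
        return labels.astype(int)
    return (labels == "patient").astype(int)


@dataclass(frozen=True)
class SplitScheme:
    """An accepted half/half train/test split of the subjects."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    n_rejected: int


def make_split(
    labels: np.ndarray,
    rng: np.random.Generator | int,
    balance_band: tuple[float, float] = (0.4, 0.6),
    max_tries: int = 100000,
) -> SplitScheme:
    """Random 50/50 split, resampled until each class's training share is in band."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    labels = np.asarray(labels)
    n = len(labels)
    if n < 4:
        raise InvalidArgumentError("need at least 4 subjects to split")
    lo, hi = balance_band
    if not 0 <= lo < hi <= 1:
        raise ConfigError("balance band must satisfy 0 <= lo < hi <= 1")
    y01 = _binary_labels(labels)
    for attempt in range(max_tries):
        train_size = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
        perm = rng.permutation(n)
        train, test = perm[:train_size], perm[train_size:]
        share1 = y01[train].mean()
        share0 = 1.0 - share1
        if lo <= share0 <= hi and lo <= share1 <= hi:
            return SplitScheme(np.sort(train), np.sort(test), attempt)
    raise ConfigError("balance band unsatisfiable for these labels")


@dataclass
class ClassificationReport:
    """Per-iteration and mean selectivity/sensitivity for one shuffle condition."""

    condition: str
    n_features: int
    per_iteration: pd.DataFrame
    n_skipped: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration)

    @property
    def means(self) -> dict[str, float]:
        cols = [
            "train_selectivity",
            "train_sensitivity",
            "test_selectivity",
            "test_sensitivity",
        ]
        return {c: float(np.nanmean(self.per_iteration[c])) for c in cols}


def _rates(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(selectivity, sensitivity) = (specificity on class 0, recall on class 1)."""
    ctrl = truth == 0
    pat = truth == 1
    sel = float((pred[ctrl] == 0).mean()) if ctrl.any() else np.nan
    sen = float((pred[pat] == 1).mean()) if pat.any() else np.nan
    return sel, sen


def bagged_classification(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    n_features: int = 6,
    n_iterations: int = 1000,
    condition: str = "actual",
    seed: int = 0,
    balance_band: tuple[float, float] = (0.4, 0.6),
) -> ClassificationReport:
    """Bagged linear-SVM classification with nested feature selection.

    Feature ranking and standardization use only the training half of each
    split, so the shuffle controls are leakage-free: ``pre_shuffle`` permutes
    ALL labels before selection/training, ``post_shuffle`` trains on true
    labels and scores the test half against permuted test labels (training
    metrics remain against true labels).
    """
    if condition not in CONDITIONS:
        raise InvalidArgumentError(f"condition must be one of {CONDITIONS}")
    if n_features < 1 or n_iterations < 1:
        raise InvalidArgumentError("n_features and n_iterations must be >= 1")
    x = np.asarray(features, dtype=float)
    y = _binary_labels(labels)
    rng = np.random.default_rng(seed)

    records = []
    n_skipped = 0
    for _ in range(n_iterations):
        split = make_split(y, rng, balance_band)
        y_work = rng.permutation(y) if condition == "pre_shuffle" else y
        tr, te = split.train_ids, split.test_ids
        y_tr = y_work[tr]
        if len(np.unique(y_tr)) < 2:
            n_skipped += 1
            continue
        order = mrmr_rank(x[tr], y_tr, n_features)
        x_tr = x[np.ix_(tr, order)]
        mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        svm = SVC(kernel="linear", C=1.0)
        svm.fit((x_tr - mu) / sd, y_tr)
        pred_tr = svm.predict((x_tr - mu) / sd)
        pred_te = svm.predict((x[np.ix_(te, order)] - mu) / sd)

        if condition == "post_shuffle":
            y_te_eval = rng.permutation(y[te])
        else:
            y_te_eval = y_work[te]
        train_sel, train_sen = _rates(pred_tr, y_tr)
        test_sel, test_sen = _rates(pred_te, y_te_eval)
        records.append(
            {
                "train_selectivity": train_sel,
                "train_sensitivity": train_sen,
                "test_selectivity": test_sel,
                "test_sensitivity": test_sen,
                "n_rejected_splits": split.n_rejected,
            }
        )
    return ClassificationReport(
        condition, n_features, pd.DataFrame(records), n_skipped
    )


def feature_count_curve(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    k_values: list[int] | None = None,
    n_iterations: int = 100,
    seed: int = 0,
    condition: str = "actual",
    balance_band: tuple[float, float] = (0.4, 0.6),
) -> pd.DataFrame:
    """Mean test selectivity/sensitivity as the selected-feature count grows.

    Each k reuses the same seed, so curves at different k are paired over the
    same split sequence and a single-k curve reproduces a direct
    :func:`bagged_classification` call.
    """
    if k_values is None:
        k_values = list(range(1, 26))
    if not k_values:
        raise InvalidArgumentError("k_values must be nonempty")
    rows = []
    for k in k_values:
        rep = bagged_classification(
            features, labels, n_features=k, n_iterations=n_iterations,
            condition=condition, seed=seed, balance_band=balance_band,
        )
        means = rep.means
        rows.append({"n_features": k, **means})
    return pd.DataFrame(rows)


def metric_share(ranked: list[int], n_nodes: int, metric: str = "PI", top: int = 25) -> int:
    """How many of the top-ranked features come from one metric family."""
    idx = FEATURE_METRICS.index(metric)
    lo, hi = idx * n_nodes, (idx + 1) * n_nodes
    return sum(1 for f in ranked[:top] if lo <= f < hi)
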