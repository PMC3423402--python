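"""Between-group statistics with permutation-based FDR correction.

Node-wise participation ranks are compared between groups with Welch
t-tests; multiplicity is handled by permutation p-values (group labels
permuted globally, preserving the dependence between nodes, with the null
statistics pooled across nodes) followed by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from connmod.cohort import RoiTimeSeries
from connmod.connectivity import welch_ttest
from connmod.exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    ShapeError,
)


def _group_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    ctrl = labels == "control"
    pat = labels == "patient"
    if ctrl.sum() < 2 or pat.sum() < 2:
        raise InsufficientDataError("need at least 2 subjects per group")
    if not np.all(ctrl | pat):
        raise InvalidArgumentError("labels must be 'control' or 'patient'")
    return ctrl, pat


def _welch_columns(
    data: np.ndarray, ctrl: np.ndarray, pat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t per column; zero-variance-everywhere columns get t=0, p=1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(data[pat], data[ctrl], axis=0, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    return t, p


def nodewise_group_test(
    values_by_subject: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Per-node Welch t-tests of patients vs controls.

    ``values_by_subject`` is subjects x nodes (e.g. PI ranks). Direction is
    the sign of (patient mean - control mean).
    """
    data = np.asarray(values_by_subject, dtype=float)
    ctrl, pat = _group_masks(labels)
    t, p = _welch_columns(data, ctrl, pat)
    direction = np.where(t >= 0, "up", "down")
    return pd.DataFrame(
        {"node": np.arange(data.shape[1]), "t": t, "p_raw": p, "direction": direction}
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def resampling_fdr(
    values_by_subject: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-values (null pooled across nodes) with BH control at q.

    Labels are permuted globally so the node-wise dependence structure is
    preserved under the null; the |t| null distribution is pooled over all
    nodes and permutations, giving p-value resolution 1/(n_perm * N + 1).
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    if not 0 < q < 1:
        raise InvalidArgumentError("q must lie in (0, 1)")
    data = np.asarray(values_by_subject, dtype=float)
    ctrl, pat = _group_masks(labels)
    n_nodes = data.shape[1]
    t_obs, _ = _welch_columns(data, ctrl, pat)

    rng = np.random.default_rng(seed)
    n_ctrl = int(ctrl.sum())
    null = np.empty((n_perm, n_nodes))
    for b in range(n_perm):
        perm = rng.permutation(data.shape[0])
        c_mask = np.zeros(data.shape[0], dtype=bool)
        c_mask[perm[:n_ctrl]] = True
        t_b, _ = _welch_columns(data, c_mask, ~c_mask)
        null[b] = np.abs(t_b)
    pool = np.sort(null.ravel())
    n_pool = pool.size
    # p_i = (1 + #{null >= |t_i|}) / (n_pool + 1)
    n_ge = n_pool - np.searchsorted(pool, np.abs(t_obs), side="left")
    p_perm = (1.0 + n_ge) / (n_pool + 1.0)

    p_adj = benjamini_hochberg(p_perm)
    p_adj = np.maximum(p_adj, p_perm)
    direction = np.where(t_obs >= 0, "up", "down")
    return pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "t": t_obs,
            "p_raw": p_perm,
            "p_adjusted": p_adj,
            "direction": direction,
            "significant": p_adj <= q,
        }
    )


def global_metric_tests(
    curves_by_subject: dict[str, np.ndarray],
    labels: np.ndarray,
    thresholds: np.ndarray,
) -> dict[str, pd.DataFrame]:
    """Welch tests of each global metric per threshold plus on pooled curve AUCs.

    ``curves_by_subject[metric]`` is subjects x thresholds. Returns one frame
    per metric with per-threshold (t, p) rows and a final 'AUC' row.
    """
    from connmod.graph_metrics import curve_auc

    ctrl, pat = _group_masks(labels)
    thresholds = np.asarray(thresholds, dtype=float)
    out = {}
    for metric, curves in curves_by_subject.items():
        curves = np.asarray(curves, dtype=float)
        if curves.shape[1] != len(thresholds):
            raise ShapeError(f"threshold grid mismatch for metric {metric!r}")
        t, p = _welch_columns(curves, ctrl, pat)
        rows = pd.DataFrame({"threshold": thresholds, "t": t, "p": p})
        aucs = np.array([curve_auc(thresholds, c) for c in curves])
        t_auc, p_auc = welch_ttest(aucs[pat], aucs[ctrl])
        rows = pd.concat(
            [
                rows,
                pd.DataFrame({"threshold": [np.nan], "t": [t_auc], "p": [p_auc]}),
            ],
            ignore_index=True,
        )
        rows["quantity"] = ["per_threshold"] * len(thresholds) + ["AUC"]
        out[metric] = rows
    return out


def compare_global_signal(
    subjects: list[RoiTimeSeries], labels: np.ndarray
) -> tuple[float, float]:
    """Welch test on the temporal SD of each subject's global (mean) signal."""
    ctrl, pat = _group_masks(labels)
    scalar = np.array(
        [s.data.mean(axis=1).std(ddof=1) for s in subjects], dtype=float
    )
    return welch_ttest(scalar[pat], scalar[ctrl])
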