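"""Pairwise correlation matrices and distance-penalty correction.

Resting-state correlations decay roughly logarithmically with inter-regional
distance; subtracting a per-subject log-linear fit emphasises connections
that are strong relative to their spatial proximity (e.g. homotopic pairs)
over the many short-range correlations between adjacent regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from connmod.cohort import Parcellation, RoiTimeSeries
from connmod.exceptions import (
    DegenerateSeriesError,
    InsufficientDataError,
    InvalidArgumentError,
    ShapeError,
    SingularFitError,
)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric signed edge-weight matrix, raw (correlation) or distance-penalized."""

    weights: np.ndarray
    stage: str  # 'raw' | 'penalized'
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ShapeError("connectivity matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise InvalidArgumentError("connectivity matrix must be symmetric")
        if self.stage not in ("raw", "penalized"):
            raise InvalidArgumentError(f"unknown stage {self.stage!r}")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class DistanceModel:
    """OLS fit of correlation against log distance over all region pairs."""

    intercept: float
    slope: float  # per log-mm
    residual_sd: float
    n_pairs: int

    def predict(self, distances: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log(distances)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "slope": self.slope,
                    "residual_sd": self.residual_sd,
                    "n_pairs": self.n_pairs,
                }
            )
        )


def compute_correlation(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Zero-lag Pearson correlation of all region pairs; diagonal exactly 1."""
    data = ts.data
    if data.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 time points for correlation")
    sds = data.std(axis=0)
    if np.any(sds == 0):
        bad = int(np.flatnonzero(sds == 0)[0])
        raise DegenerateSeriesError(f"zero-variance time series in region {bad}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, "raw", ts.subject_id)


def _pair_values(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def fit_distance_trend(
    conn: ConnectivityMatrix, parcellation: Parcellation
) -> DistanceModel:
    """Regress r(i,j) on log d(i,j) over all unordered pairs by OLS."""
    if conn.n_regions != parcellation.n_regions:
        raise ShapeError("connectivity and parcellation sizes differ")
    d = _pair_values(parcellation.distances())
    if np.any(d <= 0):
        raise InvalidArgumentError("coincident centroids give non-positive distances")
    x = np.log(d)
    y = _pair_values(conn.weights)
    if np.ptp(x) == 0:
        raise SingularFitError("all pairwise distances are equal; fit is singular")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    n = len(y)
    residual_sd = float(np.sqrt((resid**2).sum() / (n - 2))) if n > 2 else 0.0
    return DistanceModel(float(res.intercept), float(res.slope), residual_sd, n)


def apply_distance_penalty(
    conn: ConnectivityMatrix,
    model: DistanceModel,
    parcellation: Parcellation,
) -> ConnectivityMatrix:
    """Subtract the fitted distance trend from every off-diagonal correlation."""
    if conn.n_regions != parcellation.n_regions:
        raise ShapeError("connectivity and parcellation sizes differ")
    d = parcellation.distances()
    off = ~np.eye(conn.n_regions, dtype=bool)
    w = conn.weights.copy()
    w[off] = w[off] - model.predict(d[off])
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix((w + w.T) / 2.0, "penalized", conn.subject_id)


def penalize(
    conn: ConnectivityMatrix, parcellation: Parcellation
) -> tuple[ConnectivityMatrix, DistanceModel]:
    """Per-subject fit-and-subtract convenience wrapper."""
    model = fit_distance_trend(conn, parcellation)
    return apply_distance_penalty(conn, model, parcellation), model


def compare_residual_errors(
    models_a: list[DistanceModel], models_b: list[DistanceModel]
) -> tuple[float, float]:
    """Welch two-sample t-test on subject-wise residual SDs; returns (t, p)."""
    if len(models_a) < 2 or len(models_b) < 2:
        raise InsufficientDataError("need at least 2 subjects per group")
    a = np.array([m.residual_sd for m in models_a])
    b = np.array([m.residual_sd for m in models_b])
    return welch_ttest(a, b)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t-test robust to zero-variance degenerate inputs."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
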