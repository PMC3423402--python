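"""Synthetic two-group ROI time-series cohorts with planted community structure.

The generator emulates a resting-state fMRI cohort after preprocessing and
parcellation: each subject is a T x N matrix of regional activity whose
correlation structure combines (i) a distance-dependent background trend,
(ii) a planted bilateral modular structure, and (iii) a patient-group effect
that reallocates covariance between and within modules for a chosen set of
nodes, raising or lowering their true participation. Downstream stages are
validated against this known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from connmod.exceptions import (
    ConfigError,
    DegenerateCovarianceError,
    InvalidArgumentError,
    UndefinedPIError,
)

#: Default number of midline (bilateral) regions in the emulated parcellation:
#: a laterally mirrored atlas augmented with midline cingulate-style regions.
_N_MIDLINE = 5


@dataclass(frozen=True)
class Parcellation:
    """Named brain regions with hemisphere labels and centroid coordinates (mm)."""

    region_names: tuple[str, ...]
    hemispheres: tuple[str, ...]  # 'left' | 'right' | 'bilateral'
    centroids: np.ndarray  # (N, 3) float, mm

    def __post_init__(self) -> None:
        n = len(self.region_names)
        if n < 4:
            raise InvalidArgumentError("a parcellation needs at least 4 regions")
        if self.centroids.shape != (n, 3):
            raise InvalidArgumentError("centroids must be (N, 3)")
        if len(np.unique(self.centroids, axis=0)) != n:
            raise InvalidArgumentError("all centroids must be distinct")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def distances(self) -> np.ndarray:
        """Euclidean inter-centroid distance matrix (N x N, mm)."""
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


@dataclass(frozen=True)
class GroundTruth:
    """Planted community structure and group-effect bookkeeping for a cohort."""

    planted_partition: np.ndarray  # (N,) int module labels 1..K
    affected_down: tuple[int, ...]  # node indices whose participation drops in patients
    affected_up: tuple[int, ...]
    effect_size: float  # fraction of cross/within-module covariance reallocated

    def __post_init__(self) -> None:
        if set(self.affected_down) & set(self.affected_up):
            raise ConfigError("affected_down and affected_up overlap")
        if not 0.0 <= self.effect_size <= 1.0:
            raise InvalidArgumentError("effect_size must lie in [0, 1]")
        labels = np.unique(self.planted_partition)
        if labels.min() != 1 or labels.max() != len(labels):
            raise InvalidArgumentError("module labels must be contiguous from 1")

    @property
    def n_modules(self) -> int:
        return int(self.planted_partition.max())


@dataclass(frozen=True)
class RoiTimeSeries:
    """Per-subject regional time series (T rows, N regions)."""

    subject_id: str
    group: str  # 'control' | 'patient'
    data: np.ndarray  # (T, N)
    tr_seconds: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise InvalidArgumentError("time series needs T >= 2 rows")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("time series contains non-finite values")
        if np.any(self.data.std(axis=0) == 0):
            raise InvalidArgumentError("zero-variance region in time series")
        if self.tr_seconds <= 0:
            raise InvalidArgumentError("tr_seconds must be positive")
        if self.group not in ("control", "patient"):
            raise InvalidArgumentError(f"unknown group {self.group!r}")


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the emulated study: 22 controls vs 21 patients, 95
    regions, 483 retained volumes at TR 1.25 s, a 5-module bilateral
    community structure, and a patient effect on 20 participation-lowered
    plus 9 participation-raised nodes.
    """

    n_control: int = 22
    n_patient: int = 21
    n_regions: int = 95
    n_timepoints: int = 483
    tr_seconds: float = 1.25
    k_modules: int = 5
    n_affected_down: int = 20
    n_affected_up: int = 9
    effect_size: float = 0.35
    background: tuple[float, float] = (0.55, -0.08)  # r(d) = a + b log d
    noise_sd: float = 0.08  # shared edge-level heterogeneity around the trend
    within_boost: float = 0.10  # added correlation inside planted modules
    between_drop: float = 0.04  # subtracted correlation across modules
    seed: int = 0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        if self.n_control < 2 or self.n_patient < 2:
            raise ConfigError("need at least 2 subjects per group")
        if self.n_regions < 4:
            raise ConfigError("need at least 4 regions")
        if self.n_timepoints < 2:
            raise ConfigError("need at least 2 time points")
        if self.k_modules < 1 or self.k_modules > self.n_regions:
            raise ConfigError("k_modules must lie in [1, n_regions]")
        if self.n_affected_down + self.n_affected_up > self.n_regions:
            raise ConfigError("affected node sets exceed the parcellation")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ConfigError("effect_size must lie in [0, 1]")


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[RoiTimeSeries, ...]
    parcellation: Parcellation
    ground_truth: GroundTruth
    config: CohortConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def make_parcellation(n_regions: int, seed: int) -> Parcellation:
    """Generate a bilateral mirrored centroid layout with optional midline regions.

    Even ``n_regions`` yields mirrored left/right homologue pairs only; odd
    counts add midline regions (five for atlas-sized parcellations, mimicking
    merged cingulate regions, otherwise the minimum needed for parity).
    """
    if n_regions < 4:
        raise InvalidArgumentError("n_regions must be >= 4")
    n_midline = 0
    if n_regions % 2 == 1:
        n_midline = _N_MIDLINE if n_regions >= 2 * _N_MIDLINE + 4 else 1
    n_pairs = (n_regions - n_midline) // 2

    rng = np.random.default_rng(seed)
    # Left-hemisphere centroids inside a brain-sized bounding box (mm).
    left = np.column_stack(
        [
            rng.uniform(-68.0, -8.0, n_pairs),
            rng.uniform(-95.0, 65.0, n_pairs),
            rng.uniform(-40.0, 70.0, n_pairs),
        ]
    )
    right = left * np.array([-1.0, 1.0, 1.0])
    midline = np.column_stack(
        [
            np.zeros(n_midline),
            rng.uniform(-95.0, 65.0, n_midline),
            rng.uniform(-40.0, 70.0, n_midline),
        ]
    )
    names: list[str] = []
    hemis: list[str] = []
    for i in range(n_pairs):
        names.append(f"Region{i + 1:02d}_L")
        hemis.append("left")
    for i in range(n_pairs):
        names.append(f"Region{i + 1:02d}_R")
        hemis.append("right")
    for i in range(n_midline):
        names.append(f"Midline{i + 1:02d}")
        hemis.append("bilateral")
    centroids = np.vstack([left, right, midline])
    return Parcellation(tuple(names), tuple(hemis), centroids)


def make_ground_truth(
    parcellation: Parcellation,
    k_modules: int,
    n_affected_down: int,
    n_affected_up: int,
    effect_size: float,
    seed: int,
) -> GroundTruth:
    """Plant a bilateral module structure and draw disjoint affected-node sets.

    Homologue pairs are always assigned to the same module, so modules form
    bilaterally, as resting-state communities typically do.
    """
    n = parcellation.n_regions
    hemis = np.array(parcellation.hemispheres)
    rng = np.random.default_rng(seed)

    labels = np.zeros(n, dtype=int)
    left_idx = np.flatnonzero(hemis == "left")
    right_idx = np.flatnonzero(hemis == "right")
    mid_idx = np.flatnonzero(hemis == "bilateral")
    # Homologues are stored in matching order (Region_k_L <-> Region_k_R).
    pair_order = rng.permutation(len(left_idx))
    for rank, p in enumerate(pair_order):
        m = rank % k_modules + 1
        labels[left_idx[p]] = m
        labels[right_idx[p]] = m
    for rank, i in enumerate(rng.permutation(mid_idx)):
        labels[i] = rank % k_modules + 1
    # Guard: tiny parcellations may leave a module empty; relabel contiguously.
    uniq = np.unique(labels)
    relabel = {old: new + 1 for new, old in enumerate(uniq)}
    labels = np.array([relabel[v] for v in labels])

    chosen = rng.choice(n, size=n_affected_down + n_affected_up, replace=False)
    return GroundTruth(
        planted_partition=labels,
        affected_down=tuple(int(i) for i in chosen[:n_affected_down]),
        affected_up=tuple(int(i) for i in chosen[n_affected_down:]),
        effect_size=float(effect_size),
    )


def _repair_psd(mat: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``min_eig`` and rescale to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, min_eig, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise DegenerateCovarianceError("covariance could not be repaired to PSD")
    out = repaired / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def build_group_covariance(
    parcellation: Parcellation,
    ground_truth: GroundTruth,
    group: str,
    background: tuple[float, float] = (0.55, -0.08),
    noise_sd: float = 0.08,
    within_boost: float = 0.10,
    between_drop: float = 0.04,
    seed: int = 0,
) -> np.ndarray:
    """Construct a group-level correlation matrix with planted structure.

    The baseline follows ``a + b log(d)`` in inter-centroid distance d (mm),
    clipped to [-0.9, 0.9]; planted modules add within-module correlation and
    subtract a little between modules; a shared Gaussian edge-noise field
    (identical across groups, governed by ``seed``) adds heterogeneity around
    the trend. For the patient group, each affected-down node has a fraction
    ``effect_size`` of its between-module covariance reallocated within its
    own module (lowering true participation); affected-up nodes the reverse.
    The result is repaired to positive semidefinite with unit diagonal.
    """
    if group not in ("control", "patient"):
        raise InvalidArgumentError(f"unknown group {group!r}")
    n = parcellation.n_regions
    labels = ground_truth.planted_partition
    if labels.shape != (n,):
        raise InvalidArgumentError("ground truth does not match parcellation size")
    a, b = background

    d = parcellation.distances()
    off = ~np.eye(n, dtype=bool)
    base = np.zeros((n, n))
    base[off] = np.clip(a + b * np.log(d[off]), -0.9, 0.9)

    same = labels[:, None] == labels[None, :]
    r = base + np.where(same, within_boost, -between_drop) * off

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(n, n))
    r = r + np.triu(noise, 1) + np.triu(noise, 1).T

    eff = ground_truth.effect_size
    if group == "patient" and eff > 0:
        # Per-node multiplicative factors for within/between entries; the
        # within factor is sized so the between-module strength removed is
        # added back inside the module (and vice versa for "up" nodes).
        fac_within = np.ones(n)
        fac_between = np.ones(n)
        pos = np.clip(r, 0.0, None)
        for i in ground_truth.affected_down:
            w_i = pos[i, same[i] & off[i]].sum()
            b_i = pos[i, ~same[i]].sum()
            fac_between[i] = 1.0 - eff
            fac_within[i] = 1.0 + eff * b_i / max(w_i, 1e-12)
        for i in ground_truth.affected_up:
            w_i = pos[i, same[i] & off[i]].sum()
            b_i = pos[i, ~same[i]].sum()
            fac_within[i] = 1.0 - eff
            fac_between[i] = 1.0 + eff * w_i / max(b_i, 1e-12)
        f_within = np.sqrt(np.outer(fac_within, fac_within))
        f_between = np.sqrt(np.outer(fac_between, fac_between))
        r = r * np.where(same, f_within, f_between)

    r = np.clip(r, -0.9, 0.9)
    np.fill_diagonal(r, 1.0)
    return _repair_psd(r)


def true_participation(cov: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Analytic participation of each node from a covariance and a partition.

    Uses positive off-diagonal covariance as connection strength:
    PI_i = 1 - sum_m (s_im / s_i)^2.
    """
    n = cov.shape[0]
    w = np.clip(cov.copy(), 0.0, None)
    np.fill_diagonal(w, 0.0)
    modules = np.unique(partition)
    s_im = np.column_stack([w[:, partition == m].sum(axis=1) for m in modules])
    s_i = s_im.sum(axis=1)
    if np.any(s_i <= 0):
        raise UndefinedPIError("node with no positive covariance to any other node")
    return 1.0 - ((s_im / s_i[:, None]) ** 2).sum(axis=1)


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    seed: int,
    subject_id: str = "sub",
    group: str = "control",
    tr_seconds: float = 1.25,
) -> RoiTimeSeries:
    """Draw T independent zero-mean multivariate-normal samples from ``cov``."""
    if n_timepoints < 2:
        raise InvalidArgumentError("n_timepoints must be >= 2")
    vals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if vals.min() < -1e-8:
        raise InvalidArgumentError("covariance is not positive semidefinite")
    rng = np.random.default_rng(seed)
    data = rng.multivariate_normal(
        np.zeros(cov.shape[0]), cov, size=n_timepoints, method="eigh"
    )
    return RoiTimeSeries(subject_id, group, data, tr_seconds)


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Simulate a two-group cohort; write manifest and files if configured.

    All randomness flows from ``config.seed``: the parcellation and ground
    truth reuse it, and subject ``i`` (in manifest order, controls first)
    uses ``seed + 1 + i``.
    """
    config = config if config is not None else CohortConfig()
    config.validate()
    parc = make_parcellation(config.n_regions, config.seed)
    gt = make_ground_truth(
        parc,
        config.k_modules,
        config.n_affected_down,
        config.n_affected_up,
        config.effect_size,
        config.seed,
    )
    covs = {
        g: build_group_covariance(
            parc,
            gt,
            g,
            background=config.background,
            noise_sd=config.noise_sd,
            within_boost=config.within_boost,
            between_drop=config.between_drop,
            seed=config.seed,
        )
        for g in ("control", "patient")
    }
    subjects: list[RoiTimeSeries] = []
    groups = ["control"] * config.n_control + ["patient"] * config.n_patient
    for i, group in enumerate(groups):
        sid = f"{'ctrl' if group == 'control' else 'pat'}{i + 1:03d}"
        subjects.append(
            simulate_subject(
                covs[group],
                config.n_timepoints,
                seed=config.seed + 1 + i,
                subject_id=sid,
                group=group,
                tr_seconds=config.tr_seconds,
            )
        )
    cohort = Cohort(tuple(subjects), parc, gt, config)
    if config.output_dir is not None:
        write_cohort(cohort, Path(config.output_dir))
    return cohort


def write_cohort(cohort: Cohort, outdir: Path) -> None:
    """Write manifest CSV, per-subject TSVs, parcellation CSV and ground truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    parc = cohort.parcellation
    pd.DataFrame(
        {
            "name": parc.region_names,
            "hemisphere": parc.hemispheres,
            "x": parc.centroids[:, 0],
            "y": parc.centroids[:, 1],
            "z": parc.centroids[:, 2],
        }
    ).to_csv(outdir / "parcellation.csv", index=False)
    rows = []
    for s in cohort.subjects:
        fname = f"{s.subject_id}.tsv"
        pd.DataFrame(s.data, columns=list(parc.region_names)).to_csv(
            outdir / fname, sep="\t", index=False
        )
        rows.append({"subject_id": s.subject_id, "group": s.group, "path": fname})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    gt = cohort.ground_truth
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "planted_partition": gt.planted_partition.tolist(),
                "affected_down": list(gt.affected_down),
                "affected_up": list(gt.affected_up),
                "effect_size": gt.effect_size,
            },
            indent=2,
        )
    )


def load_cohort(manifest_path: str | Path, tr_seconds: float = 1.25) -> tuple[
    list[RoiTimeSeries], Parcellation | None
]:
    """Read a cohort from a manifest CSV (subject_id, group, path).

    Paths are resolved relative to the manifest; a ``parcellation.csv`` next
    to the manifest is loaded when present.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    subjects = []
    for _, row in manifest.iterrows():
        data = pd.read_csv(base / row["path"], sep="\t").to_numpy(dtype=float)
        subjects.append(
            RoiTimeSeries(str(row["subject_id"]), str(row["group"]), data, tr_seconds)
        )
    parc = None
    parc_path = base / "parcellation.csv"
    if parc_path.exists():
        tab = pd.read_csv(parc_path)
        parc = Parcellation(
            tuple(tab["name"]),
            tuple(tab["hemisphere"]),
            tab[["x", "y", "z"]].to_numpy(dtype=float),
        )
    return subjects, parc
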