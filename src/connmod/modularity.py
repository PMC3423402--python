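"""Signed-weight modularity, participation indices and consensus partitions.

Community structure is found on the FULL signed penalized matrix (no
thresholding): positive weights are rewarded inside modules at full
strength while negative weights are penalised with the asymmetric
down-weighting v-/(v+ + v-), so negative edges delineate module boundaries
without dominating the objective:

    Q* = Q+ - (v- / (v+ + v-)) Q-,
    Q+- = (1/v+-) sum_ij (w+-_ij - s+-_i s+-_j / v+-) delta(m_i, m_j),

optimised by a Louvain-style greedy agglomeration with random restarts.
The participation index of node i under a partition is
PI_i = 1 - sum_m (s_im / s_i)^2, computed on a thresholded (nonnegative)
graph; ranks 1..N (ascending, ties averaged) remove inter-subject scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from connmod.connectivity import ConnectivityMatrix
from connmod.exceptions import (
    DegenerateGraphError,
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedPIError,
)
from connmod.graph_metrics import SparseGraph


@dataclass(frozen=True)
class Partition:
    """Node-to-module assignment (labels 1..K) with its goodness of fit Q."""

    assignment: np.ndarray
    Q: float

    @property
    def K(self) -> int:
        return int(self.assignment.max())

    def __post_init__(self) -> None:
        labels = np.unique(self.assignment)
        if labels.min() != 1 or labels.max() != len(labels):
            raise InvalidArgumentError("module labels must be contiguous from 1")


@dataclass(frozen=True)
class PiVector:
    """Per-node participation in [0, 1] and its within-subject ascending rank."""

    pi: np.ndarray
    rank: np.ndarray


def _as_weights(conn) -> np.ndarray:
    w = conn.weights if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, float)
    w = (w + w.T) / 2.0
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def _split_signed(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.clip(w, 0.0, None), np.clip(-w, 0.0, None)


def _q_component(a: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    v = a.sum()
    if v == 0:
        return 0.0
    s = a.sum(axis=1)
    q = 0.0
    for m in np.unique(labels):
        idx = labels == m
        e_m = a[np.ix_(idx, idx)].sum()
        s_m = s[idx].sum()
        q += e_m / v - gamma * (s_m / v) ** 2
    return float(q)


def signed_modularity(
    w: np.ndarray | ConnectivityMatrix, labels: np.ndarray, gamma: float = 1.0
) -> float:
    """Asymmetric signed modularity Q* of a partition."""
    w = _as_weights(w)
    wp, wn = _split_signed(w)
    vp, vn = wp.sum(), wn.sum()
    if vp + vn == 0:
        raise DegenerateGraphError("all-zero matrix has no modular structure")
    qp = _q_component(wp, labels, gamma)
    qn = _q_component(wn, labels, gamma)
    return qp - (vn / (vp + vn)) * qn


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K in order of first appearance."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _louvain_moves(
    wp: np.ndarray,
    wn: np.ndarray,
    vp: float,
    vn: float,
    lam: float,
    gamma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Louvain level: greedy node moves from singleton start until stable."""
    n = wp.shape[0]
    labels = np.arange(n)
    sp, sn = wp.sum(axis=1), wn.sum(axis=1)
    tot_p, tot_n = sp.copy(), sn.copy()  # per-module strength totals
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            kp = np.bincount(labels, weights=wp[i], minlength=n)
            kn = np.bincount(labels, weights=wn[i], minlength=n)
            kp[a] -= wp[i, i]
            kn[a] -= wn[i, i]
            tot_p[a] -= sp[i]
            tot_n[a] -= sn[i]
            gain = np.zeros(n)
            if vp > 0:
                gain += 2.0 * kp / vp - 2.0 * gamma * sp[i] * tot_p / vp**2
            if vn > 0:
                gain -= lam * (2.0 * kn / vn - 2.0 * gamma * sn[i] * tot_n / vn**2)
            b = int(np.argmax(gain))
            if gain[b] <= gain[a] + 1e-12:
                b = a
            elif b != a:
                improved = True
            labels[i] = b
            tot_p[b] += sp[i]
            tot_n[b] += sn[i]
    return labels


def _aggregate(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    mods = np.unique(labels)
    c = (labels[:, None] == mods[None, :]).astype(float)
    return c.T @ w @ c


def louvain_signed(
    w: np.ndarray, seed: int = 0, gamma: float = 1.0
) -> np.ndarray:
    """Multi-level Louvain on the asymmetric signed objective; labels 1..K.

    The number of modules follows from the objective's own stopping
    behaviour: levels end when no merge or move improves Q*.
    """
    w = _as_weights(w)
    wp, wn = _split_signed(w)
    vp, vn = wp.sum(), wn.sum()
    if vp + vn == 0:
        raise DegenerateGraphError("all-zero matrix has no modular structure")
    lam = vn / (vp + vn)
    rng = np.random.default_rng(seed)

    n = w.shape[0]
    full = np.arange(n)
    cur_p, cur_n = wp, wn
    while True:
        labels = _louvain_moves(cur_p, cur_n, vp, vn, lam, gamma, rng)
        labels = _canonical(labels) - 1
        k = labels.max() + 1
        full = labels[full]
        if k == cur_p.shape[0]:  # no merges at this level: converged
            break
        cur_p = _aggregate(cur_p, labels)
        cur_n = _aggregate(cur_n, labels)
    return _canonical(full + 1)


def _merge_to_k(w: np.ndarray, labels: np.ndarray, k_target: int) -> np.ndarray:
    """Greedily merge the module pair whose merge costs the least Q."""
    labels = labels.copy()
    while labels.max() > k_target:
        mods = np.unique(labels)
        best_q, best_pair = -np.inf, None
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1 :]:
                trial = labels.copy()
                trial[trial == m2] = m1
                q = signed_modularity(w, _canonical(trial))
                if q > best_q:
                    best_q, best_pair = q, (m1, m2)
        m1, m2 = best_pair
        labels[labels == m2] = m1
        labels = _canonical(labels)
    return labels


def _split_to_k(
    w: np.ndarray, labels: np.ndarray, k_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Split the largest module (sub-optimisation, eigenvector fallback) until K."""
    labels = labels.copy()
    while labels.max() < k_target:
        sizes = np.bincount(labels)[1:]
        big = int(np.argmax(sizes)) + 1
        idx = np.flatnonzero(labels == big)
        sub = w[np.ix_(idx, idx)]
        try:
            sub_labels = louvain_signed(sub, seed=int(rng.integers(2**31 - 1)))
        except DegenerateGraphError:
            sub_labels = np.ones(len(idx), dtype=int)
        if sub_labels.max() == 1:
            # forced bisection along the leading eigenvector
            vals, vecs = np.linalg.eigh(sub)
            vec = vecs[:, -1]
            half = vec > np.median(vec)
            if half.all() or not half.any():
                half = np.zeros(len(idx), dtype=bool)
                half[: len(idx) // 2] = True
            sub_labels = half.astype(int) + 1
        shift = labels.max()
        labels[idx[sub_labels > 1]] = shift + sub_labels[sub_labels > 1] - 1
        labels = _canonical(labels)
    return labels


def _enforce_k(
    w: np.ndarray, labels: np.ndarray, k_target: int, rng: np.random.Generator
) -> np.ndarray:
    if labels.max() < k_target:
        labels = _split_to_k(w, labels, k_target, rng)
    if labels.max() > k_target:
        labels = _merge_to_k(w, labels, k_target)
    return labels


def signed_modularity_partition(
    conn: ConnectivityMatrix | np.ndarray,
    seed: int = 0,
    k_target: int | None = None,
    gamma: float = 1.0,
) -> Partition:
    """One optimisation run of the signed modularity objective (no thresholding)."""
    w = _as_weights(conn)
    labels = louvain_signed(w, seed=seed, gamma=gamma)
    if k_target is not None and labels.max() != k_target:
        labels = _enforce_k(w, labels, k_target, np.random.default_rng(seed))
    return Partition(labels, signed_modularity(w, labels, gamma))


def best_partition(
    conn: ConnectivityMatrix | np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
    k_target: int | None = None,
    gamma: float = 1.0,
) -> Partition:
    """Best-Q partition over random restarts with distinct derived seeds.

    With ``k_target``, the best restart that lands on exactly K modules wins;
    if none does, the overall best partition is repaired (least-cost merges,
    or re-optimisation within the largest module) to exactly K.
    """
    if n_restarts < 1:
        raise InvalidArgumentError("n_restarts must be >= 1")
    w = _as_weights(conn)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    runs = []
    for s in seeds:
        labels = louvain_signed(w, seed=int(s), gamma=gamma)
        runs.append(Partition(labels, signed_modularity(w, labels, gamma)))
    if k_target is None:
        return max(runs, key=lambda p: p.Q)
    matching = [p for p in runs if p.K == k_target]
    if matching:
        return max(matching, key=lambda p: p.Q)
    best = max(runs, key=lambda p: p.Q)
    labels = _enforce_k(w, best.assignment, k_target, rng)
    return Partition(labels, signed_modularity(w, labels, gamma))


def participation_index(
    g: SparseGraph | np.ndarray, partition: Partition | np.ndarray
) -> PiVector:
    """Strength-share participation of each node on a nonnegative graph."""
    w = g.weights if isinstance(g, SparseGraph) else np.asarray(g, float)
    if np.any(w < 0):
        raise InvalidArgumentError("participation requires nonnegative weights")
    labels = (
        partition.assignment if isinstance(partition, Partition) else np.asarray(partition)
    )
    if labels.shape[0] != w.shape[0]:
        raise InvalidArgumentError("partition does not cover the graph's nodes")
    mods = np.unique(labels)
    s_im = np.column_stack([w[:, labels == m].sum(axis=1) for m in mods])
    s_i = s_im.sum(axis=1)
    if np.any(s_i == 0):
        raise UndefinedPIError("isolated node: participation undefined")
    pi = 1.0 - ((s_im / s_i[:, None]) ** 2).sum(axis=1)
    return PiVector(pi, rank_pi(pi))


def rank_pi(pi: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..N, ties averaged (lowest PI gets rank 1)."""
    return stats.rankdata(np.asarray(pi), method="average")


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.array_equal(_canonical(a), _canonical(b)))


def group_consensus_partition(
    matrices: list[np.ndarray | ConnectivityMatrix],
    k_target: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 20,
) -> tuple[Partition, dict]:
    """Single partition summarising all subjects via Q-weighted co-assignment.

    Iteratively: per-subject best partitions are combined into a node x node
    co-assignment matrix with subject contributions weighted by their
    (nonnegative) Q; the centred consensus matrix is re-partitioned from
    several restarts, whose agreement forms the next consensus matrix, until
    the best partition is stable across two iterations. The final partition
    is constrained to exactly ``k_target`` modules.
    """
    if len(matrices) < 2:
        raise InsufficientDataError("consensus needs at least 2 subjects")
    if k_target < 2:
        raise InvalidArgumentError("k_target must be >= 2")
    ws = [_as_weights(m) for m in matrices]
    n = ws[0].shape[0]
    rng = np.random.default_rng(seed)

    def coassign(parts: list[Partition]) -> np.ndarray:
        qs = np.array([max(p.Q, 0.0) for p in parts])
        if qs.sum() == 0:
            qs = np.ones(len(parts))
        a = np.zeros((n, n))
        for q, p in zip(qs, parts):
            a += q * (p.assignment[:, None] == p.assignment[None, :])
        return a / qs.sum()

    # one shared seed keeps the consensus equivariant under subject reordering
    s_subj = int(rng.integers(2**31 - 1))
    subject_parts = [
        best_partition(w, n_restarts=n_restarts, seed=s_subj) for w in ws
    ]
    a = coassign(subject_parts)

    prev: Partition | None = None
    converged = False
    n_iter = 0
    d = np.zeros((n, n))
    for n_iter in range(1, max_iter + 1):
        off = ~np.eye(n, dtype=bool)
        d = a - a[off].mean()
        np.fill_diagonal(d, 0.0)
        runs = [
            signed_modularity_partition(d, seed=int(rng.integers(2**31 - 1)))
            for _ in range(n_restarts)
        ]
        best = max(runs, key=lambda p: p.Q)
        if prev is not None and _same_partition(best.assignment, prev.assignment):
            converged = True
            break
        prev = best
        a = coassign(runs)

    assert prev is not None
    labels = prev.assignment
    if labels.max() != k_target:
        matching = [p for p in runs if p.K == k_target]
        if matching:
            labels = max(matching, key=lambda p: p.Q).assignment
        else:
            labels = _enforce_k(d, labels, k_target, rng)
    off = ~np.eye(n, dtype=bool)
    diagnostics = {
        "n_iterations": n_iter,
        "converged": converged,
        "agreement": float(a[off].mean()),
        "subject_K": [p.K for p in subject_parts],
        "subject_Q": [p.Q for p in subject_parts],
    }
    mean_q = float(
        np.mean([signed_modularity(w, labels) for w in ws])
    )
    return Partition(labels, mean_q), diagnostics
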