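"""Community-state typing and transition dynamics.

Samples are clustered on the square root of the Jensen-Shannon divergence
(base-2, so divergences and distances both lie in [0, 1] and sqrt-JSD is a
metric) with partitioning around medoids (PAM, classical deterministic
BUILD + SWAP). The number of states is chosen by maximizing a
distance-based Calinski-Harabasz index over a K range. Per-mouse state
trajectories are summarized as a transition map: counts of mice moving
between states across consecutive scheduled timepoints, plus per-timepoint
state occupancy.

The Calinski-Harabasz index is computed purely from pairwise distances via
the identity sum_i ||x_i - centroid||^2 = (1/2n) sum_ij d_ij^2, so no
coordinate embedding is required; a principal-coordinates projection is
offered separately for visualization only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy

from .io import CohortMetadata, OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "relative_abundance",
    "jsd",
    "distance_matrix",
    "DistanceMatrix",
    "pam",
    "ch_index",
    "choose_k",
    "ClusterSolution",
    "transition_map",
    "TransitionMap",
    "pcoa_coordinates",
]


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions (rows sum to 1), indexed by sample id."""
    totals = table.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero-total sample(s): {[table.sample_ids[i] for i in zero]}"
        )
    rel = table.counts / totals[:, None]
    return pd.DataFrame(
        rel, index=pd.Index(table.sample_ids, name="sample_id"),
        columns=table.otu_ids,
    )


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits: H((p+q)/2) - (H(p)+H(q))/2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    m = (p + q) / 2.0
    val = _entropy(m, base=2) - (_entropy(p, base=2) + _entropy(q, base=2)) / 2.0
    return float(max(val, 0.0))


def _plogp_bits(x: np.ndarray) -> np.ndarray:
    """Row sums of x*log2(x) with 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(x > 0, x * np.log2(np.where(x > 0, x, 1.0)), 0.0)
    return t.sum(axis=-1)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n},{n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def distance_matrix(rel: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise sqrt-JSD distances between the rows of a simplex matrix."""
    if isinstance(rel, pd.DataFrame):
        ids = [str(s) for s in rel.index]
        X = rel.to_numpy(dtype=float)
    else:
        X = np.asarray(rel, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if X.size and not np.allclose(X.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must lie on the simplex")
    n = X.shape[0]
    h = -_plogp_bits(X)  # per-row entropy, bits
    D = np.zeros((n, n))
    for i in range(n):
        # vectorized over j > i: H((p_i + p_j)/2) - (H_i + H_j)/2
        M = (X[i][None, :] + X[i + 1:]) / 2.0
        hm = -_plogp_bits(M)
        div = hm - (h[i] + h[i + 1:]) / 2.0
        D[i, i + 1:] = np.sqrt(np.clip(div, 0.0, None))
    D = D + D.T
    return DistanceMatrix(ids, D)


# ---------------------------------------------------------------------------
# PAM (partitioning around medoids), deterministic BUILD + SWAP


@dataclass
class ClusterSolution:
    """A PAM partition: labels in 1..k, medoid sample ids, and the CH trace."""

    k: int
    medoid_ids: list[str]
    labels: pd.Series  # sample_id -> 1..k
    total_cost: float
    ch_by_k: dict[int, float]


def _assignment_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    # first medoid: minimum total distance; ties -> lowest index (argmin)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum_i max(0, dnear_i - d(i, c))
        gains = np.maximum(dnear[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        dnear = np.minimum(dnear, D[:, c])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    n = D.shape[0]
    medoids = list(medoids)
    cost = _assignment_cost(D, medoids)
    while True:
        Dm = D[:, medoids]  # n x k
        order = np.argsort(Dm, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = Dm[np.arange(n), nearest]
        d2 = Dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        best = (0.0, None, None)  # (new_cost - cost, m_pos, h)
        for pos in range(len(medoids)):
            # distance to the nearest medoid excluding the one being removed
            d_rest = np.where(nearest == pos, d2, d1)
            # cost after swapping medoids[pos] -> h, for every candidate h
            cand_costs = np.minimum(d_rest[:, None], D).sum(axis=0)
            cand_costs[medoids] = np.inf
            h = int(np.argmin(cand_costs))
            delta = cand_costs[h] - cost
            if delta < best[0] - 1e-12:
                best = (delta, pos, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        new_cost = _assignment_cost(D, medoids)
        assert new_cost <= cost + 1e-9, "PAM swap increased cost"
        cost = new_cost
    return medoids, cost


def _farthest_first(D: np.ndarray, k: int) -> list[int]:
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[:, medoids[0]].copy()
    while len(medoids) < k:
        c = int(np.argmax(dnear))
        medoids.append(c)
        dnear = np.minimum(dnear, D[:, c])
    return medoids


def pam(D: DistanceMatrix, k: int) -> ClusterSolution:
    """PAM k-medoids: BUILD + best-improvement SWAP to a local optimum.

    The SWAP phase is additionally run from two alternative deterministic
    seedings (farthest-first and the k most central samples) and the lowest
    total cost wins; the greedy BUILD start is kept on ties, so the result
    is never worse than BUILD alone. Fully deterministic: every tie breaks
    toward the lowest sample index, and repeated runs on the same matrix
    give identical partitions.
    """
    n = D.n
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n_samples={n}, got {k}")
    starts = [
        _pam_build(D.values, k),
        _farthest_first(D.values, k),
        list(np.argsort(D.values.sum(axis=1), kind="stable")[:k]),
    ]
    medoids, cost = None, np.inf
    for start in starts:
        m, c = _pam_swap(D.values, [int(i) for i in start])
        if c < cost - 1e-12:
            medoids, cost = m, c
    medoids = sorted(medoids)
    labels_idx = np.argmin(D.values[:, medoids], axis=1)
    labels = pd.Series(
        labels_idx + 1, index=pd.Index(D.sample_ids, name="sample_id"),
        name="state",
    )
    # a medoid is always its own nearest medoid (distance 0)
    return ClusterSolution(
        k=k,
        medoid_ids=[D.sample_ids[m] for m in medoids],
        labels=labels,
        total_cost=cost,
        ch_by_k={},
    )


def ch_index(D: DistanceMatrix, labels: np.ndarray | pd.Series) -> float:
    """Distance-based Calinski-Harabasz index.

    W = sum over clusters of (1/2n_c) * sum of squared pairwise distances
    within the cluster; T likewise over all samples; B = T - W;
    CH = (B/(k-1)) / (W/(n-k)).
    """
    lab = np.asarray(labels.values if isinstance(labels, pd.Series) else labels)
    n = D.n
    if lab.shape[0] != n:
        raise ValueError("labels length does not match distance matrix")
    uniq = np.unique(lab)
    k = uniq.size
    if k < 2:
        raise ValueError("Calinski-Harabasz index needs >= 2 clusters")
    D2 = D.values ** 2
    T = D2.sum() / (2.0 * n)
    W = 0.0
    for u in uniq:
        idx = np.flatnonzero(lab == u)
        W += D2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    B = max(T - W, 0.0)
    if W <= 0.0:
        logger.warning("ch_index: zero within-cluster dispersion; returning inf")
        return float("inf")
    return float((B / (k - 1)) / (W / (n - k)))


def choose_k(D: DistanceMatrix, k_range: range | None = None) -> ClusterSolution:
    """Run PAM across ``k_range`` (default 2..10) and keep the CH-optimal K.

    Ties on the CH value resolve to the smaller K. The returned solution
    carries the full ``ch_by_k`` trace.
    """
    if k_range is None:
        k_range = range(2, 11)
    ks = [k for k in k_range if 2 <= k < D.n]
    if not ks:
        raise ValueError(f"no valid k in {k_range} for n={D.n}")
    solutions: dict[int, ClusterSolution] = {}
    ch_by_k: dict[int, float] = {}
    for k in ks:
        sol = pam(D, k)
        ch_by_k[k] = ch_index(D, sol.labels)
        solutions[k] = sol
    best_k = max(sorted(ch_by_k), key=lambda k: (ch_by_k[k], -k))
    best = solutions[best_k]
    best.ch_by_k = ch_by_k
    return best


# ---------------------------------------------------------------------------
# transition map


@dataclass
class TransitionMap:
    """State occupancy and transition counts across consecutive timepoints.

    ``counts[(t, t+1)]`` is a k x k matrix of mice moving state k1 -> k2
    between scheduled timepoints t and t+1 (mice missing either timepoint
    contribute nothing across that gap); ``occupancy`` is a timepoint x
    state table of mouse counts.
    """

    counts: dict[tuple[int, int], np.ndarray]
    occupancy: pd.DataFrame
    states: list[int]


def transition_map(
    labels: pd.Series, meta: CohortMetadata
) -> TransitionMap:
    """Per-mouse state trajectories folded into transition counts."""
    df = meta.frame.loc[labels.index, ["mouse_id", "timepoint_index"]].copy()
    df["state"] = labels.values
    states = sorted(int(s) for s in df["state"].unique())
    s_pos = {s: i for i, s in enumerate(states)}
    # the schedule comes from the full metadata, so a timepoint every labeled
    # mouse happens to miss still breaks trajectories into a gap
    tps = sorted(meta.frame["timepoint_index"].unique())

    occupancy = (
        df.groupby(["timepoint_index", "state"]).size().unstack(fill_value=0)
        .reindex(index=tps, columns=states, fill_value=0)
    )
    occupancy.index.name = "timepoint_index"

    counts: dict[tuple[int, int], np.ndarray] = {
        (t1, t2): np.zeros((len(states), len(states)), dtype=int)
        for t1, t2 in zip(tps, tps[1:])
    }
    n_gaps = 0
    for _, traj in df.groupby("mouse_id", sort=False):
        traj = traj.sort_values("timepoint_index")
        t_arr = traj["timepoint_index"].to_numpy()
        s_arr = traj["state"].to_numpy()
        for (t1, t2), (s1, s2) in zip(
            zip(t_arr, t_arr[1:]), zip(s_arr, s_arr[1:])
        ):
            if (t1, t2) in counts:
                counts[(t1, t2)][s_pos[int(s1)], s_pos[int(s2)]] += 1
            else:
                n_gaps += 1
    if n_gaps:
        logger.info(
            "transition_map: %d mouse trajectory step(s) spanned a missing "
            "timepoint and were skipped", n_gaps,
        )
    return TransitionMap(counts=counts, occupancy=occupancy, states=states)


def pcoa_coordinates(D: DistanceMatrix, n_axes: int = 2) -> pd.DataFrame:
    """Principal-coordinates projection of a distance matrix (plots only)."""
    n = D.n
    D2 = D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_axes]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    return pd.DataFrame(
        coords,
        index=pd.Index(D.sample_ids, name="sample_id"),
        columns=[f"PCo{i + 1}" for i in range(len(order))],
    )
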