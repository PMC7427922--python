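"""Phenogroup discovery: distances, agglomerative clustering, k selection.

The patient-by-patient dissimilarity is the squared Euclidean distance on
the encoded matrix.  Agglomeration uses Lance-Williams updates (Ward by
default, operating directly on the squared-distance matrix) with a
deterministic lexicographic tie-break, so runs are bit-reproducible.  The
cluster count is chosen among the 2..5-cluster cuts by outcome-frequency
homogeneity: the cut whose cluster-by-outcome chi-square p-value is
smallest wins (ties to the smaller k), and every candidate's purity and
test are reported so the choice can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .preprocess import EncodedMatrix
from . import stats as _stats

LINKAGES = ("ward", "complete", "average", "single")


@dataclass
class DistanceMatrix:
    d: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.row_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.diag(self.d).any():
            raise ValueError("distance matrix diagonal not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")


@dataclass
class Dendrogram:
    """Scipy-style merge list: rows (id_i, id_j, height, size).

    Original points have ids 0..n-1; the cluster formed at step t gets id
    n + t.
    """

    merges: np.ndarray  # (n-1, 4)
    row_ids: list[str]
    linkage: str

    @property
    def n(self) -> int:
        return len(self.row_ids)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # patient_id -> cluster id 0..k-1 (A=0), -1 = noise
    k: int

    def __post_init__(self) -> None:
        assigned = self.labels[self.labels >= 0]
        if assigned.nunique() != self.k:
            raise ValueError(
                f"expected {self.k} non-empty clusters, got {assigned.nunique()}"
            )

    def sizes(self) -> pd.Series:
        return self.labels[self.labels >= 0].value_counts().sort_index()


@dataclass
class ClusteringEvaluation:
    k: int
    purity: float
    chi2: float
    p_value: float
    per_cluster_outcome_freq: dict[int, float]
    sizes: dict[int, int]


# ---------------------------------------------------------------------------


def distance_matrix(matrix: EncodedMatrix) -> DistanceMatrix:
    """Squared Euclidean distances between all patient pairs."""
    if not matrix.is_complete():
        raise ValueError("distance_matrix requires a complete (imputed) matrix")
    d = squareform(pdist(matrix.values, metric="sqeuclidean"))
    d = (d + d.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, row_ids=list(matrix.row_ids))


def hierarchical_cluster(D: DistanceMatrix, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering by Lance-Williams updates, O(n^3).

    Ward's update is applied to the squared-Euclidean dissimilarities
    directly (heights are on the squared scale).  At each step the pair
    with the smallest dissimilarity merges; exact ties break to the
    lexicographically smallest pair of cluster ids.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(D.row_ids)
    if n < 2:
        raise ValueError("need at least 2 patients to cluster")
    d = D.d.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    ids = list(range(n))  # active cluster ids, always ascending
    sizes = {i: 1 for i in range(n)}
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        m = d.shape[0]
        # first occurrence of the min in row-major upper triangle ==
        # lexicographically smallest (i, j); ids are ascending so
        # positional order equals id order
        iu = np.triu_indices(m, k=1)
        flat = d[iu]
        pos = int(np.argmin(flat))
        a, b = int(iu[0][pos]), int(iu[1][pos])
        ia, ib = ids[a], ids[b]
        h = d[a, b]
        na, nb = sizes[ia], sizes[ib]
        new_id = n + step
        merges[step] = (ia, ib, h, na + nb)

        # Lance-Williams row for the merged cluster vs every other active k
        others = [x for x in range(m) if x not in (a, b)]
        dak = d[a, others]
        dbk = d[b, others]
        if linkage == "single":
            new_row = np.minimum(dak, dbk)
        elif linkage == "complete":
            new_row = np.maximum(dak, dbk)
        elif linkage == "average":
            new_row = (na * dak + nb * dbk) / (na + nb)
        else:  # ward
            nk = np.array([sizes[ids[x]] for x in others], dtype=float)
            new_row = ((na + nk) * dak + (nb + nk) * dbk - nk * h) / (na + nb + nk)

        keep = np.array(others, dtype=int)
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)), constant_values=np.inf)
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        ids = [ids[x] for x in others] + [new_id]
        sizes[new_id] = na + nb
        del sizes[ia], sizes[ib]
    return Dendrogram(merges=merges, row_ids=list(D.row_ids), linkage=linkage)


def cut_tree(
    dend: Dendrogram, k: int, outcomes: pd.Series | None = None
) -> ClusterAssignment:
    """Undo the last k-1 merges and renumber the resulting clusters.

    With outcomes supplied, clusters are labelled by decreasing outcome
    frequency (cluster 0 = "A" = highest); otherwise by decreasing size.
    Ties break by decreasing size, then by first patient appearance.
    """
    n = dend.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        i, j, _, _ = dend.merges[step]
        new = n + step
        parent[find(int(i))] = new
        parent[find(int(j))] = new
    roots = [find(i) for i in range(n)]
    uniq: dict[int, int] = {}
    raw = np.array([uniq.setdefault(r, len(uniq)) for r in roots])
    labels = pd.Series(raw, index=pd.Index(dend.row_ids, name="patient_id"))
    return _renumber(labels, k, outcomes)


def _renumber(
    labels: pd.Series, k: int, outcomes: pd.Series | None
) -> ClusterAssignment:
    order_keys = []
    for c in sorted(labels[labels >= 0].unique()):
        members = labels.index[labels == c]
        size = len(members)
        if outcomes is not None:
            freq = float(np.asarray(outcomes.loc[members], dtype=float).mean())
        else:
            freq = 0.0
        first = int(np.argmax((labels == c).to_numpy()))
        order_keys.append((-freq, -size, first, c))
    mapping = {c: rank for rank, (_, _, _, c) in enumerate(sorted(order_keys))}
    mapping[-1] = -1
    return ClusterAssignment(labels=labels.map(mapping), k=k)


def density_cluster(
    matrix: EncodedMatrix, eps: float, min_pts: int
) -> ClusterAssignment:
    """Density-reachability clustering on the squared-Euclidean distances.

    ``eps`` is on the squared-distance scale.  Noise points get label -1
    and are excluded from the cluster count.
    """
    from sklearn.cluster import DBSCAN

    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    D = distance_matrix(matrix)
    raw = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit_predict(D.d)
    labels = pd.Series(raw, index=pd.Index(matrix.row_ids, name="patient_id"))
    k = int((labels >= 0).any() and labels[labels >= 0].nunique())
    return _renumber(labels, k, None)


# ---------------------------------------------------------------------------
# evaluation


def purity(assign: ClusterAssignment, outcomes: pd.Series) -> float:
    """Fraction of patients sharing their cluster's majority outcome."""
    labels = assign.labels
    missing = labels.index.difference(outcomes.index)
    if len(missing):
        raise ValueError(f"outcomes missing for patients {list(missing)[:5]}")
    y = outcomes.loc[labels.index].astype(int)
    total = 0
    for c in sorted(labels[labels >= 0].unique()):
        counts = y[labels == c].value_counts()
        total += int(counts.max())
    return total / int((labels >= 0).sum())


def outcome_contingency(
    assign: ClusterAssignment, outcomes: pd.Series
) -> np.ndarray:
    """k x 2 cluster-by-outcome count table (rows ordered by cluster label)."""
    labels = assign.labels
    y = outcomes.loc[labels.index].astype(int)
    rows = []
    for c in sorted(labels[labels >= 0].unique()):
        sub = y[labels == c]
        rows.append([int((sub == 1).sum()), int((sub == 0).sum())])
    return np.array(rows)


def outcome_homogeneity_test(
    assign: ClusterAssignment, outcomes: pd.Series
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the k x 2 table."""
    if assign.k < 2:
        raise ValueError("need at least 2 clusters")
    table = outcome_contingency(assign, outcomes)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty cluster in contingency table")
    res = _stats.chi_square_test(table, correction="off")
    return res.statistic, res.p_value


def evaluate_cut(
    assign: ClusterAssignment, outcomes: pd.Series
) -> ClusteringEvaluation:
    chi2, p = outcome_homogeneity_test(assign, outcomes)
    labels = assign.labels
    y = outcomes.loc[labels.index].astype(int)
    freqs = {
        int(c): float(y[labels == c].mean())
        for c in sorted(labels[labels >= 0].unique())
    }
    sizes = {int(c): int((labels == c).sum()) for c in freqs}
    return ClusteringEvaluation(
        k=assign.k,
        purity=purity(assign, outcomes),
        chi2=chi2,
        p_value=p,
        per_cluster_outcome_freq=freqs,
        sizes=sizes,
    )


def select_k(
    dend: Dendrogram,
    outcomes: pd.Series,
    k_range: range = range(2, 6),
) -> tuple[ClusterAssignment, list[ClusteringEvaluation]]:
    """Cut at each candidate k and keep the most outcome-heterogeneous cut.

    The winner minimizes the homogeneity-test p-value; exact ties go to
    the smaller k.  All evaluations are returned for reporting/override.
    """
    if outcomes is None:
        raise ValueError("select_k requires outcomes")
    evals: list[ClusteringEvaluation] = []
    cuts: dict[int, ClusterAssignment] = {}
    for k in k_range:
        assign = cut_tree(dend, k, outcomes=outcomes)
        cuts[k] = assign
        evals.append(evaluate_cut(assign, outcomes))
    best = min(evals, key=lambda e: (e.p_value, e.k))
    return cuts[best.k], evals


# ---------------------------------------------------------------------------
# model-style wrapper


class PhenomapModel:
    """Hierarchical phenomapping of an encoded cohort.

    Parameters
    ----------
    matrix : EncodedMatrix
        Complete (imputed) numeric patient matrix.
    outcomes : pandas.Series
        Binary progression outcome aligned to the matrix rows.
    """

    def __init__(self, matrix: EncodedMatrix, outcomes: pd.Series):
        if not matrix.is_complete():
            raise ValueError("PhenomapModel requires a complete (imputed) matrix")
        missing = pd.Index(matrix.row_ids).difference(outcomes.index)
        if len(missing):
            raise ValueError(f"outcomes missing for patients {list(missing)[:5]}")
        self.matrix = matrix
        self.outcomes = outcomes.loc[list(matrix.row_ids)].astype(int)

    def fit(
        self, linkage: str = "ward", k_range: range = range(2, 6)
    ) -> "PhenomapResults":
        D = distance_matrix(self.matrix)
        dend = hierarchical_cluster(D, linkage=linkage)
        selected, evals = select_k(dend, self.outcomes, k_range)
        return PhenomapResults(
            model=self, dendrogram=dend, assignment=selected, evaluations=evals
        )


@dataclass
class PhenomapResults:
    """Fitted phenomap: dendrogram, selected cut, per-k evaluations."""

    model: PhenomapModel
    dendrogram: Dendrogram
    assignment: ClusterAssignment
    evaluations: list[ClusteringEvaluation]

    @property
    def k(self) -> int:
        return self.assignment.k

    def cut(self, k: int) -> ClusterAssignment:
        return cut_tree(self.dendrogram, k, outcomes=self.model.outcomes)

    def cluster_letter(self, label: int) -> str:
        return chr(ord("A") + label)

    def summary(self) -> str:
        lines = [
            "Phenomap (agglomerative, %s linkage on squared Euclidean distances)"
            % self.dendrogram.linkage,
            f"n = {self.dendrogram.n} patients; selected k = {self.k}",
            "",
            f"{'k':>3} {'purity':>8} {'chi2':>8} {'p':>8}  cluster sizes (HFpEF freq)",
        ]
        for e in self.evaluations:
            detail = ", ".join(
                f"{self.cluster_letter(c)}:{e.sizes[c]} "
                f"({100 * e.per_cluster_outcome_freq[c]:.1f}%)"
                for c in sorted(e.sizes)
            )
            mark = " *" if e.k == self.k else ""
            lines.append(
                f"{e.k:>3} {e.purity:>8.3f} {e.chi2:>8.3f} {e.p_value:>8.4f}  "
                f"{detail}{mark}"
            )
        return "\n".join(lines)
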