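"""Social-network and dominance metrics from observation logs.

Association is measured with the dyadic association index
DAI = D_ab / (D_a + D_b - D_ab), where D_ab is time a pair spent within
1 m and D_a, D_b are the individuals' focal-sampling times.  Network
position is the eigenvector centrality of the weighted DAI matrix;
dominance is David's Score from the agonistic win/loss matrix, with
high/medium/low rank tiers cut by 1-D K-means; kinship is the number of
direct relatives each individual has within the group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

__all__ = [
    "ProximityData",
    "DaiMatrix",
    "DominanceScores",
    "CentralityVector",
    "dai",
    "dai_matrix",
    "eigenvector_centrality",
    "davids_score",
    "rank_tiers",
    "kinship_counts",
]


@dataclass
class ProximityData:
    """Co-proximity seconds per dyad plus focal seconds per individual."""

    ids: list[str]
    dyad_seconds: np.ndarray
    focal_seconds: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.dyad_seconds = np.asarray(self.dyad_seconds, dtype=float)
        self.focal_seconds = np.asarray(self.focal_seconds, dtype=float)
        if self.dyad_seconds.shape != (n, n):
            raise ValueError("dyad_seconds must be n x n")
        if self.focal_seconds.shape != (n,):
            raise ValueError("focal_seconds must have one entry per individual")
        if not np.allclose(self.dyad_seconds, self.dyad_seconds.T):
            raise ValueError("dyad_seconds must be symmetric")
        if np.any(self.dyad_seconds < 0) or np.any(self.focal_seconds < 0):
            raise ValueError("times must be nonnegative")
        if np.any(np.diag(self.dyad_seconds) != 0):
            raise ValueError("dyad_seconds diagonal must be zero")
        fa = self.focal_seconds[:, None] + self.focal_seconds[None, :]
        if np.any(self.dyad_seconds > fa + 1e-9):
            raise ValueError("dyad time exceeds combined focal time")


@dataclass
class DaiMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("DAI matrix must be symmetric")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("DAI values must lie in [0, 1]")


@dataclass
class DominanceScores:
    ids: list[str]
    ds: np.ndarray
    rank_tier: list[str] | None = None


@dataclass
class CentralityVector:
    ids: list[str]
    centrality: np.ndarray


def dai(d_ab: float, d_a: float, d_b: float) -> float:
    """Dyadic association index D_ab / (D_a + D_b - D_ab) in [0, 1]."""
    denom = d_a + d_b - d_ab
    if denom <= 0:
        raise ValueError("undefined dyad: D_a + D_b - D_ab must be positive")
    if d_ab < 0:
        raise ValueError("association time must be nonnegative")
    val = d_ab / denom
    if val > 1 + 1e-12:
        raise ValueError("DAI above 1: association time inconsistent with focal times")
    return float(min(val, 1.0))


def dai_matrix(p: ProximityData) -> DaiMatrix:
    """Element-wise DAI over all dyads (zero diagonal)."""
    n = len(p.ids)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = dai(
                    p.dyad_seconds[i, j], p.focal_seconds[i], p.focal_seconds[j]
                )
            except ValueError as exc:
                raise ValueError(f"dyad ({p.ids[i]}, {p.ids[j]}): {exc}") from exc
    return DaiMatrix(ids=list(p.ids), values=out)


def eigenvector_centrality(
    m: DaiMatrix | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10000,
    ids: list[str] | None = None,
) -> CentralityVector:
    """Leading-eigenvector centrality of a weighted association matrix.

    Accepts a DaiMatrix or any symmetric nonnegative matrix.  Power
    iteration from a uniform start; entries are nonnegative by
    Perron–Frobenius on each connected component.  A disconnected graph
    is handled per component, with all scores normalised by the single
    global maximum (and a warning logged); isolated individuals score 0.
    """
    if isinstance(m, DaiMatrix):
        a = np.asarray(m.values, dtype=float)
        ids = list(m.ids)
    else:
        a = np.asarray(m, dtype=float)
        if not np.allclose(a, a.T) or np.any(a < 0):
            raise ValueError("association matrix must be symmetric and nonnegative")
        if ids is None:
            ids = [f"id{i}" for i in range(a.shape[0])]
    n = a.shape[0]
    if not np.any(a > 0):
        raise ValueError("all-zero association matrix has no centrality")
    n_comp, labels = connected_components(a > 0, directed=False)
    active_comps = {labels[i] for i in range(n) if a[i].any()}
    if len(active_comps) > 1 or n_comp > 1:
        warnings.warn(
            "association graph is disconnected; centrality computed per component",
            stacklevel=2,
        )
    cent = np.zeros(n)
    for comp in active_comps:
        idx = np.where(labels == comp)[0]
        sub = a[np.ix_(idx, idx)]
        if not sub.any():
            continue
        # diagonal shift keeps eigenvectors but breaks the +/- lambda tie of
        # bipartite components, which would otherwise make iteration oscillate
        shift = sub.sum(axis=1).max()
        sub = sub + shift * np.eye(len(idx))
        v = np.full(len(idx), 1.0 / np.sqrt(len(idx)))
        for _ in range(max_iter):
            nv = sub @ v
            norm = np.linalg.norm(nv)
            if norm == 0:
                break
            nv /= norm
            if np.linalg.norm(nv - v) < tol:
                v = nv
                break
            v = nv
        else:
            resid = float(np.linalg.norm(sub @ v - (v @ sub @ v) * v))
            raise RuntimeError(
                f"power iteration did not converge in {max_iter} steps (residual {resid:.3e})"
            )
        cent[idx] = np.abs(v)
    cent /= cent.max()
    return CentralityVector(ids=ids, centrality=cent)


def davids_score(
    wins: np.ndarray, ids: list[str] | None = None, dyad_corrected: bool = False
) -> DominanceScores:
    """David's Score from a win matrix W[i, j] = wins of i over j.

    With the default raw win proportions, P_ij = W_ij / (W_ij + W_ji)
    for dyads that interacted and 0 otherwise; DS_i = w_i + w2_i - l_i -
    l2_i where w_i = sum_j P_ij, w2_i = sum_j P_ij * w_j, and l terms are
    the transposed analogues.  ``dyad_corrected=True`` uses the
    chance-corrected proportion Dij = P_ij - (P_ij - 0.5)/(n_ij + 1).
    Scores always sum to zero.
    """
    w = np.asarray(wins, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n) or n < 2:
        raise ValueError("wins must be a square matrix for >= 2 individuals")
    if np.any(w < 0) or np.any(np.diag(w) != 0):
        raise ValueError("wins must be nonnegative with zero diagonal")
    if ids is None:
        ids = [f"id{i}" for i in range(n)]
    tot = w + w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 0.0)
    if dyad_corrected:
        p = np.where(tot > 0, p - (p - 0.5) / (tot + 1.0), 0.0)
    np.fill_diagonal(p, 0.0)
    w1 = p.sum(axis=1)
    l1 = p.sum(axis=0)
    w2 = p @ w1
    l2 = p.T @ l1
    ds = w1 + w2 - l1 - l2
    return DominanceScores(ids=list(ids), ds=ds)


def rank_tiers(
    ds: np.ndarray, k: int = 3, seed: int = 0, n_init: int = 50
) -> list[str]:
    """Cut David's Scores into high/medium/low tiers by 1-D K-means.

    Clusters are relabeled by descending cluster mean; fewer than ``k``
    distinct score values cannot support ``k`` clusters and raise.
    """
    ds = np.asarray(ds, dtype=float)
    if len(np.unique(ds)) < k:
        raise ValueError(f"need at least {k} distinct scores for {k} tiers")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(ds.reshape(-1, 1))
    order = np.argsort(-km.cluster_centers_.ravel())
    tier_names = ["high", "medium", "low"] if k == 3 else [f"tier{i}" for i in range(k)]
    relabel = {int(cluster): tier_names[rank] for rank, cluster in enumerate(order)}
    return [relabel[int(c)] for c in labels]


def kinship_counts(
    pedigree: list[tuple[str, str]],
    roster: list[str],
    relations: tuple[str, ...] = ("parent", "offspring", "sibling"),
) -> dict[str, int]:
    """Number of direct relatives each roster member has within the group.

    ``pedigree`` holds (parent, offspring) links, which may reference
    individuals outside the roster; only roster members are counted as
    relatives.  The default relation set is parents, offspring, and
    siblings sharing a known parent.  A cyclic pedigree is rejected.
    """
    parents: dict[str, set[str]] = {}
    children: dict[str, set[str]] = {}
    for parent, child in pedigree:
        if parent == child:
            raise ValueError("cyclic pedigree: self-parentage")
        parents.setdefault(child, set()).add(parent)
        children.setdefault(parent, set()).add(child)
    _check_acyclic(children)

    roster_set = set(roster)
    counts: dict[str, int] = {}
    for ind in roster:
        rel: set[str] = set()
        if "parent" in relations:
            rel |= parents.get(ind, set())
        if "offspring" in relations:
            rel |= children.get(ind, set())
        if "sibling" in relations:
            for par in parents.get(ind, set()):
                rel |= children.get(par, set()) - {ind}
        counts[ind] = len(rel & roster_set)
    return counts


def _check_acyclic(children: dict[str, set[str]]) -> None:
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        state[node] = 1
        for ch in children.get(node, ()):  # descend parent -> child
            s = state.get(ch, 0)
            if s == 1:
                raise ValueError("cyclic pedigree")
            if s == 0:
                visit(ch)
        state[node] = 2

    for node in list(children):
        if state.get(node, 0) == 0:
            visit(node)
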