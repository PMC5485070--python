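"""Population structure: marker PCA, spatial weights, Moran's I, Ward groups.

The procedure identifies geographically informative genetic structure in an
accession panel:

1. PCA of the column-centred, column-scaled 0/1 marker matrix.
2. A neighbour graph over collection sites (symmetrized k-nearest-neighbour
   by default, Gabriel graph optionally), row-standardized into spatial
   weights.
3. Moran's I per principal component; the leading run of PCs whose spatial
   autocorrelation is significant (p < alpha, default 0.001) is retained.
4. Ward agglomerative clustering of the retained PC scores, cut into a
   fixed number of genetic groups.
5. A per-trait ANOVA of phenotypes on group membership after correcting for
   life-cycle strategy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.neighbors import NearestNeighbors

from .genotypes import GenotypeMatrix, GeoRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "SpatialWeights",
    "MoranResult",
    "GeneticGroups",
    "pca_markers",
    "build_spatial_weights",
    "morans_i",
    "select_informative_pcs",
    "ward_cluster",
    "cluster_phenotype_anova",
]


@dataclass
class PcaResult:
    """Accession scores on marker principal components."""

    scores: np.ndarray                 # n x p
    explained_fraction: np.ndarray     # per-PC fraction of total variance
    loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        ef = np.asarray(self.explained_fraction, dtype=float)
        if np.any(ef < 0) or np.any(np.diff(ef) > 1e-12) or ef.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must be non-negative, "
                             "non-increasing and sum to <= 1")
        self.explained_fraction = ef


@dataclass
class SpatialWeights:
    """Row-standardized neighbour weights over accessions."""

    accession_ids: list[str]
    neighbours: list[np.ndarray]      # per accession, indices of neighbours
    weights: list[np.ndarray]         # matching row-standardized weights
    scheme: str = "knn"

    def __post_init__(self) -> None:
        for i, (nb, w) in enumerate(zip(self.neighbours, self.weights)):
            if len(nb) != len(w):
                raise ValueError("neighbour/weight length mismatch")
            if i in nb:
                raise ValueError(f"self-neighbour at index {i}")
            if len(nb) and abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"row {i} weights do not sum to 1")

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (nb, w) in enumerate(zip(self.neighbours, self.weights)):
            W[i, nb] = w
        return W


@dataclass
class MoranResult:
    statistic: float
    expectation: float
    p_value: float
    method: str
    z_score: float | None = None


@dataclass
class GeneticGroups:
    """Ward-tree group assignment of accessions."""

    k: int
    assignment: dict[str, int]        # accession_id -> group label in 1..k
    linkage: np.ndarray               # scipy linkage matrix (merge history)

    def labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[a] for a in ids])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_markers(geno: GenotypeMatrix, n_components: int) -> PcaResult:
    """PCA of the column-centred, column-scaled marker matrix.

    Explained fractions are relative to the total variance of the scaled
    matrix (which equals the number of polymorphic markers).
    """
    X = geno.calls.astype(float)
    p = X.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; PCA undefined")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - pp) / np.sqrt(pp * (1.0 - pp))
    n = Z.shape[0]
    if n_components > min(n - 1, Z.shape[1]):
        raise ValueError(
            f"n_components {n_components} exceeds min(n - 1, m) = "
            f"{min(n - 1, Z.shape[1])}"
        )
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float(np.sum(Z * Z))
    scores = U[:, :n_components] * s[:n_components]
    explained = (s[:n_components] ** 2) / total
    return PcaResult(
        scores=scores,
        explained_fraction=explained,
        loadings=Vt[:n_components].T,
    )


# ---------------------------------------------------------------------------
# Spatial weights
# ---------------------------------------------------------------------------

def _gabriel_edges(pts: np.ndarray) -> set[tuple[int, int]]:
    """Gabriel graph by direct check: edge (i, j) is kept iff no third point
    lies in the closed disk with segment ij as diameter (so a point exactly
    on the circle blocks the edge)."""
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            mid = (pts[i] + pts[j]) / 2.0
            r2 = d2[i, j] / 4.0
            inside = np.sum((pts - mid) ** 2, axis=1) <= r2 + 1e-9 * r2
            inside[i] = inside[j] = False
            if not inside.any():
                edges.add((i, j))
    return edges


def build_spatial_weights(
    geo: Sequence[GeoRecord],
    scheme: str = "knn",
    k: int = 5,
) -> SpatialWeights:
    """Neighbour graph on (longitude, latitude) points, row-standardized.

    ``knn`` builds a k-nearest-neighbour graph (raw-degree Euclidean
    distances) symmetrized by union before standardization; distance ties
    are resolved by index order.  ``gabriel`` builds the Gabriel graph,
    which is symmetric by construction but undefined for coincident points.
    """
    pts = np.array([[g.longitude, g.latitude] for g in geo], dtype=float)
    n = len(pts)
    if n < 2 or len(np.unique(pts, axis=0)) < 2:
        raise ValueError("need at least 2 distinct coordinates")
    adjacency: list[set[int]] = [set() for _ in range(n)]
    if scheme == "knn":
        if len(np.unique(pts, axis=0)) < len(pts):
            logger.info("coincident points present; knn ties broken by index order")
        k_eff = min(k, n - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pts)
        _, idx = nn.kneighbors(pts)
        for i in range(n):
            for j in idx[i]:
                if j != i:
                    adjacency[i].add(int(j))
                    adjacency[int(j)].add(i)   # symmetrize by union
    elif scheme == "gabriel":
        if len(np.unique(pts, axis=0)) < n:
            raise ValueError("gabriel scheme undefined for coincident points")
        for i, j in _gabriel_edges(pts):
            adjacency[i].add(j)
            adjacency[j].add(i)
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    neighbours, weights = [], []
    for i in range(n):
        nb = np.array(sorted(adjacency[i]), dtype=int)
        w = np.full(len(nb), 1.0 / len(nb)) if len(nb) else np.empty(0)
        neighbours.append(nb)
        weights.append(w)
    return SpatialWeights(
        accession_ids=[g.accession_id for g in geo],
        neighbours=neighbours,
        weights=weights,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def _moran_statistic(x: np.ndarray, W: np.ndarray) -> float:
    n = len(x)
    z = x - x.mean()
    s0 = W.sum()
    return float((n / s0) * (z @ W @ z) / (z @ z))


def morans_i(
    values: np.ndarray,
    w: SpatialWeights,
    method: str = "analytic",
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Moran's I with an analytic (randomization) or permutation p-value.

    The analytic p-value uses the normal approximation with the variance
    under random relabelling of the observed values.  The permutation
    p-value is two-sided around the expectation E[I] = -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    if len(x) != w.n:
        raise ValueError("values length does not match weights")
    if np.var(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    W = w.dense()
    n = len(x)
    e_i = -1.0 / (n - 1)
    i_obs = _moran_statistic(x, W)
    if method == "analytic":
        s0 = W.sum()
        s1 = 0.5 * np.sum((W + W.T) ** 2)
        s2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
        z = x - x.mean()
        b2 = n * np.sum(z ** 4) / (np.sum(z ** 2) ** 2)
        var = (
            n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
            - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i * e_i
        zscore = (i_obs - e_i) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(zscore))
        p = float(min(max(p, np.finfo(float).tiny), 1.0))
        return MoranResult(i_obs, e_i, p, "analytic", z_score=float(zscore))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        obs_dev = abs(i_obs - e_i)
        for _ in range(n_perm):
            i_perm = _moran_statistic(rng.permutation(x), W)
            if abs(i_perm - e_i) >= obs_dev - 1e-15:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
        return MoranResult(i_obs, e_i, float(p), "permutation")
    raise ValueError(f"unknown Moran method {method!r}")


def select_informative_pcs(
    pca: PcaResult,
    w: SpatialWeights,
    alpha: float = 0.001,
    method: str = "analytic",
    rule: str = "prefix",
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Indices (0-based) of spatially informative PCs.

    Under the default ``prefix`` rule, PCs are scanned from PC1 upward and
    the scan stops at the first PC whose Moran's-I p-value fails ``alpha``;
    under ``any``, every passing PC is retained regardless of position.
    Returns a dict recording the retained indices, the rule, and the
    per-PC Moran results.
    """
    results: list[MoranResult] = []
    retained: list[int] = []
    n_pcs = pca.scores.shape[1]
    for j in range(n_pcs):
        res = morans_i(pca.scores[:, j], w, method=method, n_perm=n_perm,
                       seed=None if seed is None else seed + j)
        results.append(res)
        if res.p_value < alpha:
            retained.append(j)
        elif rule == "prefix":
            break
    if rule == "prefix":
        # retained is already the leading run
        pass
    elif rule != "any":
        raise ValueError(f"unknown selection rule {rule!r}")
    return {
        "retained": retained,
        "rule": rule,
        "alpha": alpha,
        "moran": results,
        "n_scanned": len(results),
    }


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def ward_cluster(
    scores: np.ndarray,
    n_groups: int,
    accession_ids: Sequence[str] | None = None,
) -> GeneticGroups:
    """Ward agglomerative clustering of PC scores, cut into ``n_groups``.

    Group labels are contiguous integers 1..k ordered by first appearance.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must be in [1, {n}]")
    if accession_ids is None:
        accession_ids = [str(i) for i in range(n)]
    Z = hierarchy.linkage(scores, method="ward")
    raw = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return GeneticGroups(
        k=int(labels.max()),
        assignment={a: int(l) for a, l in zip(accession_ids, labels)},
        linkage=Z,
    )


def ward_tree_newick(groups: GeneticGroups, ids: Sequence[str]) -> str:
    """Newick export of the Ward merge tree (branch lengths = merge heights)."""
    tree = hierarchy.to_tree(groups.linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Group-effect ANOVA
# ---------------------------------------------------------------------------

def cluster_phenotype_anova(
    responses: pd.DataFrame,
    groups: GeneticGroups,
    life_cycle: pd.Series,
) -> pd.DataFrame:
    """Type-II F test for the genetic-group factor, per trait.

    Fits ``response ~ life_cycle + group`` by least squares for each trait
    column of ``responses`` (indexed by accession id) and reports the
    type-II F statistic and p-value for the group factor.  Groups with
    fewer than two accessions are rejected: reduce ``n_groups`` instead.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    ids = list(responses.index.astype(str))
    labels = groups.labels(ids)
    counts = pd.Series(labels).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"groups {sorted(small.index.tolist())} have < 2 accessions; "
            "reduce n_groups"
        )
    lc = life_cycle.reindex(responses.index)
    if lc.isna().any():
        raise ValueError("every accession needs a life-cycle label")
    out = []
    for trait in responses.columns:
        df = pd.DataFrame(
            {
                "y": responses[trait].to_numpy(dtype=float),
                "life_cycle": lc.astype(str).to_numpy(),
                "group": labels.astype(str),
            }
        ).dropna(subset=["y"])
        fit = ols("y ~ C(life_cycle) + C(group)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        row = table.loc["C(group)"]
        out.append(
            {
                "trait": trait,
                "F": float(row["F"]),
                "p_value": float(row["PR(>F)"]),
                "df_group": float(row["df"]),
            }
        )
    return pd.DataFrame(out).set_index("trait")
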