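import itertools

import numpy as np
import pandas as pd
import pytest

from stresshap.genotypes import GenotypeMatrix, GeoRecord
from stresshap.structure import (GeneticGroups, MoranResult, PcaResult,
                                 SpatialWeights, build_spatial_weights,
                                 cluster_phenotype_anova, morans_i,
                                 pca_markers, select_informative_pcs,
                                 ward_cluster)


def _geno_from_calls(calls):
    n, m = calls.shape
    markers = pd.DataFrame(
        {"marker_id": [f"m{j}" for j in range(m)], "chromosome": "1",
         "position": np.arange(1, m + 1)})
    return GenotypeMatrix([f"a{i}" for i in range(n)], markers, calls)


def _geo(points):
    return [GeoRecord(f"a{i}", la, lo, 0.0) for i, (lo, la) in enumerate(points)]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_duplicate_rows_coincide_on_pcs(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 2, 30)
        calls = np.vstack([a, a, b, b])
        res = pca_markers(_geno_from_calls(calls), 2)
        assert abs(res.scores[0, 0] - res.scores[1, 0]) < 1e-10
        assert abs(res.scores[2, 0] - res.scores[3, 0]) < 1e-10
        assert abs(res.scores[0, 0] - res.scores[2, 0]) > 1e-6

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 2, (6, 20))
        geno = _geno_from_calls(calls)
        res = pca_markers(geno, 4)
        p = calls.mean(0)
        poly = (p > 0) & (p < 1)
        Z = (calls[:, poly] - p[poly]) / np.sqrt(p[poly] * (1 - p[poly]))
        evals, evecs = np.linalg.eigh(Z @ Z.T)
        order = np.argsort(evals)[::-1]
        for j in range(4):
            v = evecs[:, order[j]] * np.sqrt(evals[order[j]])
            s = res.scores[:, j]
            assert min(np.max(np.abs(s - v)), np.max(np.abs(s + v))) < 1e-10

    def test_monomorphic_only_errors(self):
        calls = np.ones((4, 10), dtype=int)
        with pytest.raises(ValueError, match="monomorphic"):
            pca_markers(_geno_from_calls(calls), 2)

    def test_explained_fraction_invariants(self, small_sim):
        res = pca_markers(small_sim.genotypes, 10)
        ef = res.explained_fraction
        assert np.all(ef >= 0) and np.all(np.diff(ef) <= 1e-12)
        assert ef.sum() <= 1 + 1e-9


# ---------------------------------------------------------------------------
# Spatial weights
# ---------------------------------------------------------------------------

class TestSpatialWeights:
    def test_collinear_knn_union(self):
        w = build_spatial_weights(_geo([(0, 0), (1, 0), (2, 0)]),
                                  scheme="knn", k=1)
        # middle point is nearest to both ends; union symmetrization links it
        # to both, each end only to the middle
        assert set(w.neighbours[1]) == {0, 2}
        assert set(w.neighbours[0]) == {1}
        assert set(w.neighbours[2]) == {1}

    def test_rows_standardized(self, small_sim):
        w = build_spatial_weights(small_sim.geo, scheme="knn", k=5)
        for row in w.weights:
            assert row.sum() == pytest.approx(1.0)

    def test_square_gabriel_edges(self):
        w = build_spatial_weights(
            _geo([(0, 0), (1, 0), (1, 1), (0, 1)]), scheme="gabriel")
        edges = {(i, int(j)) for i, nbs in enumerate(w.neighbours) for j in nbs}
        # the four sides, no diagonals
        assert edges == {(0, 1), (1, 0), (1, 2), (2, 1), (2, 3), (3, 2),
                         (0, 3), (3, 0)}

    def test_gabriel_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.random((9, 2)) * 10
        w = build_spatial_weights(_geo([tuple(p) for p in pts]),
                                  scheme="gabriel")
        got = {(i, int(j)) for i, nbs in enumerate(w.neighbours) for j in nbs
               if i < j}
        expected = set()
        for i, j in itertools.combinations(range(len(pts)), 2):
            mid = (pts[i] + pts[j]) / 2
            r2 = np.sum((pts[i] - pts[j]) ** 2) / 4
            ok = all(np.sum((pts[k] - mid) ** 2) > r2 + 1e-9 * r2
                     for k in range(len(pts)) if k not in (i, j))
            if ok:
                expected.add((i, j))
        assert got == expected

    def test_gabriel_coincident_points_error(self):
        with pytest.raises(ValueError, match="coincident"):
            build_spatial_weights(_geo([(0, 0), (0, 0), (1, 1)]),
                                  scheme="gabriel")


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def _rook_lattice_weights():
    # 2x2 lattice, rook adjacency
    nbrs = {0: [1, 2], 1: [0, 3], 2: [0, 3], 3: [1, 2]}
    return SpatialWeights(
        accession_ids=[f"a{i}" for i in range(4)],
        neighbours=[np.array(nbrs[i]) for i in range(4)],
        weights=[np.full(2, 0.5) for _ in range(4)],
    )


class TestMoran:
    def test_constant_values_error(self):
        w = _rook_lattice_weights()
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(4), w)

    def test_matches_double_sum_oracle(self):
        w = _rook_lattice_weights()
        x = np.array([1.0, 2.0, 2.0, 1.0])
        res = morans_i(x, w, method="analytic")
        W = w.dense()
        z = x - x.mean()
        n, s0 = 4, W.sum()
        oracle = (n / s0) * sum(
            W[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
        ) / sum(z[i] ** 2 for i in range(n))
        assert res.statistic == pytest.approx(oracle, abs=1e-12)
        assert res.expectation == pytest.approx(-1 / 3)

    def test_gradient_on_line_is_autocorrelated(self):
        pts = [(float(i), 0.0) for i in range(50)]
        w = build_spatial_weights(_geo(pts), scheme="knn", k=2)
        values = np.array([p[0] for p in pts])
        res = morans_i(values, w, method="permutation", n_perm=999, seed=1)
        assert res.statistic > 0
        assert res.p_value < 0.05

    def test_permutation_p_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        pts = [(float(i % 7), float(i // 7)) for i in range(21)]
        w = build_spatial_weights(_geo(pts), scheme="knn", k=3)
        x = rng.normal(size=21)
        p1 = morans_i(x, w, method="permutation", n_perm=499, seed=11).p_value
        p2 = morans_i(x, w, method="permutation", n_perm=499, seed=11).p_value
        assert p1 == p2

    def test_permutation_mean_matches_expectation(self):
        # mean of I over random relabellings approaches -1/(n-1)
        rng = np.random.default_rng(4)
        pts = [(float(i % 5), float(i // 5)) for i in range(20)]
        w = build_spatial_weights(_geo(pts), scheme="knn", k=3)
        x = rng.normal(size=20)
        W = w.dense()
        n, s0 = 20, W.sum()
        stats_ = []
        for _ in range(10_000):
            xp = rng.permutation(x)
            z = xp - xp.mean()
            stats_.append((n / s0) * (z @ W @ z) / (z @ z))
        stats_ = np.array(stats_)
        se = stats_.std() / np.sqrt(len(stats_))
        assert abs(stats_.mean() - (-1 / 19)) < 3 * se


# ---------------------------------------------------------------------------
# PC selection
# ---------------------------------------------------------------------------

class TestSelectInformativePcs:
    def _weights_and_coords(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 2)) * 10
        return build_spatial_weights(_geo([tuple(p) for p in pts]), "knn", 5), pts

    def test_coordinates_copied_pc_retained(self):
        w, pts = self._weights_and_coords()
        scores = np.column_stack([pts[:, 0], np.random.default_rng(1).normal(size=60)])
        pca = PcaResult(scores=scores, explained_fraction=np.array([0.3, 0.1]))
        sel = select_informative_pcs(pca, w, alpha=0.001)
        assert 0 in sel["retained"]

    def test_spatially_random_pcs_empty(self):
        w, _ = self._weights_and_coords(seed=3)
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(60, 5))
        pca = PcaResult(scores=scores,
                        explained_fraction=np.linspace(0.2, 0.1, 5))
        sel = select_informative_pcs(pca, w, alpha=0.001)
        assert sel["retained"] == []

    def test_prefix_rule_stops_at_first_failure(self):
        w, pts = self._weights_and_coords(seed=5)
        rng = np.random.default_rng(6)
        scores = np.column_stack(
            [pts[:, 0], rng.normal(size=60), pts[:, 1]])
        pca = PcaResult(scores=scores,
                        explained_fraction=np.array([0.3, 0.2, 0.1]))
        prefix = select_informative_pcs(pca, w, alpha=0.001, rule="prefix")
        any_rule = select_informative_pcs(pca, w, alpha=0.001, rule="any")
        assert prefix["retained"] == [0]
        assert any_rule["retained"] == [0, 2]

    def test_determinism(self, small_sim):
        geno = small_sim.genotypes
        pca = pca_markers(geno, 5)
        w = build_spatial_weights(small_sim.geo, "knn", 5)
        s1 = select_informative_pcs(pca, w, method="permutation", seed=3)
        s2 = select_informative_pcs(pca, w, method="permutation", seed=3)
        assert s1["retained"] == s2["retained"]


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def brute_force_ward(X):
    """Exhaustive greedy Ward: merge the pair minimizing the SSE increase.

    Returns the sequence of merged partitions (as frozensets of frozensets)
    and the SSE increase at each step.
    """
    clusters = [frozenset([i]) for i in range(len(X))]
    partitions, deltas = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ia = np.array(sorted(clusters[a]))
            ib = np.array(sorted(clusters[b]))
            na, nb = len(ia), len(ib)
            ca, cb = X[ia].mean(0), X[ib].mean(0)
            delta = na * nb / (na + nb) * np.sum((ca - cb) ** 2)
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        partitions.append(frozenset(clusters))
        deltas.append(delta)
    return partitions, deltas


class TestWard:
    def test_singletons(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        groups = ward_cluster(X, 5)
        assert sorted(groups.assignment.values()) == [1, 2, 3, 4, 5]

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)),
                       rng.normal(10, 0.1, (20, 2))])
        groups = ward_cluster(X, 2)
        labels = np.array([groups.assignment[str(i)] for i in range(40)])
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_merge_sequence_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        groups = ward_cluster(X, 1)
        # replay scipy's merge sequence into partitions
        n = len(X)
        members = {i: frozenset([i]) for i in range(n)}
        partitions = []
        active = set(range(n))
        for step, (a, b, dist, _) in enumerate(groups.linkage):
            new = members[int(a)] | members[int(b)]
            members[n + step] = new
            active -= {int(a), int(b)}
            active.add(n + step)
            partitions.append(frozenset(members[k] for k in active))
        oracle_partitions, oracle_deltas = brute_force_ward(X)
        assert partitions == oracle_partitions
        # scipy's ward heights relate to the SSE increase: h = sqrt(2 delta)
        np.testing.assert_allclose(groups.linkage[:, 2],
                                   np.sqrt(2 * np.array(oracle_deltas)),
                                   atol=1e-10)

    def test_objective_monotone_along_merges(self, small_sim):
        pca = pca_markers(small_sim.genotypes, 5)
        groups = ward_cluster(pca.scores, 1)
        heights = groups.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-10)


# ---------------------------------------------------------------------------
# Group ANOVA
# ---------------------------------------------------------------------------

class TestClusterAnova:
    def _setup(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"a{i}" for i in range(n)]
        groups = GeneticGroups(
            k=3,
            assignment={a: i % 3 + 1 for i, a in enumerate(ids)},
            linkage=np.zeros((n - 1, 4)),
        )
        lc = pd.Series(rng.choice(["winter", "summer"], n),
                       index=pd.Index(ids))
        return ids, groups, lc, rng

    def test_null_p_uniform(self):
        ids, groups, lc, rng = self._setup()
        hits = 0
        reps = 1000
        for _ in range(reps):
            resp = pd.DataFrame({"t": rng.normal(size=60)},
                                index=pd.Index(ids))
            p = cluster_phenotype_anova(resp, groups, lc).loc["t", "p_value"]
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_shifted_groups_detected(self):
        ids, groups, lc, rng = self._setup(seed=2)
        shift = np.array([groups.assignment[a] for a in ids]) * 2.0
        resp = pd.DataFrame({"t": rng.normal(size=60) + shift},
                            index=pd.Index(ids))
        p = cluster_phenotype_anova(resp, groups, lc).loc["t", "p_value"]
        assert p < 1e-3

    def test_small_group_errors(self):
        ids, groups, lc, rng = self._setup()
        groups.assignment[ids[0]] = 99
        resp = pd.DataFrame({"t": rng.normal(size=60)}, index=pd.Index(ids))
        with pytest.raises(ValueError, match="reduce n_groups"):
            cluster_phenotype_anova(resp, groups, lc)
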