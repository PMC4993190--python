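"""Ward functional grouping, summary tables and trait correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from seedgerm.grouping import (
    family_summary,
    group_summary,
    linkage_to_newick,
    multiple_r_squared,
    trait_correlation,
    ward_cluster,
    ward_linkage,
)
from seedgerm.io import GROUP1_SPECIES, load_table1_fixture
from seedgerm.types import EstimationError, ValidationError


def brute_force_ward(X):
    """Independent greedy Ward oracle: recompute within-cluster ESS from scratch.

    At each step, evaluate the total ESS increase of every candidate merge by
    summing squared deviations from the merged cluster's mean, and merge the
    cheapest pair (lowest ids on ties).
    """
    X = np.asarray(X, float)
    n = len(X)

    def ess(members):
        pts = X[list(members)]
        return float(np.sum((pts - pts.mean(axis=0)) ** 2))

    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                delta = ess(clusters[a] | clusters[b]) - ess(clusters[a]) - ess(clusters[b])
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        delta, a, b = best
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        merges.append((a, b, delta))
        next_id += 1
    return merges


def _profiles(X, ids=None):
    ids = ids or [f"s{i}" for i in range(len(X))]
    return pd.DataFrame(
        {"species_id": ids, "t0": X[:, 0], "topt": X[:, 1],
         "tmax": X[:, 0] * 0 + 35.0, "psi_b": -np.ones(len(X))}
    )


class TestWardLinkage:
    def test_matches_exhaustive_oracle_small_n(self):
        rng = np.random.default_rng(11)
        for n in (4, 5, 6, 7):
            X = rng.normal(size=(n, 3))
            mine = ward_linkage(X)
            oracle = brute_force_ward(X)
            for m, (a, b, delta) in zip(mine, oracle):
                assert {m.left, m.right} == {a, b}
                assert m.height == pytest.approx(delta, rel=1e-9)

    def test_two_pairs_and_outlier(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0], [20.0, -10.0]])
        df = _profiles(X)
        fg = ward_cluster(df, k=3, features=("t0", "topt"))
        labels = [fg.labels[s] for s in df.species_id]
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[4] not in (labels[0], labels[2])

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        hs = [m.height for m in ward_linkage(X)]
        assert all(b >= a - 1e-12 for a, b in zip(hs, hs[1:]))

    def test_agrees_with_scipy_ward(self):
        """Independent cross-check: scipy heights h relate to ESS increase by h^2/2."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        mine = ward_linkage(X)
        Z = linkage(X, method="ward")
        np.testing.assert_allclose(
            sorted(m.height for m in mine), sorted(Z[:, 2] ** 2 / 2.0), rtol=1e-8
        )
        df = pd.DataFrame(
            {"species_id": [f"s{i}" for i in range(len(X))],
             "t0": X[:, 0], "topt": X[:, 1], "tmax": X[:, 2], "psi_b": X[:, 3]}
        )
        for k in (2, 3, 5):
            fg = ward_cluster(df, k=k)
            scipy_labels = fcluster(Z, k, criterion="maxclust")
            # same partition up to label permutation
            mine_labels = np.array([fg.labels[s] for s in df.species_id])
            same_mine = mine_labels[:, None] == mine_labels[None, :]
            same_scipy = scipy_labels[:, None] == scipy_labels[None, :]
            # scipy uses Euclidean distances; partitions coincide for generic data
            assert np.array_equal(same_mine, same_scipy)

    def test_k_extremes_and_nesting(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 4))
        df = _profiles(X)
        singletons = ward_cluster(df, k=8, features=("t0", "topt"))
        assert len(set(singletons.labels.values())) == 8
        one = ward_cluster(df, k=1, features=("t0", "topt"))
        assert set(one.labels.values()) == {1}
        for k in (7, 6, 5, 4, 3, 2):
            a = ward_cluster(df, k=k, features=("t0", "topt")).labels
            b = ward_cluster(df, k=k - 1, features=("t0", "topt")).labels
            # cutting one level deeper merges exactly two existing groups
            groups_a = {frozenset(s for s in a if a[s] == g) for g in set(a.values())}
            groups_b = {frozenset(s for s in b if b[s] == g) for g in set(b.values())}
            merged = groups_b - groups_a
            split = groups_a - groups_b
            assert len(merged) == 1 and len(split) == 2
            assert next(iter(merged)) == frozenset.union(*split)

    def test_missing_feature_and_bad_k(self):
        df = _profiles(np.zeros((3, 2))).drop(columns=["psi_b"])
        with pytest.raises(ValidationError, match="psi_b"):
            ward_cluster(df, k=2)
        with pytest.raises(ValidationError):
            ward_cluster(_profiles(np.zeros((3, 2))), k=4)


class TestSummaries:
    def test_group1_means_from_reference_table(self):
        t1 = load_table1_fixture()
        sub = t1[t1.species.isin(GROUP1_SPECIES)]
        assert round(sub.tmax_mean.mean(), 1) == 41.2
        assert round(sub.topt_mean.mean(), 1) == 32.4
        assert round(sub.t0_mean.mean(), 1) == 10.0

    def test_singleton_group_sd_zero_with_flag(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [9.0, 9.0]])
        df = _profiles(X)
        fg = ward_cluster(df, k=2, features=("t0", "topt"))
        summ = group_summary(fg, df, features=("t0", "topt"))
        single = summ[summ.n_species == 1]
        assert len(single) == 1
        assert bool(single.singleton.iloc[0])
        assert float(single.t0_sd.iloc[0]) == 0.0

    def test_identical_members_sd_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [8.0, 8.0]])
        df = _profiles(X)
        fg = ward_cluster(df, k=2, features=("t0", "topt"))
        summ = group_summary(fg, df, features=("t0", "topt"))
        pair = summ[summ.n_species == 2]
        assert float(pair.t0_sd.iloc[0]) == 0.0

    def test_family_means_from_reference_table(self):
        t1 = load_table1_fixture().rename(columns={"species": "species_id"})
        summ = family_summary(t1, feature_cols=["tb_mean"])
        assert round(float(summ.loc["Brassicaceae", "tb_mean_mean"]), 1) == 5.4
        assert round(float(summ.loc["Fabaceae", "tb_mean_mean"]), 1) == 2.5
        # a single-species family reproduces the species value with SD 0
        assert float(summ.loc["Hydrophylaceae", "tb_mean_mean"]) == pytest.approx(3.6)
        assert float(summ.loc["Hydrophylaceae", "tb_mean_sd"]) == 0.0


class TestTraitCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, r2, p = trait_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_null_case_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        r, r2, p = trait_correlation(x, rng.normal(size=500))
        assert r2 < 0.02

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        # textbook formula by hand
        r_hand = float(np.sum((x - 3) * (y - y.mean())) /
                       np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - y.mean()) ** 2)))
        r, r2, _ = trait_correlation(x, y)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert r2 == pytest.approx(r_hand**2, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(EstimationError):
            trait_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_multiple_r_squared_perfect_fit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        assert multiple_r_squared(X, y) == pytest.approx(1.0)


class TestNewick:
    def test_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 2))
        merges = ward_linkage(X)
        nwk = linkage_to_newick(merges, [f"s{i}" for i in range(6)])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == [f"s{i}" for i in range(6)]
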