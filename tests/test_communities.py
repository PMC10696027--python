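import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from csncrit.communities import (
    CommunityPartition,
    community_descriptor_screen,
    descriptor_filter,
    louvain_partition,
    modularity_direct,
    moods_median_test,
)
from csncrit.network import ThresholdNetwork, build_network, sample_er


def from_edges(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return ThresholdNetwork(graph=g)


def k4(offset):
    return [(offset + i, offset + j) for i in range(4) for j in range(i + 1, 4)]


class TestLouvain:
    def test_two_disjoint_cliques(self):
        part = louvain_partition(from_edges(8, k4(0) + k4(4)), seed=1)
        assert part.sizes == [4, 4]
        # two equal disconnected cliques: Q = 1 - 1/k with k = 2
        assert part.modularity == pytest.approx(0.5)
        assert part.fraction_connected == 1.0

    def test_edgeless_graph_gives_singletons(self):
        part = louvain_partition(from_edges(5, []), seed=1)
        assert part.sizes == [1] * 5
        assert part.modularity == 0.0
        assert part.fraction_connected == 0.0

    def test_every_node_assigned_once_and_sizes_sum(self):
        net = sample_er(60, 120, seed=8)
        part = louvain_partition(net, seed=3)
        assert sorted(part.assignment.keys()) == list(range(60))
        assert sum(part.sizes) == 60

    def test_modularity_matches_direct_formula(self):
        for s in range(5):
            net = sample_er(40, 90, seed=100 + s)
            part = louvain_partition(net, seed=s)
            assert part.modularity == pytest.approx(
                modularity_direct(net, part.assignment), abs=1e-12
            )

    def test_reproducible_under_seed(self):
        net = sample_er(50, 100, seed=21)
        a = louvain_partition(net, seed=5)
        b = louvain_partition(net, seed=5)
        assert a.assignment == b.assignment

    def test_recovers_planted_families(self, planted_store):
        """Exact recovery at any threshold inside the similarity gap."""
        from csncrit.synth import planted_families

        truth = planted_families(planted_store)
        for t in (0.5, 0.6, 0.7):
            part = louvain_partition(build_network(planted_store, t), seed=0)
            labels = [part.assignment[i] for i in range(len(truth))]
            # adjusted Rand == 1 iff the partitions are identical up to relabel
            pairs = {}
            for a, b in zip(truth, labels):
                pairs.setdefault(a, set()).add(b)
            assert all(len(v) == 1 for v in pairs.values())
            assert len({next(iter(v)) for v in pairs.values()}) == len(pairs)


class TestDescriptorFilter:
    def test_constant_column_dropped(self):
        t = pd.DataFrame({"const": [1.0] * 10, "varied": np.arange(10.0)})
        out = descriptor_filter(t)
        assert list(out.columns) == ["varied"]

    def test_near_constant_dropped(self):
        col = np.ones(100)
        col[:5] = 2.0  # 5% variability < 10%
        t = pd.DataFrame({"near": col, "ok": np.arange(100.0)})
        assert list(descriptor_filter(t, 0.10).columns) == ["ok"]

    def test_distinct_values_kept(self):
        t = pd.DataFrame({"x": np.arange(20.0)})
        assert list(descriptor_filter(t).columns) == ["x"]

    def test_boundary_is_strict(self):
        col = np.ones(100)
        col[:10] = 2.0  # exactly 10% variability: kept (not "lower than")
        t = pd.DataFrame({"edge": col})
        assert list(descriptor_filter(t, 0.10).columns) == ["edge"]


class TestMoodsMedianTest:
    def test_fully_separated_groups(self):
        chi2, p = moods_median_test([[1, 2, 3, 4], [5, 6, 7, 8]])
        assert chi2 == pytest.approx(8.0)
        assert p == pytest.approx(0.004678, abs=1e-5)

    def test_identical_samples(self):
        chi2, p = moods_median_test([[1, 2, 3], [1, 2, 3]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_interleaved_groups(self):
        chi2, _ = moods_median_test([[1, 3], [2, 4]])
        assert chi2 == pytest.approx(0.0)

    def test_ties_counted_not_above(self):
        # grand median 2; the tied 2s go to the not-above row
        chi2, _ = moods_median_test([[2, 2, 2, 3], [1, 2, 2, 2]])
        assert chi2 == pytest.approx(1.1428571, abs=1e-6)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            moods_median_test([[5, 5], [5, 5]])  # nothing above the grand median

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            moods_median_test([[1, 2]])
        with pytest.raises(ValueError):
            moods_median_test([[1, 2], []])

    def test_matches_scipy(self, rng):
        for _ in range(25):
            groups = [rng.normal(loc, 1.0, size=int(rng.integers(5, 25)))
                      for loc in rng.uniform(-1, 1, size=int(rng.integers(2, 5)))]
            chi2, p = moods_median_test(groups)
            ref_chi2, ref_p, _, _ = sps.median_test(
                *groups, ties="below", correction=False
            )
            assert chi2 == pytest.approx(ref_chi2)
            assert p == pytest.approx(ref_p)


def _partition_three(n_per=40):
    assignment = {i: i // n_per for i in range(3 * n_per)}
    return CommunityPartition(
        assignment=assignment, sizes=[n_per] * 3, modularity=0.5, fraction_connected=1.0
    )


class TestDescriptorScreen:
    def test_separated_descriptor_flagged(self, rng):
        part = _partition_three()
        medians = np.repeat([10.0, 20.0, 30.0], 40)
        table = pd.DataFrame({
            "separated": medians + rng.normal(0, 1, 120),
            "flat": rng.normal(0, 1, 120),
        })
        res = community_descriptor_screen(table, part)
        assert bool(res.significant["separated"]) is True
        assert bool(res.significant["flat"]) is False
        assert res.bonferroni_m == 2 * 3

    def test_identical_distribution_not_flagged(self, rng):
        part = _partition_three()
        table = pd.DataFrame({"same": rng.normal(5, 2, 120)})
        res = community_descriptor_screen(table, part)
        assert bool(res.significant["same"]) is False

    def test_type_one_error_controlled(self, rng):
        """<= 1% of 200 null descriptors flagged at alpha 0.01 with Bonferroni."""
        part = _partition_three()
        table = pd.DataFrame(
            {f"d{k}": rng.normal(0, 1, 120) for k in range(200)}
        )
        res = community_descriptor_screen(table, part, alpha=0.01)
        assert res.n_significant / 200 <= 0.01

    def test_invariant_to_community_relabelling(self, rng):
        part = _partition_three()
        relabelled = CommunityPartition(
            assignment={n: {0: 2, 1: 0, 2: 1}[c] for n, c in part.assignment.items()},
            sizes=part.sizes, modularity=0.5, fraction_connected=1.0,
        )
        table = pd.DataFrame({
            "x": np.repeat([1.0, 5.0, 9.0], 40) + rng.normal(0, 0.5, 120)
        })
        a = community_descriptor_screen(table, part)
        b = community_descriptor_screen(table, relabelled)
        assert bool(a.significant["x"]) == bool(b.significant["x"])
        # the set of pairwise p-values is the same up to pair relabelling
        assert sorted(a.pvalues.loc["x"]) == pytest.approx(sorted(b.pvalues.loc["x"]))

    def test_medians_and_iqrs_reported(self):
        part = _partition_three()
        table = pd.DataFrame({"x": np.repeat([1.0, 5.0, 9.0], 40)})
        res = community_descriptor_screen(table, part)
        assert res.profiles.loc["x", "median_c1"] == 1.0
        assert res.profiles.loc["x", "median_c3"] == 9.0
        assert res.profiles.loc["x", "iqr_c2"] == 0.0

    def test_too_few_communities_rejected(self):
        part = CommunityPartition(
            assignment={0: 0, 1: 0, 2: 1}, sizes=[2, 1], modularity=0.0,
            fraction_connected=1.0,
        )
        with pytest.raises(ValueError):
            community_descriptor_screen(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), part)
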