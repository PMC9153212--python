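"""Tree construction under the sum/crossing rules, decomposition, stats."""

import itertools

import numpy as np
import pytest

from clonescape import (
    MutationCluster,
    build_tree,
    classify_variants,
    decompose_regions,
    lineage_stats,
    pairwise_relation,
    place_cnv_events,
    simulate_read_counts,
    simulate_truth,
    SimulationConfig,
    CNVSegment,
)
from clonescape.datatypes import CloneNode, CloneTree, RegionComposition
from clonescape.errors import (
    ClassificationUndefinedError,
    IncomparableClustersError,
    InfeasiblePhylogenyError,
)
from clonescape.phylogeny import Relation
from clonescape.synthetic import simulate_age_coupled_cohort

from conftest import toy_matrix, truth_clusters


def _cluster(cid, ccfs, size=10):
    return MutationCluster(
        cid, [f"{cid}_{i}" for i in range(size)],
        {f"R{j + 1}": v for j, v in enumerate(ccfs)},
    )


class TestPairwiseRelation:
    def test_uniform_dominance(self):
        a, b = _cluster("a", (0.9, 0.8)), _cluster("b", (0.5, 0.2))
        assert pairwise_relation(a, b) == Relation.A_CAN_CONTAIN_B
        assert pairwise_relation(b, a) == Relation.B_CAN_CONTAIN_A

    def test_crossing(self):
        a, b = _cluster("a", (0.6, 0.2)), _cluster("b", (0.2, 0.6))
        assert pairwise_relation(a, b) == Relation.BRANCHING

    def test_within_tolerance_is_ambiguous(self):
        a, b = _cluster("a", (0.5, 0.5)), _cluster("b", (0.48, 0.52))
        assert pairwise_relation(a, b) == Relation.AMBIGUOUS

    def test_no_shared_samples(self):
        a = MutationCluster("a", [], {"R1": 0.5})
        b = MutationCluster("b", [], {"R2": 0.5})
        with pytest.raises(IncomparableClustersError):
            pairwise_relation(a, b)


class TestBuildTree:
    purities = {"R1": 0.9, "R2": 0.9}

    def test_single_cluster_trunk_only(self):
        res = build_tree([_cluster("T", (1.0, 1.0))], self.purities)
        assert list(res.tree.nodes) == ["T"]

    def test_three_cluster_sibling_example(self):
        """T=(1,1), X=(0.6,0.1), Y=(0.3,0.7): X and Y branch under T."""
        res = build_tree(
            [
                _cluster("T", (1.0, 1.0)),
                _cluster("X", (0.6, 0.1)),
                _cluster("Y", (0.3, 0.7)),
            ],
            self.purities,
        )
        assert res.tree.nodes["X"].parent_id == "T"
        assert res.tree.nodes["Y"].parent_id == "T"
        assert res.tree.ambiguous_attachments == {}

    def test_ambiguous_attachment_recorded(self):
        """H fits under either of the crossing clusters C and G."""
        res = build_tree(
            [
                _cluster("T", (1.0, 1.0)),
                _cluster("C", (0.5, 0.4)),
                _cluster("G", (0.4, 0.5)),
                _cluster("H", (0.2, 0.2)),
            ],
            self.purities,
        )
        chosen = res.tree.nodes["H"].parent_id
        assert chosen in {"C", "G"}
        assert set(res.tree.ambiguous_attachments["H"]) == {"C", "G"} - {chosen}

    def test_chain_of_nested_clusters(self):
        res = build_tree(
            [
                _cluster("T", (1.0, 1.0)),
                _cluster("C", (0.5, 0.5)),
                _cluster("G", (0.4, 0.4)),
                _cluster("H", (0.2, 0.2)),
            ],
            self.purities,
        )
        assert res.tree.nodes["G"].parent_id == "C"
        assert res.tree.nodes["H"].parent_id == "G"

    def test_no_feasible_tree_reported(self):
        with pytest.raises(InfeasiblePhylogenyError):
            build_tree(
                [_cluster("A", (0.6, 0.2)), _cluster("B", (0.2, 0.6))],
                self.purities,
            )

    def test_low_purity_sample_excluded(self):
        clusters = [
            MutationCluster("T", ["t"], {"R1": 1.0, "R2": 1.0, "R3": 1.0}),
            MutationCluster("X", ["x"], {"R1": 0.5, "R2": 0.4, "R3": 0.0}),
        ]
        res = build_tree(clusters, {"R1": 0.9, "R2": 0.9, "R3": 0.02})
        assert res.tree.nodes["X"].parent_id == "T"


def _brute_force_trees(clusters, tol):
    """Independent oracle: enumerate every parent vector and filter by the
    rules directly (root containment, ancestor non-crossing, sum rule)."""
    by_id = {c.cluster_id: c for c in clusters}
    samples = sorted({s for c in clusters for s in c.ccf})
    root = max(
        clusters, key=lambda c: np.mean([c.ccf[s] for s in samples])
    ).cluster_id
    others = [c.cluster_id for c in clusters if c.cluster_id != root]
    valid = []
    for parents in itertools.product([root] + others, repeat=len(others)):
        pmap = dict(zip(others, parents))
        if any(k == v for k, v in pmap.items()):
            continue
        # acyclicity and reachability
        ok = True
        for node in others:
            seen, cur = set(), node
            while cur != root:
                if cur in seen or cur not in pmap:
                    ok = False
                    break
                seen.add(cur)
                cur = pmap[cur]
            if not ok:
                break
        if not ok:
            continue
        # ancestor dominance (no crossing along any ancestor chain)
        for node in others:
            cur = pmap[node]
            while True:
                if any(
                    by_id[cur].ccf[s] < by_id[node].ccf[s] - tol for s in samples
                ):
                    ok = False
                    break
                if cur == root:
                    break
                cur = pmap[cur]
            if not ok:
                break
        if not ok:
            continue
        # sum rule at every node
        for s in samples:
            for nid in [root] + others:
                kids = [k for k, p in pmap.items() if p == nid]
                if sum(by_id[k].ccf[s] for k in kids) > by_id[nid].ccf[s] + tol:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            valid.append(pmap)
    return root, valid


@pytest.mark.parametrize("trial", range(200))
def test_search_matches_brute_force_enumeration(trial):
    """Branch-and-bound equals exhaustive arborescence enumeration (<=6)."""
    rng = np.random.default_rng(1000 + trial)
    k = int(rng.integers(2, 7))
    n_samples = int(rng.integers(2, 5))
    # random truth tree and fractions yield rule-consistent CCFs
    parents = {0: None}
    for i in range(1, k):
        parents[i] = int(rng.integers(0, i))
    ccfs = np.zeros((k, n_samples))
    for s in range(n_samples):
        fr = rng.dirichlet(np.ones(k))
        for node in reversed(range(k)):
            ccfs[node, s] = fr[node] + sum(
                ccfs[ch, s] for ch in range(k) if parents[ch] == node
            )
    clusters = [
        _cluster(f"K{i}", tuple(np.round(ccfs[i], 3)), size=5) for i in range(k)
    ]
    purities = {f"R{j + 1}": 0.9 for j in range(n_samples)}
    tol = 0.05
    root, valid = _brute_force_trees(clusters, tol)
    try:
        res = build_tree(clusters, purities, tol=tol)
    except InfeasiblePhylogenyError:
        assert not valid
        return
    assert valid, "search found a tree the oracle says cannot exist"
    got = {
        nid: res.tree.nodes[nid].parent_id
        for nid in res.tree.nodes
        if res.tree.nodes[nid].parent_id is not None
    }
    assert got in valid


class TestDecomposition:
    def _tree(self):
        return CloneTree(
            [
                CloneNode("T", None, "T", n_mutations=10),
                CloneNode("X", "T", "X", n_mutations=5),
                CloneNode("Y", "T", "Y", n_mutations=5),
            ]
        )

    def test_founder_filling_example(self):
        """CCFs T=1.0, X=0.6, Y=0.3 decompose to X .6, Y .3, founder .1."""
        clusters = [
            MutationCluster("T", ["t"], {"R1": 1.0}),
            MutationCluster("X", ["x"], {"R1": 0.6}),
            MutationCluster("Y", ["y"], {"R1": 0.3}),
        ]
        comps = decompose_regions(self._tree(), clusters, {"R1": 0.9})
        fr = comps[0].fractions
        assert fr["X"] == pytest.approx(0.6)
        assert fr["Y"] == pytest.approx(0.3)
        assert fr["T"] == pytest.approx(0.1)
        assert comps[0].multi_lineage

    def test_pure_founder_region(self):
        clusters = [
            MutationCluster("T", ["t"], {"R1": 1.0}),
            MutationCluster("X", ["x"], {"R1": 0.0}),
            MutationCluster("Y", ["y"], {"R1": 0.0}),
        ]
        comps = decompose_regions(self._tree(), clusters, {"R1": 0.9})
        assert comps[0].fractions["T"] == pytest.approx(1.0)
        assert not comps[0].multi_lineage

    def test_low_purity_flagged_inferred_only(self):
        clusters = [
            MutationCluster("T", ["t"], {"R1": 1.0, "R2": 1.0}),
            MutationCluster("X", ["x"], {"R1": 0.5, "R2": 0.6}),
            MutationCluster("Y", ["y"], {"R1": 0.2, "R2": 0.1}),
        ]
        comps = decompose_regions(
            self._tree(), clusters, {"R1": 0.9, "R2": 0.03}
        )
        flags = {c.sample_id: c.inferred_only for c in comps}
        assert flags == {"R1": False, "R2": True}

    def test_conservation(self):
        rng = np.random.default_rng(3)
        clusters = [
            MutationCluster("T", ["t"], {"R1": 1.0}),
            MutationCluster("X", ["x"], {"R1": float(rng.uniform(0, 0.6))}),
            MutationCluster("Y", ["y"], {"R1": float(rng.uniform(0, 0.4))}),
        ]
        comps = decompose_regions(self._tree(), clusters, {"R1": 0.9})
        assert sum(comps[0].fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestClassification:
    def test_patterns(self):
        counts = toy_matrix(
            {
                "1:1": [(100, 50), (100, 50), (100, 50)],  # truncal
                "1:2": [(100, 50), (100, 50), (150, 0)],  # shared
                "1:3": [(150, 0), (150, 0), (100, 50)],  # private
                "1:4": [(150, 0), (150, 0), (150, 1)],  # undetected
            },
            samples=["R1", "R2", "R3"],
        )
        labels = classify_variants(counts, {s: 0.8 for s in ["R1", "R2", "R3"]})
        assert labels["1:1:A>T"].value == "truncal"
        assert labels["1:2:A>T"].value == "shared"
        assert labels["1:3:A>T"].value == "private"
        assert "1:4:A>T" not in labels

    def test_too_few_samples(self):
        counts = toy_matrix({"1:1": (10, 10)})
        with pytest.raises(ClassificationUndefinedError):
            classify_variants(counts, {"S1": 0.8})


class TestLineageStats:
    def test_single_branch_age(self):
        tree = CloneTree(
            [
                CloneNode("T", None, "T", n_mutations=2),
                CloneNode("A", "T", "A", n_mutations=30),
            ]
        )
        comps = [
            RegionComposition("R1", {"T": 0.1, "A": 0.9}),
            RegionComposition("R2", {"T": 0.4, "A": 0.6}),
        ]
        stats, corr = lineage_stats(tree, comps, {"R1": 0.8, "R2": 0.8})
        assert stats[0].molecular_age == 30
        assert stats[0].average_ccf == pytest.approx(0.75)
        assert corr is None

    def test_age_ccf_coupling_yields_positive_correlation(self):
        hits, reps = 0, 40
        for seed in range(reps):
            tree, comps, purities = simulate_age_coupled_cohort(
                n_lineages=10, seed=seed
            )
            _, corr = lineage_stats(tree, comps, purities)
            if corr is not None and corr[0] > 0 and corr[1] < 0.05:
                hits += 1
        assert hits / reps >= 0.9


def test_place_cnv_events_truncal_and_branch():
    cfg = SimulationConfig(n_regions=4, n_clusters=4)
    truth = simulate_truth(cfg, seed=301)
    counts = simulate_read_counts(truth, cfg, seed=302)
    clusters = truth_clusters(truth, counts)
    tree = truth.tree
    placements = {
        nid: list(truth.tree.nodes[nid].cnv_events) for nid in truth.tree.nodes
    }
    bare = CloneTree(
        [
            CloneNode(n.node_id, n.parent_id, n.cluster_id,
                      n_mutations=n.n_mutations)
            for n in truth.tree.nodes.values()
        ]
    )
    placed, unplaced = place_cnv_events(
        bare, truth.segments, truth.purities, clusters
    )
    for nid, events in placements.items():
        for ev in events:
            assert ev in placed.nodes[nid].cnv_events
    assert not unplaced
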