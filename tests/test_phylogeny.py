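"""Distances, Poisson correction, NJ reconstruction, bootstrap and subgroups."""

import math

import numpy as np
import pytest

from mybkit.phylogeny import (
    Alignment,
    DistanceMatrix,
    Node,
    SaturationError,
    SupportTree,
    assign_subgroups,
    bootstrap_support,
    distance_matrix,
    nj_build,
    pdistance,
    poisson_correct,
)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        aln = Alignment(("a", "b"), ("AAAA", "AAAA"))
        assert pdistance(aln, "a", "b") == 0.0

    def test_one_mismatch_in_four(self):
        aln = Alignment(("a", "b"), ("AAAA", "AAAT"))
        assert pdistance(aln, "a", "b") == 0.25

    def test_pairwise_deletion_ignores_gapped_columns(self):
        aln = Alignment(("a", "b"), ("AA--", "AAT-"))
        assert pdistance(aln, "a", "b") == 0.0

    def test_all_gap_pair_errors(self):
        aln = Alignment(("a", "b", "c"), ("A---", "-AAA", "AAAA"))
        with pytest.raises(ValueError):
            pdistance(aln, "a", "b")

    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0), (0.1, 0.10536), (0.5, 0.69315),
    ])
    def test_poisson_closed_form(self, p, expected):
        assert poisson_correct(p) == pytest.approx(expected, abs=5e-6)

    def test_poisson_matches_log_identity_everywhere(self):
        for p in np.linspace(0.0, 0.99, 250):
            assert abs(poisson_correct(p) - (-math.log1p(-p))) < 1e-9

    def test_poisson_saturation(self):
        with pytest.raises(SaturationError):
            poisson_correct(1.0)

    def test_poisson_strictly_increasing(self):
        grid = np.linspace(0, 0.95, 50)
        values = [poisson_correct(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))


def random_additive_tree(n: int, rng: np.random.Generator):
    """Random binary topology with random branch lengths; returns the
    leaf-to-leaf additive distance matrix and the generating bipartitions."""
    nodes = [{"leaves": (f"t{i}",), "dist": {f"t{i}": 0.0}} for i in range(n)]
    bipartitions = []
    cross: dict[tuple[str, str], float] = {}

    def join(a, b):
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for x in a["leaves"]:
            for y in b["leaves"]:
                key = tuple(sorted((x, y)))
                cross[key] = a["dist"][x] + la + lb + b["dist"][y]
        merged = {
            "leaves": a["leaves"] + b["leaves"],
            "dist": {**{k: v + la for k, v in a["dist"].items()},
                     **{k: v + lb for k, v in b["dist"].items()}},
        }
        return merged

    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        merged = join(a, b)
        if 2 <= len(merged["leaves"]) <= n - 2:
            bipartitions.append(frozenset(merged["leaves"]))
        nodes.append(merged)
    ids = tuple(sorted(nodes[0]["leaves"]))
    m = np.zeros((n, n))
    for (x, y), d in cross.items():
        i, j = ids.index(x), ids.index(y)
        m[i, j] = m[j, i] = d
    # normalize bipartitions to the side excluding the smallest leaf
    all_leaves = set(ids)
    ref = min(all_leaves)
    norm = set()
    for bp in bipartitions:
        side = frozenset(all_leaves - bp) if ref in bp else bp
        if 2 <= len(side) <= n - 2:
            norm.add(side)
    return DistanceMatrix(ids, m, "additive"), norm


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        dm = DistanceMatrix(("a", "b", "c"),
                            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.]]), "p")
        tree = nj_build(dm)
        assert len(tree.root.children) == 3
        recon = tree.path_distances()
        assert np.allclose(recon.data, dm.data[[0, 1, 2]][:, [0, 1, 2]])

    def test_four_taxon_additive_split(self):
        ids = ("A", "B", "C", "D")
        m = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0.]])
        tree = nj_build(DistanceMatrix(ids, m, "additive"))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # additive matrix must be reproduced exactly by tree path lengths
        assert np.allclose(tree.path_distances().data, m)

    def test_equal_distance_matrix_is_deterministic(self):
        ids = tuple("abcde")
        m = np.ones((5, 5)) - np.eye(5)
        t1 = nj_build(DistanceMatrix(ids, m, "p")).newick()
        t2 = nj_build(DistanceMatrix(ids, m, "p")).newick()
        assert t1 == t2

    def test_nonfinite_distance_rejected(self):
        m = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0.]])
        with pytest.raises(ValueError):
            nj_build(DistanceMatrix(("a", "b", "c"), m, "p"))

    @pytest.mark.parametrize("trial", range(20))
    def test_recovers_random_additive_topologies(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 13))
        dm, truth = random_additive_tree(n, rng)
        tree = nj_build(dm)
        assert tree.bipartitions() == truth
        assert np.allclose(tree.path_distances().data, dm.data, atol=1e-9)

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        dm, _ = random_additive_tree(8, rng)
        noisy = dm.data + rng.uniform(0, 0.05, dm.data.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = nj_build(DistanceMatrix(dm.ids, noisy, "p"))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=list(dm.ids)))
        ref = min(dm.ids)
        all_leaves = set(dm.ids)
        sk_bps = set()
        for node in sk_tree.non_tips():
            clade = frozenset(t.name for t in node.tips())
            side = frozenset(all_leaves - clade) if ref in clade else clade
            if 2 <= len(side) <= len(all_leaves) - 2:
                sk_bps.add(side)
        assert ours.bipartitions() == sk_bps


def two_block_alignment() -> Alignment:
    """Two clean 4-taxon clades separated by 20 diagnostic columns each."""
    block_a = "A" * 20 + "C" * 20
    block_b = "G" * 20 + "C" * 20
    rows = {f"a{i}": block_a for i in range(4)} | {f"b{i}": block_b for i in range(4)}
    return Alignment.from_dict(rows)


class TestBootstrap:
    def test_clean_split_gets_high_support(self):
        aln = two_block_alignment()
        for seed in (1, 2, 3):
            boot = bootstrap_support(aln, n_replicates=200, seed=seed, method="p")
            split = frozenset({"b0", "b1", "b2", "b3"})
            supports = {}

            def collect(node):
                for child, _ in node.children:
                    if not child.is_leaf:
                        clade = frozenset(child.leaves())
                        supports[clade] = child.support
                        collect(child)

            collect(boot.tree.root)
            matching = [s for c, s in supports.items()
                        if c == split or c == frozenset(aln.ids) - split]
            assert matching and all(s >= 95 for s in matching)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = two_block_alignment()
        boot = bootstrap_support(aln, n_replicates=1, seed=5, method="p")
        values = [n.support for n in boot.tree._internal_nodes()
                  if n.support is not None]
        assert values and set(values) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self):
        aln = two_block_alignment()
        t1 = bootstrap_support(aln, 50, seed=9, method="p").tree.newick()
        t2 = bootstrap_support(aln, 50, seed=9, method="p").tree.newick()
        assert t1 == t2

    def test_supports_within_bounds_and_leaf_order_invariant(self):
        aln = two_block_alignment()
        shuffled = Alignment(tuple(reversed(aln.ids)), tuple(reversed(aln.rows)))
        b1 = bootstrap_support(aln, 100, seed=3, method="p")
        b2 = bootstrap_support(shuffled, 100, seed=3, method="p")
        sup1 = {frozenset(n.leaves()): n.support for n in b1.tree._internal_nodes()}
        sup2 = {frozenset(n.leaves()): n.support for n in b2.tree._internal_nodes()}
        for clade, s in sup1.items():
            assert 0.0 <= s <= 100.0
        assert sup1 == sup2


def fixture_tree(clade_support: float, rest_supports: float = 10.0) -> SupportTree:
    """((x1,x2,x3)@support, y1, y2, (y3,y4)@rest) rooted star."""
    sub = Node(children=[(Node(name="x1"), 1.0), (Node(name="x2"), 1.0),
                         (Node(name="x3"), 1.0)], support=clade_support)
    other = Node(children=[(Node(name="y3"), 1.0), (Node(name="y4"), 1.0)],
                 support=rest_supports)
    root = Node(children=[(sub, 1.0), (Node(name="y1"), 1.0),
                          (Node(name="y2"), 1.0), (other, 1.0)])
    return SupportTree(root)


class TestSubgroups:
    def test_unsupported_tree_leaves_all_unassigned(self):
        asg = assign_subgroups(fixture_tree(40.0, 10.0))
        assert set(asg.mapping.values()) == {"unassigned"}
        assert asg.subgroups == {}

    def test_single_supported_clade_of_three(self):
        asg = assign_subgroups(fixture_tree(100.0, 10.0))
        assert len(asg.subgroups) == 1
        assert asg.subgroups["S1"]["members"] == ("x1", "x2", "x3")
        assert asg.mapping["y1"] == "unassigned"

    def test_nested_supported_clades_take_outermost(self):
        inner = Node(children=[(Node(name="x1"), 1.0), (Node(name="x2"), 1.0)],
                     support=99.0)
        outer = Node(children=[(inner, 1.0), (Node(name="x3"), 1.0)], support=80.0)
        root = Node(children=[(outer, 1.0), (Node(name="y1"), 1.0),
                              (Node(name="y2"), 1.0)])
        asg = assign_subgroups(SupportTree(root))
        assert len(asg.subgroups) == 1
        assert asg.subgroups["S1"]["members"] == ("x1", "x2", "x3")

    def test_min_size_excludes_small_clades(self):
        asg = assign_subgroups(fixture_tree(100.0, 100.0), min_size=3)
        assert len(asg.subgroups) == 1
        assert asg.mapping["y3"] == "unassigned"

    def test_planted_subgroups_recovered_exactly(self, divergent_family):
        from mybkit.domain import scan_protein
        fam = divergent_family
        doms = {g: scan_protein(p, min_score=6)[0] for g, p in fam.proteins.items()}
        dseqs = {g: fam.proteins[g][h.start - 1:h.end] for g, h in doms.items()}
        boot = bootstrap_support(Alignment.from_dict(dseqs), 100, seed=3)
        asg = assign_subgroups(boot.tree, reroot=True)
        planted: dict[str, set] = {}
        for g, rec in fam.truth.records.items():
            planted.setdefault(rec.subgroup, set()).add(g)
        got = sorted(sorted(i["members"]) for i in asg.subgroups.values())
        assert got == sorted(sorted(v) for v in planted.values())
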