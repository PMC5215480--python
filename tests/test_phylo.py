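"""Distances, neighbor joining, ladderization, RF and Newick round-trips."""

import io
import math

import numpy as np
import pytest

import multilocus as ml
from multilocus import LocusAlignment, build_container
from multilocus.errors import (
    AlphabetError,
    ComparisonError,
    IncompleteDistanceError,
    NewickParseError,
)
from multilocus.fixtures import random_binary_tree
from multilocus.phylo import (
    DistanceMatrix,
    PhyloTree,
    build_trees,
    dist_multilocus,
    ladderize,
    nj_tree,
    pairwise_distance,
    rf_distance,
    tree_distance_matrix,
)

from conftest import make_container

DET = set("ACGT")
TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def brute_force_pair_counts(s1, s2):
    """Per-column scan: compared sites, mismatches, transitions."""
    L = mism = ts = 0
    for a, b in zip(s1, s2):
        if a in DET and b in DET:
            L += 1
            if a != b:
                mism += 1
                if frozenset((a, b)) in TRANSITIONS:
                    ts += 1
    return L, mism, ts


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestPairwiseDistance:
    def test_identical_rows_zero_under_every_model(self):
        a = LocusAlignment("l", {"x": "ACGTACGT", "y": "ACGTACGT"})
        for model in ("raw-count", "p", "jc69", "k80"):
            assert pairwise_distance(a, model)[("x", "y")] == 0.0

    def test_pairwise_deletion_toy(self):
        a = LocusAlignment("l", {"x": "ACGT-A", "y": "ACCTNA"})
        d = pairwise_distance(a, "p")
        assert d[("x", "y")] == pytest.approx(0.2)  # 5 compared, 1 mismatch
        assert pairwise_distance(a, "raw-count")[("x", "y")] == 1.0

    def test_jc69_closed_form(self):
        # p = 0.25 over 4 compared sites with 1 mismatch... use 4 sites
        a = LocusAlignment("l", {"x": "AAAA", "y": "AAAC"})
        d = pairwise_distance(a, "jc69")
        assert d[("x", "y")] == pytest.approx(-0.75 * math.log(1 - 1 / 3))

    def test_k80_closed_form(self):
        # 10 sites: 2 transitions (A<->G), 1 transversion (A<->C)
        a = LocusAlignment("l", {"x": "AAAAAAAAAA", "y": "GGCAAAAAAA"})
        d = pairwise_distance(a, "k80")
        P, Q = 0.2, 0.1
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert d[("x", "y")] == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_on_random_gappy_data(self, rng):
        bases = np.array(list("ACGT-N?RY"))
        for _ in range(10):
            n, L = 5, 40
            rows = {
                f"s{i}": "".join(
                    bases[rng.integers(0, len(bases), size=L)]
                )
                for i in range(n)
            }
            a = LocusAlignment("l", rows)
            dp = pairwise_distance(a, "p")
            dk = pairwise_distance(a, "k80")
            labels = a.labels
            for i in range(n):
                for j in range(i + 1, n):
                    L2, mism, ts = brute_force_pair_counts(
                        a[labels[i]], a[labels[j]]
                    )
                    if L2 == 0:
                        assert np.isnan(dp.values[i, j])
                        assert dp.undefined[i, j]
                        continue
                    assert dp.values[i, j] == pytest.approx(mism / L2)
                    P, Q = ts / L2, (mism - ts) / L2
                    if 1 - 2 * P - Q > 0 and 1 - 2 * Q > 0:
                        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(
                            1 - 2 * Q
                        )
                        assert dk.values[i, j] == pytest.approx(expected)
                    else:
                        assert dk.saturated[i, j]

    def test_symmetry_and_zero_diagonal(self, rng):
        bases = np.array(list("ACGT"))
        rows = {
            f"s{i}": "".join(bases[rng.integers(0, 4, size=60)])
            for i in range(6)
        }
        a = LocusAlignment("l", rows)
        for model in ("p", "jc69", "k80", "raw-count"):
            d = pairwise_distance(a, model)
            # saturated jc69/k80 pairs hold NaN symmetrically
            assert np.allclose(d.values, d.values.T, equal_nan=True)
            assert np.array_equal(d.saturated, d.saturated.T)
            assert np.all(np.diag(d.values) == 0)

    def test_saturation_flagged(self):
        a = LocusAlignment("l", {"x": "ACGT", "y": "CATG"})  # p = 1
        d = pairwise_distance(a, "jc69")
        assert np.isnan(d[("x", "y")])
        assert d.saturated[0, 1]

    def test_zero_overlap_flagged_undefined(self):
        a = LocusAlignment("l", {"x": "AC--", "y": "--GT"})
        d = pairwise_distance(a, "p")
        assert d.undefined[0, 1] and np.isnan(d.values[0, 1])

    def test_jc69_requires_nucleotide(self):
        a = LocusAlignment("l", {"x": "MK", "y": "ML"}, "amino-acid")
        with pytest.raises(AlphabetError):
            pairwise_distance(a, "jc69")
        # p works on amino acids
        assert pairwise_distance(a, "p")[("x", "y")] == 0.5

    def test_jc69_first_order_agreement_at_small_p(self):
        # one mismatch in 1000 sites: p = 0.001
        x = "A" * 1000
        y = "C" + "A" * 999
        a = LocusAlignment("l", {"x": x, "y": y})
        p = pairwise_distance(a, "p")[("x", "y")]
        d = pairwise_distance(a, "jc69")[("x", "y")]
        assert abs(d - p) / p < 0.01


class TestDistMultilocus:
    def test_single_locus_pool_equals_per_locus(self, rng):
        c = make_container([[True] * 4], [50], rng)
        per = dist_multilocus(c)
        pooled = dist_multilocus(c, pool=True)
        assert np.allclose(per["locus1"].values, pooled.values)

    def test_duplicated_locus_preserves_p(self, rng):
        c = make_container([[True] * 4, [True] * 4], [40, 40], rng)
        # make locus2 a copy of locus1
        twin = LocusAlignment("locus2", c.locus("locus1").sequences)
        c2 = build_container([c.locus("locus1"), twin])
        per = dist_multilocus(c2)
        pooled = dist_multilocus(c2, pool=True)
        assert np.allclose(pooled.values, per["locus1"].values)

    def test_raw_counts_add_without_missing_data(self, rng):
        c = make_container([[True] * 5] * 3, [30, 45, 25], rng)
        per = dist_multilocus(c, model="raw-count")
        pooled = dist_multilocus(c, pool=True, model="raw-count")
        total = sum(d.values for d in per.values())
        assert np.allclose(pooled.values, total)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def quartet_ls_best_topology(d):
    """Least-squares fit of all 3 unrooted quartet topologies (oracle).

    Each topology wx|yz has 5 branch parameters (4 leaf, 1 internal); the
    winner is the topology with the smallest sum of squared residuals over
    the 6 pairwise distances.  Returns the winning cherry as a label set.
    """
    labels = d.labels
    best = None
    for order in [(0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2)]:
        rows, obs = [], []
        for i in range(4):
            for j in range(i + 1, 4):
                row = [0.0] * 5
                row[i] = 1.0
                row[j] = 1.0
                if (i < 2) != (j < 2):  # path crosses the internal branch
                    row[4] = 1.0
                rows.append(row)
                obs.append(d.values[order[i], order[j]])
        A = np.array(rows)
        sol, *_ = np.linalg.lstsq(A, np.array(obs), rcond=None)
        sse = float(np.sum((A @ sol - np.array(obs)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, frozenset({labels[order[0]], labels[order[1]]}))
    return best[1]


class TestNeighborJoining:
    additive = DistanceMatrix(
        ["A", "B", "C", "D"],
        np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        ),
    )

    def test_additive_quartet_topology_and_lengths(self):
        t = nj_tree(self.additive)
        # topology AB|CD
        assert t.bipartitions() == {frozenset({"C", "D"})}
        # leaf branch lengths 1, 2, 3, 4 and internal branch 1
        lengths = {}
        for nd in t.skbio_tree.traverse(include_self=False):
            key = nd.name if nd.is_tip() else "internal"
            lengths[key] = pytest.approx(nd.length)
        assert lengths["A"] == 1 and lengths["B"] == 2
        assert lengths["C"] == 3 and lengths["D"] == 4
        assert lengths["internal"] == 1

    def test_agrees_with_quartet_least_squares(self):
        best = quartet_ls_best_topology(self.additive)
        assert best == frozenset({"A", "B"})

    def test_three_leaf_closed_form(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        t = nj_tree(d)
        got = {nd.name: nd.length for nd in t.skbio_tree.children}
        assert got["a"] == pytest.approx(1)
        assert got["b"] == pytest.approx(1)
        assert got["c"] == pytest.approx(3)

    def test_two_leaf_degenerate(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 4], [4, 0]], float))
        t = nj_tree(d)
        assert sorted(t.leaf_names) == ["a", "b"]
        assert sum(t.branch_lengths()) == pytest.approx(4)

    def test_recovers_random_additive_trees(self, rng):
        for n in range(4, 9):
            for _ in range(10):
                labels = [f"t{k}" for k in range(n)]
                gen = random_binary_tree(labels, rng)
                d = tree_distance_matrix(gen)
                rec = nj_tree(d)
                assert rf_distance(rec, gen) == 0
                # branch lengths reproduce the patristic distances
                back = tree_distance_matrix(rec)
                order = [back.labels.index(l) for l in d.labels]
                assert np.allclose(
                    back.values[np.ix_(order, order)], d.values
                )

    def test_matches_independent_nj_topology(self, rng):
        """Cross-check against scikit-bio's own NJ on noisy matrices."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            n = 7
            labels = [f"t{k}" for k in range(n)]
            gen = random_binary_tree(labels, rng)
            d = tree_distance_matrix(gen)
            noisy = d.values + rng.uniform(0, 0.01, size=d.values.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            mine = nj_tree(DistanceMatrix(d.labels, noisy))
            theirs = PhyloTree(skbio_nj(SkbioDM(noisy, d.labels)))
            assert rf_distance(mine, theirs) == 0

    def test_undefined_pairs_poison(self):
        vals = np.array(
            [[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]], dtype=float
        )
        d = DistanceMatrix(
            ["a", "b", "c"], vals, undefined=~np.isfinite(vals)
        )
        with pytest.raises(IncompleteDistanceError):
            nj_tree(d)


# ---------------------------------------------------------------------------
# build_trees workflow
# ---------------------------------------------------------------------------

class TestBuildTrees:
    def test_worked_example_leaf_counts(self, worked_example):
        trees = build_trees(worked_example)
        assert [trees[n].n_leaves for n in worked_example.locus_names] == [
            5, 6, 8, 5,
        ]

    def test_pooled_tree_covers_everyone(self, worked_example):
        t = build_trees(worked_example, pool=True)
        assert t.n_leaves == 8

    def test_clamped_branches_non_negative(self, worked_example):
        for t in build_trees(worked_example).values():
            assert min(t.branch_lengths()) >= 0

    def test_unclamped_may_go_negative(self):
        # a famously non-additive matrix yields a negative NJ branch
        vals = np.array(
            [
                [0, 5, 9, 9],
                [5, 0, 10, 10],
                [9, 10, 0, 1],
                [9, 10, 1, 0],
            ],
            dtype=float,
        )
        t = nj_tree(DistanceMatrix(list("abcd"), vals))
        clamped = t.clamped()
        assert min(clamped.branch_lengths()) >= 0
        assert clamped.bipartitions() == t.bipartitions()

    def test_sparse_locus_skipped_with_warning(self, rng):
        presence = [[True, True, False, False], [True] * 4]
        c = make_container(presence, [20, 20], rng)
        with pytest.warns(UserWarning, match="skipped"):
            trees = build_trees(c)
        assert list(trees) == ["locus2"]


# ---------------------------------------------------------------------------
# ladderize
# ---------------------------------------------------------------------------

class TestLadderize:
    def test_caterpillar_reordered(self):
        t = PhyloTree.from_newick("(a:1,(b:1,(c:1,d:1):1):1);")
        lad = ladderize(t)
        first = lad.skbio_tree.children[0]
        assert not first.is_tip()  # big clade first

    def test_idempotent_on_random_trees(self, rng):
        for _ in range(10):
            labels = [f"t{k}" for k in range(7)]
            t = random_binary_tree(labels, rng)
            once = ladderize(t)
            twice = ladderize(once)
            assert once.to_newick() == twice.to_newick()

    def test_preserves_topology_and_lengths(self, rng):
        t = random_binary_tree([f"t{k}" for k in range(6)], rng)
        lad = ladderize(t)
        assert rf_distance(t, lad) == 0
        assert sorted(lad.branch_lengths()) == pytest.approx(
            sorted(t.branch_lengths())
        )


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def brute_force_rf(t1, t2):
    """Independent split enumeration via dendropy."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(
        data=t1.to_newick(), schema="newick", taxon_namespace=tns
    )
    d2 = dendropy.Tree.get(
        data=t2.to_newick(), schema="newick", taxon_namespace=tns
    )
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestRfDistance:
    def test_identical_topologies_zero(self, rng):
        t = random_binary_tree([f"t{k}" for k in range(6)], rng)
        assert rf_distance(t, t.copy()) == 0

    def test_distinct_quartets(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,B:1,D:1);")
        assert rf_distance(t1, t2) == 2

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(10):
            labels = [f"t{k}" for k in range(6)]
            t1 = random_binary_tree(labels, rng)
            t2 = random_binary_tree(labels, rng)
            assert rf_distance(t1, t2) == brute_force_rf(t1, t2)

    def test_restricts_to_common_leaves(self, rng):
        labels = [f"t{k}" for k in range(8)]
        t1 = random_binary_tree(labels, rng)
        t2 = t1.restricted_to(labels[:6])
        assert rf_distance(t1, t2) == 0

    def test_too_few_shared_leaves(self, rng):
        t1 = random_binary_tree(["a", "b", "c", "d"], rng)
        t2 = random_binary_tree(["a", "b", "x", "y"], rng)
        with pytest.raises(ComparisonError):
            rf_distance(t1, t2)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

class TestNewick:
    def test_simple_round_trip(self):
        t = ml.read_newick("(a:1,b:1);")
        assert sorted(t.leaf_names) == ["a", "b"]
        assert ml.write_newick(t) == "(a:1,b:1);"

    def test_write_read_write_fixpoint(self, rng):
        for _ in range(10):
            t = random_binary_tree([f"t{k}" for k in range(6)], rng)
            s1 = ml.write_newick(t)
            s2 = ml.write_newick(ml.read_newick(s1))
            assert s1 == s2

    def test_six_significant_digits(self):
        t = PhyloTree.from_newick("(a:0.123456789,b:1);")
        assert "0.123457" in ml.write_newick(t)

    def test_labels_with_spaces_quoted(self):
        t = ml.read_newick("('big bird':1,b:1);")
        out = ml.write_newick(t)
        assert "'big bird'" in out
        assert sorted(ml.read_newick(out).leaf_names) == ["b", "big bird"]

    def test_malformed_rejected(self):
        with pytest.raises(NewickParseError):
            ml.read_newick("((a:1,b:2")

    def test_multifurcation_preserved(self):
        t = ml.read_newick("(a:1,b:1,c:1,d:1);")
        assert len(t.skbio_tree.children) == 4
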