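"""p-distance, NJ, cophenetic, consenTRAIT (vs brute force), Mantel."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from fibermeta.synthetic_data import simulate_tree
from fibermeta.trait_phylogenetics import (
    consentrait,
    consentrait_test,
    cophenetic,
    mantel,
    midpoint_root,
    neighbor_joining,
    p_distance,
)


class TestPDistance:
    def test_identical(self):
        dm = p_distance({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert dm["a", "b"] == 0.0

    def test_quarter(self):
        dm = p_distance({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
        assert dm["a", "b"] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        dm = p_distance({"a": "ACNT", "b": "ACGA", "c": "ACGT"})
        assert dm["a", "b"] == pytest.approx(1 / 3)

    def test_no_comparable_positions(self):
        with pytest.raises(ValueError, match="a.*b"):
            p_distance({"a": "NN--", "b": "ACGT", "c": "ACGT"})

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="aligned"):
            p_distance({"a": "ACG", "b": "ACGT", "c": "ACGT"})


class TestNeighborJoining:
    def test_four_taxon_worked_example(self):
        # additive distances from tree (A:1,B:2)|(C:3,D:4) with internal edge 1
        d = DistanceMatrix(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            ids=list("ABCD"),
        )
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        # topology AB|CD: A and B are siblings
        a = tree.find("A")
        assert sorted(t.name for t in a.parent.tips()) == ["A", "B"]
        internal = [
            n.length for n in tree.non_tips(include_self=False)
        ]
        assert internal == pytest.approx([1.0])
        np.testing.assert_allclose(
            cophenetic(tree).filter(d.ids).data, d.data, atol=1e-12
        )

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("XYZ"))
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["X"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["Y"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["Z"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_round_trip(self, seed):
        ref = simulate_tree(12, seed=seed)
        d_ref = cophenetic(ref)
        rebuilt = neighbor_joining(d_ref)
        d_new = cophenetic(rebuilt)
        np.testing.assert_allclose(
            d_new.filter(d_ref.ids).data, d_ref.data, atol=1e-9
        )

    def test_matches_skbio_nj_on_additive_matrix(self):
        from skbio.tree import nj as skbio_nj

        ref = simulate_tree(10, seed=3)
        d_ref = cophenetic(ref)
        ours = cophenetic(neighbor_joining(d_ref)).filter(d_ref.ids)
        theirs = skbio_nj(d_ref).tip_tip_distances().filter(d_ref.ids)
        np.testing.assert_allclose(ours.data, theirs.data, atol=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


class TestCophenetic:
    def test_worked_example(self, balanced_quartet):
        dm = cophenetic(balanced_quartet)
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(4.0)

    def test_ultrametric_root_to_tip(self, balanced_quartet):
        depths = [balanced_quartet.distance(t) for t in balanced_quartet.tips()]
        assert np.ptp(depths) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_four_point_condition(self, seed):
        tree = simulate_tree(8, seed=seed)
        dm = cophenetic(tree)
        ids = list(dm.ids)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            i, j, k, l = rng.choice(len(ids), size=4, replace=False)
            s1 = dm.data[i, j] + dm.data[k, l]
            s2 = dm.data[i, k] + dm.data[j, l]
            s3 = dm.data[i, l] + dm.data[j, k]
            top = sorted([s1, s2, s3])
            assert top[1] == pytest.approx(top[2], abs=1e-9)


class TestConsenTrait:
    def test_cherry_clade(self, balanced_quartet):
        res = consentrait(balanced_quartet, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert res.tau_d == pytest.approx(1.0)
        assert len(res.clades) == 1
        assert res.clades[0].tip_names == ("A", "B")
        assert res.n_singletons == 0

    def test_whole_tree_clade(self, balanced_quartet):
        res = consentrait(balanced_quartet, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert res.tau_d == pytest.approx(2.0)
        assert len(res.clades) == 1
        assert res.clades[0].n_tips == 4

    def test_singleton_half_terminal_branch(self, balanced_quartet):
        trait = {"A": 1, "B": 0, "C": 0, "D": 0}
        res = consentrait(balanced_quartet, trait)
        assert res.tau_d == pytest.approx(0.5)
        assert res.n_singletons == 1 and not res.clades
        res_no = consentrait(balanced_quartet, trait, count_singletons=False)
        assert res_no.tau_d == 0.0

    def test_trait_absent_errors(self, balanced_quartet):
        with pytest.raises(ValueError, match="absent"):
            consentrait(balanced_quartet, {"A": 0, "B": 0, "C": 0, "D": 0})

    def test_invariant_to_tip_order(self):
        tree = simulate_tree(20, seed=1)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(2)
        states = rng.integers(0, 2, size=20)
        if states.sum() == 0:
            states[0] = 1
        trait = dict(zip(tips, states))
        tau1 = consentrait(tree, trait).tau_d
        shuffled_keys = dict(sorted(trait.items(), reverse=True))
        tau2 = consentrait(tree, shuffled_keys).tau_d
        assert tau1 == tau2

    @staticmethod
    def brute_force(tree: TreeNode, trait: dict, cutoff: float, singles: bool):
        """Independent oracle: enumerate every internal node, filter by the
        cutoff, apply the no-qualifying-ancestor maximality rule."""
        internal = list(tree.non_tips(include_self=True))
        qualifying = []
        for node in internal:
            tips = list(node.tips())
            frac = np.mean([trait[t.name] for t in tips])
            if frac >= cutoff:
                qualifying.append(node)
        maximal = [
            n
            for n in qualifying
            if not any(a in qualifying for a in n.ancestors())
        ]
        depths, covered = [], set()
        for node in maximal:
            tip_depths = [node.distance(t) for t in node.tips()]
            depths.append(np.mean(tip_depths))
            covered |= {t.name for t in node.tips()}
        single_depths = [
            (t.length or 0.0) / 2
            for t in tree.tips()
            if trait[t.name] == 1 and t.name not in covered
        ]
        if singles:
            depths += single_depths
        tau = float(np.mean(depths)) if depths else 0.0
        return tau, len(maximal), len(single_depths)

    @pytest.mark.parametrize("count_singletons", [True, False])
    def test_matches_brute_force_enumeration(self, count_singletons):
        tree = simulate_tree(12, seed=9)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(10)
        n_checked = 0
        for _ in range(250):
            states = rng.integers(0, 2, size=12)
            if states.sum() == 0:
                continue
            trait = dict(zip(tips, states))
            res = consentrait(tree, trait, cutoff=0.9, count_singletons=count_singletons)
            tau_bf, n_clades_bf, n_single_bf = self.brute_force(
                tree, trait, 0.9, count_singletons
            )
            assert res.tau_d == pytest.approx(tau_bf, abs=1e-12)
            assert len(res.clades) == n_clades_bf
            assert res.n_singletons == n_single_bf
            n_checked += 1
        assert n_checked > 200


class TestConsenTraitTest:
    def test_conserved_clade_significant(self):
        tree = simulate_tree(64, seed=4)
        # mark one deep clade of >= 6 tips as the trait
        node = next(
            n for n in tree.non_tips() if 6 <= len(list(n.tips())) <= 16
        )
        marked = {t.name for t in node.tips()}
        trait = {t.name: int(t.name in marked) for t in tree.tips()}
        res = consentrait_test(tree, trait, n_permutations=999, seed=5)
        assert res.p_value <= 0.01

    def test_single_permutation_bounds(self, balanced_quartet):
        trait = {"A": 1, "B": 1, "C": 0, "D": 0}
        res = consentrait_test(balanced_quartet, trait, n_permutations=1, seed=0)
        assert res.p_value in (0.5, 1.0)

    def test_all_positive_returns_one(self, balanced_quartet, caplog):
        trait = {"A": 1, "B": 1, "C": 1, "D": 1}
        with caplog.at_level("WARNING"):
            res = consentrait_test(balanced_quartet, trait, n_permutations=10, seed=0)
        assert res.p_value == 1.0

    def test_determinism(self):
        tree = simulate_tree(30, seed=6)
        trait = {t.name: int(k < 6) for k, t in enumerate(tree.tips())}
        r1 = consentrait_test(tree, trait, n_permutations=99, seed=7)
        r2 = consentrait_test(tree, trait, n_permutations=99, seed=7)
        assert r1.p_value == r2.p_value


class TestMantel:
    def _pair(self, seed=0, n=12):
        t1 = simulate_tree(n, seed=seed)
        return cophenetic(t1)

    def test_self_correlation(self):
        d1 = self._pair()
        res = mantel(d1, d1, n_permutations=49, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_rank_reversal(self):
        d1 = self._pair()
        rev_data = d1.data.max() * 1.1 - d1.data
        np.fill_diagonal(rev_data, 0.0)
        res = mantel(d1, DistanceMatrix(rev_data, ids=d1.ids), n_permutations=49, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_id_mismatch(self):
        d1 = self._pair()
        d2 = DistanceMatrix(d1.data, ids=[f"x{k}" for k in range(len(d1.ids))])
        with pytest.raises(ValueError, match="ids"):
            mantel(d1, d2)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(11)
        d1 = self._pair(seed=2)
        noise = rng.normal(0, 0.01, size=d1.data.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d2 = DistanceMatrix(np.abs(d1.data + noise), ids=d1.ids)
        ours = mantel(d1, d2, n_permutations=99, seed=0)
        theirs = skbio_mantel(d1, d2, method="spearman", permutations=0)
        assert ours.r == pytest.approx(float(theirs[0]), abs=1e-9)

    def test_independent_trees_uncorrelated(self):
        # independence requires randomizing the name-to-tip assignment of the
        # second tree: sequential tip naming alone makes neighboring labels
        # phylogenetically close in both trees
        rs, ps = [], []
        rng = np.random.default_rng(123)
        for seed in range(25):
            d1 = cophenetic(simulate_tree(50, seed=seed))
            d2 = cophenetic(simulate_tree(50, seed=seed + 1000))
            relabeled = DistanceMatrix(
                d2.data, ids=list(rng.permutation(list(d2.ids)))
            )
            res = mantel(d1, relabeled, n_permutations=99, seed=seed)
            rs.append(abs(res.r))
            ps.append(res.p_value)
        assert np.median(rs) < 0.3
        assert np.mean(np.asarray(ps) > 0.05) >= 0.8


class TestMidpointRoot:
    def test_longest_path_split(self):
        tree = TreeNode.read(["((A:1,B:4):1,(C:2,D:9):1);"])
        rooted = midpoint_root(tree)
        depths = {t.name: rooted.distance(t) for t in rooted.tips()}
        # longest path B..D = 15; midpoint depth 7.5 from each end
        assert max(depths.values()) == pytest.approx(7.5)
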