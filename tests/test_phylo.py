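import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from fibermeta import (
    read_newick, pairwise_distance, neighbor_joining, root_with_outgroup,
    consentrait_depth, mantel_test, run_conservation, simulate_tree,
    plant_conserved_traits,
)
from fibermeta.io import ValidationError


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        d = pairwise_distance({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert np.allclose(d.data, 0.0)

    def test_one_of_four_sites(self):
        d = pairwise_distance({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
        assert d["a", "b"] == pytest.approx(0.25)

    def test_gap_sites_excluded_pairwise(self):
        d = pairwise_distance({"a": "AC-T", "b": "ACGT", "c": "ACGT"})
        assert d["a", "b"] == pytest.approx(0.0)

    def test_no_comparable_sites_errors(self):
        with pytest.raises(ValidationError, match="comparable"):
            pairwise_distance({"a": "AC--", "b": "--GT", "c": "ACGT"})


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
            ids=["A", "B", "C"],
        )
        t = neighbor_joining(dm)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["A"] == pytest.approx(0.05, abs=1e-12)
        assert lengths["B"] == pytest.approx(0.15, abs=1e-12)
        assert lengths["C"] == pytest.approx(0.25, abs=1e-12)

    def test_additive_distances_recovered_exactly(self):
        for seed in range(10):
            tree = simulate_tree(10, 0.3, seed=seed)
            d = tree.tip_tip_distances()
            nj = neighbor_joining(d)
            assert tree.compare_rfd(nj, rooted=False) == 0
            d2 = nj.tip_tip_distances()
            A = pd.DataFrame(d.data, index=d.ids, columns=d.ids)
            B = pd.DataFrame(d2.data, index=d2.ids, columns=d2.ids)
            B = B.loc[list(d.ids), list(d.ids)]
            assert np.abs(A.to_numpy() - B.to_numpy()).max() < 1e-8

    def test_matches_skbio_nj_topology(self):
        """Cross-check against scikit-bio's independent NJ implementation."""
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(17)
        n = 8
        X = rng.random((n, 4))
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"t{i}" for i in range(n)])
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert ours.compare_rfd(theirs, rooted=False) == 0

    def test_outgroup_rooting_bisects_pendant_edge(self):
        dm = DistanceMatrix(
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
            ids=["A", "B", "C"],
        )
        rooted = root_with_outgroup(neighbor_joining(dm), "C")
        assert len(rooted.children) == 2
        out_tip = rooted.find("C")
        assert out_tip.parent is rooted
        assert out_tip.length == pytest.approx(0.125)  # half of 0.25

    def test_missing_outgroup_errors(self):
        t = read_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        with pytest.raises(ValidationError, match="outgroup"):
            root_with_outgroup(t, "Z")


# ---------------------------------------------------------------------------
# naive recursive consenTRAIT oracle (independent of the packaged version)


def naive_consentrait(tree, trait, cutoff=0.9):
    """Direct recursive re-derivation: returns (tau, clade depths, n_singletons)."""

    def tips_of(node):
        return [t.name for t in node.tips()] if not node.is_tip() else [node.name]

    def mean_depth(node):
        tips = list(node.tips()) if not node.is_tip() else [node]
        total = 0.0
        for t in tips:
            d = 0.0
            x = t
            while x is not node:
                d += x.length or 0.0
                x = x.parent
            total += d
        return total / len(tips)

    qualifying = []
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        tips = tips_of(node)
        npos = sum(trait[t] for t in tips)
        if npos >= 2 and npos / len(tips) >= cutoff:
            qualifying.append(node)
    maximal = []
    for node in qualifying:
        anc = node.parent
        ok = True
        while anc is not None:
            if anc in qualifying:
                ok = False
                break
            anc = anc.parent
        if ok:
            maximal.append(node)
    covered = set()
    depths = []
    for node in maximal:
        depths.append(mean_depth(node))
        covered |= set(tips_of(node))
    singles = [t for t in tree.tips() if trait[t.name] and t.name not in covered]
    for t in singles:
        depths.append((t.length or 0.0) / 2.0)
    tau = float(np.mean(depths)) if depths else 0.0
    return tau, sorted(mean_depth(n) for n in maximal), len(singles)


class TestConsenTrait:
    def test_all_positive_ultrametric_gives_root_height(self):
        t = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        res = consentrait_depth(t, {x: 1 for x in "ABCD"}, n_perm=0)
        assert res.tau_d == pytest.approx(0.2, abs=1e-12)
        assert len(res.clades) == 1

    def test_hand_traversal_two_tip_clade(self):
        t = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        res = consentrait_depth(t, {"A": 1, "B": 1, "C": 0, "D": 0}, n_perm=0)
        assert res.tau_d == pytest.approx(0.1, abs=1e-12)
        assert res.n_singletons == 0
        assert res.clades[0].n_tips == 2

    def test_single_positive_tip_is_half_terminal_edge(self):
        t = read_newick("((A:0.12,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        res = consentrait_depth(t, {"A": 1, "B": 0, "C": 0, "D": 0}, n_perm=0)
        assert res.tau_d == pytest.approx(0.06, abs=1e-12)
        assert res.n_singletons == 1 and not res.clades

    def test_tau_equals_mean_of_reported_depths(self):
        tree = simulate_tree(30, 0.2, seed=3)
        rng = np.random.default_rng(3)
        trait = {t.name: int(rng.random() < 0.4) for t in tree.tips()}
        res = consentrait_depth(tree, trait, n_perm=0)
        depths = [c.depth for c in res.clades] + list(res.singleton_depths)
        assert res.tau_d == pytest.approx(np.mean(depths), abs=1e-12)

    def test_maximality_no_nested_clades(self):
        tree = simulate_tree(40, 0.2, seed=5)
        trait = {t.name: int(i % 2 == 0)
                 for i, t in enumerate(tree.tips())}
        res = consentrait_depth(tree, trait, cutoff=0.6, n_perm=0)
        # structural check via the oracle's maximal set
        _, oracle_depths, _ = naive_consentrait(
            tree, trait, cutoff=0.6)
        assert sorted(c.depth for c in res.clades) == pytest.approx(oracle_depths)

    def test_matches_naive_oracle_on_random_trees(self):
        for seed in range(25):
            tree = simulate_tree(int(5 + seed % 20), 0.25, seed=seed)
            rng = np.random.default_rng(100 + seed)
            trait = {t.name: int(rng.random() < 0.45) for t in tree.tips()}
            if sum(trait.values()) == 0:
                continue
            res = consentrait_depth(tree, trait, n_perm=0)
            tau, depths, nsingle = naive_consentrait(tree, trait)
            assert res.tau_d == pytest.approx(tau, abs=1e-12)
            assert sorted(c.depth for c in res.clades) == pytest.approx(depths)
            assert res.n_singletons == nsingle

    def test_branch_rescaling_scales_tau(self):
        tree = simulate_tree(25, 0.2, seed=9)
        rng = np.random.default_rng(9)
        trait = {t.name: int(rng.random() < 0.5) for t in tree.tips()}
        base = consentrait_depth(tree, trait, n_perm=0).tau_d
        scaled = tree.copy()
        for nd in scaled.traverse(include_self=False):
            nd.length *= 3.0
        assert consentrait_depth(scaled, trait, n_perm=0).tau_d == \
            pytest.approx(3.0 * base, rel=1e-12)

    def test_no_positive_tips_errors(self):
        t = read_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        with pytest.raises(ValidationError, match="positive"):
            consentrait_depth(t, {"A": 0, "B": 0, "C": 0}, n_perm=0)

    def test_low_cutoff_errors(self):
        t = read_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        with pytest.raises(ValueError, match="cutoff"):
            consentrait_depth(t, {"A": 1, "B": 1, "C": 0}, cutoff=0.5)


class TestMantel:
    def _random_dm(self, seed, n=12):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 3))
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])

    def test_self_correlation_is_one(self):
        d = self._random_dm(0)
        r, p = mantel_test(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_rank_invariance_under_monotone_transform(self):
        d = self._random_dm(1)
        d2 = DistanceMatrix(d.data ** 2, ids=d.ids)
        r, _ = mantel_test(d, d2, n_perm=49, seed=0)
        assert r == pytest.approx(1.0)

    def test_label_mismatch_errors(self):
        d1 = self._random_dm(2)
        d2 = DistanceMatrix(d1.data, ids=[f"x{i}" for i in range(12)])
        with pytest.raises(ValidationError):
            mantel_test(d1, d2)


class TestRunConservation:
    def test_planted_traits_recovered_on_pipeline_path(self):
        tree = simulate_tree(120, 0.15, seed=2)
        traits_map, truth = plant_conserved_traits(tree, 2, 2, 0.02, seed=2)

        class Traits:
            positive_otus = {k for k, v in traits_map.items() if v > 0}
            negative_otus = {k for k, v in traits_map.items() if v < 0}

        rep = run_conservation(tree, Traits(), n_perm=199, seed=0)
        assert rep.positive.permutation_p < 0.05
        assert rep.negative.permutation_p < 0.05
        # depths on the sheared tree remain close to the planted depths
        assert rep.positive.tau_d == pytest.approx(
            truth.planted_depth_positive, rel=0.5)

    def test_all_singletons_mean_half_terminal_edge(self):
        t = read_newick(
            "((A:0.1,(B:0.2,C:0.1):0.1):0.1,((D:0.3,E:0.1):0.1,F:0.1):0.1);")
        trait = {"A": 1, "B": 0, "C": 0, "D": 1, "E": 0, "F": 0}
        res = consentrait_depth(t, trait, n_perm=0)
        assert res.n_singletons == 2 and not res.clades
        assert res.tau_d == pytest.approx(np.mean([0.05, 0.15]), abs=1e-12)

    def test_too_few_trait_tips_errors(self):
        tree = simulate_tree(10, 0.2, seed=0)
        tips = [t.name for t in tree.tips()]

        class Traits:
            positive_otus = {tips[0]}
            negative_otus = {tips[1]}

        with pytest.raises(ValidationError, match=">= 3"):
            run_conservation(tree, Traits(), n_perm=9, seed=0)
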