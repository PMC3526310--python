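"""Tree pruning, BLS, branch-length fitting and the selection LRT."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mirtarget import conservation as cv
from mirtarget import simulate as sm

FOUR_TAXON = "((A:1,B:2):1,(C:3,D:4):2);"


def sim_site(tree, model, ncols, rho, rng, ref="s1"):
    root = "".join(rng.choice(list("ACGU"), size=ncols))
    return sm.sim_alignment(tree, root, model, {(0, ncols): rho}, rng, ref=ref)


class TestAlignment:
    def test_ref_site_columns_skip_gaps(self):
        aln = cv.UtrAlignment("hg", {"hg": "AC-GU", "mm": "ACAGU"})
        assert list(aln.ref_site_columns(1, 3)) == [1, 3]

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            cv.UtrAlignment("hg", {"hg": "ACGU", "mm": "ACG"})

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            cv.UtrAlignment("hg", {"mm": "ACGU"})


class TestSpeciesWithSite:
    ALN = cv.UtrAlignment(
        "hg",
        {
            "hg": "AAACGUAAA",
            "mm": "AAACGUAAA",        # identical: found in both modes
            "rn": "ACGUAAAAA",        # shifted: anywhere only
            "bt": "AAACGAAAA",        # substitution: neither
        },
    )

    def test_identical_rows_found_in_both_modes(self):
        for mode in ("anywhere", "same_columns"):
            found, _ = cv.species_with_site(self.ALN, "ACGU", (2, 6), mode)
            assert {"hg", "mm"} <= found

    def test_shifted_site_only_in_anywhere_mode(self):
        anywhere, _ = cv.species_with_site(self.ALN, "ACGU", (2, 6), "anywhere")
        same, _ = cv.species_with_site(self.ALN, "ACGU", (2, 6), "same_columns")
        assert "rn" in anywhere and "rn" not in same

    def test_substitution_excluded_everywhere(self):
        for mode in ("anywhere", "same_columns"):
            found, _ = cv.species_with_site(self.ALN, "ACGU", (2, 6), mode)
            assert "bt" not in found

    def test_position_conservation_fraction(self):
        # of the non-reference species with the motif (mm, rn), only mm
        # keeps it at the reference columns
        frac = cv.position_conservation_fraction(self.ALN, "ACGU", (2, 6))
        assert frac == pytest.approx(0.5)


class TestPruneAndBls:
    def test_keep_all_preserves_length(self):
        t = cv.read_tree(FOUR_TAXON)
        assert cv.total_branch_length(
            cv.prune_tree(t, {"A", "B", "C", "D"})
        ) == pytest.approx(13.0)

    def test_keep_single_leaf_zero_length(self):
        t = cv.read_tree(FOUR_TAXON)
        assert cv.total_branch_length(cv.prune_tree(t, {"A"})) == 0.0

    def test_hand_computed_subset(self):
        t = cv.read_tree(FOUR_TAXON)
        assert cv.total_branch_length(
            cv.prune_tree(t, {"A", "C", "D"})
        ) == pytest.approx(11.0)

    def test_empty_keep_rejected(self):
        with pytest.raises(ValueError):
            cv.prune_tree(cv.read_tree(FOUR_TAXON), set())

    def test_bls_site_everywhere_equals_total_length(self, twelve_leaf_tree):
        species = cv.leaf_labels(twelve_leaf_tree)
        assert cv.bls(species, twelve_leaf_tree) == pytest.approx(
            cv.total_branch_length(twelve_leaf_tree)
        )

    def test_bls_reference_only_is_zero(self, twelve_leaf_tree):
        assert cv.bls({"s1"}, twelve_leaf_tree) == 0.0

    def test_bls_monotone_in_species_set(self, twelve_leaf_tree):
        order = sorted(cv.leaf_labels(twelve_leaf_tree))
        prev = 0.0
        for k in range(1, len(order) + 1):
            score = cv.bls(set(order[:k]), twelve_leaf_tree)
            assert score >= prev - 1e-12
            prev = score

    def test_prune_matches_edge_cut_oracle(self, rng):
        """Induced-subtree length equals summing edges separating kept leaves."""
        import dendropy

        t = cv.read_tree(
            "((A:0.3,(B:0.2,C:0.7):0.15):0.4,((D:0.5,E:0.1):0.25,(F:0.6,(G:0.35,H:0.45):0.05):0.3):0.2);"
        )
        leaves = sorted(cv.leaf_labels(t))
        below = {}
        for nd in t.postorder_node_iter():
            if nd.parent_node is None:
                continue
            if nd.is_leaf():
                below[id(nd)] = {nd.taxon.label}
            else:
                below[id(nd)] = set().union(
                    *[below[id(ch)] for ch in nd.child_nodes()]
                )
        for size in (2, 3, 5, 8):
            for keep in itertools.islice(itertools.combinations(leaves, size), 12):
                keep = set(keep)
                expected = sum(
                    nd.edge.length
                    for nd in t.postorder_node_iter()
                    if nd.parent_node is not None
                    and 0 < len(below[id(nd)] & keep) < len(keep)
                )
                got = cv.total_branch_length(cv.prune_tree(t, keep))
                assert got == pytest.approx(expected, abs=1e-12)


class TestFitBranchLengths:
    def test_two_taxon_jc_matches_closed_form(self):
        rng = np.random.default_rng(0)
        model = cv.SubstModel.jc69()
        tree = cv.read_tree("(A:0.1,B:0.1);")
        aln = sim_site(tree, model, 10_000, 2.0, rng, ref="A")  # rho scales 0.1+0.1
        rows = aln.rows
        p_diff = np.mean([a != b for a, b in zip(rows["A"], rows["B"])])
        jc = -0.75 * np.log(1 - 4 * p_diff / 3)
        fit = cv.fit_branch_lengths(aln, tree, model)
        assert cv.total_branch_length(fit) == pytest.approx(jc, abs=1e-3)

    def test_identical_rows_collapse_to_zero(self):
        aln = cv.UtrAlignment("A", {"A": "ACGU" * 10, "B": "ACGU" * 10})
        with pytest.warns(UserWarning, match="lower bound"):
            fit = cv.fit_branch_lengths(aln, cv.read_tree("(A:0.1,B:0.1);"),
                                        cv.SubstModel.jc69())
        assert cv.total_branch_length(fit) <= 1e-6

    def test_branch_recovery_on_known_tree(self):
        newick = "((A:0.12,B:0.3):0.18,C:0.25,(D:0.4,E:0.08):0.22);"
        tree = cv.read_tree(newick)
        model = cv.SubstModel.hky85()
        rng = np.random.default_rng(5)
        aln = sim_site(tree, model, 10_000, 1.0, rng, ref="A")
        fit = cv.fit_branch_lengths(aln, cv.read_tree(newick), model)
        truth = {
            nd.taxon.label: nd.edge.length
            for nd in tree.leaf_node_iter()
        }
        fitted = {
            nd.taxon.label: nd.edge.length
            for nd in fit.leaf_node_iter()
        }
        for label, t_true in truth.items():
            assert fitted[label] == pytest.approx(t_true, rel=0.15)

    def test_too_few_columns_rejected(self):
        aln = cv.UtrAlignment("A", {"A": "ACGU", "B": "ACGU"})
        with pytest.raises(ValueError, match="non-gap columns"):
            cv.fit_branch_lengths(aln, cv.read_tree("(A:0.1,B:0.1);"))


class TestSelectionTest:
    def test_single_species_is_uninformative(self, twelve_leaf_tree):
        aln = cv.UtrAlignment("s1", {"s1": "ACGUACG"})
        res = cv.selection_test(aln, twelve_leaf_tree)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_short_site_rejected(self, twelve_leaf_tree):
        aln = cv.UtrAlignment("s1", {"s1": "ACGUA", "s2": "ACGUA"})
        with pytest.raises(ValueError):
            cv.selection_test(aln, twelve_leaf_tree)

    def test_statistic_invariant_under_column_permutation(self, twelve_leaf_tree):
        model = cv.SubstModel.hky85()
        rng = np.random.default_rng(9)
        aln = sim_site(twelve_leaf_tree, model, 8, 0.4, rng)
        perm = np.random.default_rng(1).permutation(8)
        shuffled = cv.UtrAlignment(
            aln.ref,
            {sp: "".join(seq[c] for c in perm) for sp, seq in aln.rows.items()},
        )
        r1 = cv.selection_test(aln, twelve_leaf_tree, model)
        r2 = cv.selection_test(shuffled, twelve_leaf_tree, model)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-6)

    def test_conserved_site_beats_neutral_site(self, twelve_leaf_tree):
        model = cv.SubstModel.hky85()
        rng = np.random.default_rng(13)
        neutral = sim_site(twelve_leaf_tree, model, 7, 1.0, rng)
        conserved = cv.UtrAlignment(
            "s1", {sp: "ACGUACG" for sp in neutral.rows}
        )
        r_neutral = cv.selection_test(neutral, twelve_leaf_tree, model)
        r_cons = cv.selection_test(conserved, twelve_leaf_tree, model)
        assert r_cons.rho_hat <= 1e-3
        assert r_cons.neg_log10_p > r_neutral.neg_log10_p

    def test_statistic_non_negative_and_rho_bounded(self, twelve_leaf_tree):
        model = cv.SubstModel.hky85()
        rng = np.random.default_rng(17)
        for _ in range(10):
            aln = sim_site(twelve_leaf_tree, model, 7, float(rng.uniform(0.1, 1.0)), rng)
            res = cv.selection_test(aln, twelve_leaf_tree, model)
            assert res.statistic >= 0.0
            assert 0 < res.rho_hat <= 1.0


class TestPhastconsMean:
    def test_full_coverage_all_ones(self):
        mean, cov = cv.phastcons_mean(np.ones(10), (2, 9))
        assert mean == 1.0 and cov == 1.0

    def test_hand_arithmetic(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8, 1.0, 0.0, 0.5])
        mean, cov = cv.phastcons_mean(scores, (0, 7))
        assert mean == pytest.approx(0.5)

    def test_partial_coverage(self):
        scores = np.array([0.4, np.nan, 0.8, np.nan])
        mean, cov = cv.phastcons_mean(scores, (0, 4))
        assert mean == pytest.approx(0.6)
        assert cov == pytest.approx(0.5)

    def test_no_coverage_returns_absent(self):
        mean, cov = cv.phastcons_mean(np.full(5, np.nan), (0, 5))
        assert mean is None and cov == 0.0
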