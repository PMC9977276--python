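"""Marginal ancestral reconstruction: oracle equivalence, MAP extraction,
gap parsimony, calibration-flavored sanity checks."""

import numpy as np
import pytest

from ancseq.alignment import ProteinAlignment
from ancseq.alphabet import AA_INDEX, AMINO_ACIDS
from ancseq.asr import (
    AncestralReconstructionModel,
    extract_map_ancestor,
    infer_gap_mask,
    infer_gap_masks_all,
    marginal_posteriors,
)
from ancseq.likelihood import PruningEngine
from ancseq.substitution import get_model
from ancseq.synthetic import simulate_evolution, simulate_tree
from ancseq.tree import PhyloTree

from conftest import brute_force_likelihood_and_posteriors, random_instance


class TestMarginalPosteriors:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        tree, model, aln = random_instance(100 + seed, 4, 3, 2)
        _, expected = brute_force_likelihood_and_posteriors(tree, model, aln)
        engine = PruningEngine(tree, model, aln)
        for nid in tree.internal_ids:
            got = engine.expand_to_sites(engine.node_posteriors_patterns(nid))
            assert np.abs(got - expected[nid]).max() < 1e-8

    def test_rows_normalized(self, small_simulation):
        truth = small_simulation
        model = AncestralReconstructionModel(
            truth.alignment, truth.tree, truth.model, use_empirical_frequencies=False
        )
        res = model.fit(fit_alpha=False)
        post = res.posteriors(truth.tree.root)
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-9

    def test_zero_branches_identical_column_gives_delta(self):
        model = get_model("LG", gamma_shape=None)
        tree = PhyloTree.from_newick("((A:0,B:0):0,C:0);")
        aln = ProteinAlignment(["A", "B", "C"], ["W", "W", "W"])
        for nid in tree.internal_ids:
            post = marginal_posteriors(tree, model, aln, nid)
            assert post[0, AA_INDEX["W"]] == pytest.approx(1.0, abs=1e-12)

    def test_leaf_query_returns_observed_state(self, lg_model):
        tree = PhyloTree.from_newick("((A:0.2,B:0.4):0.1,C:0.3);")
        aln = ProteinAlignment(["A", "B", "C"], ["KX", "EE", "D-"])
        ka = [k for k in tree.leaf_ids if tree.labels[k] == "A"][0]
        post = marginal_posteriors(tree, lg_model, aln, ka)
        assert post[0, AA_INDEX["K"]] == 1.0
        assert np.allclose(post[1], 0.05)  # 'X': uniform over residues

    def test_rerooting_leaves_nonroot_posteriors_unchanged(self, lg_model):
        tree = simulate_tree(8, 0.7, seed=55)
        truth = simulate_evolution(tree, lg_model, 40, seed=56)
        engine = PruningEngine(tree, lg_model, truth.alignment)
        target = tree.mrca(sorted(tree.leaf_set(tree.internal_ids[0])))
        want = engine.expand_to_sites(engine.node_posteriors_patterns(target))
        leafset = tree.leaf_set(target)
        # reroot on an edge outside the target clade
        outside = [
            k
            for k in range(tree.n_nodes - 1)
            if not (tree.leaf_set(k) & leafset) and tree.parent[k] != tree.root
        ]
        rerooted = tree.reroot_at_edge(outside[0], fraction=0.4)
        engine2 = PruningEngine(rerooted, lg_model, truth.alignment)
        target2 = rerooted.mrca(sorted(leafset))
        got = engine2.expand_to_sites(engine2.node_posteriors_patterns(target2))
        assert np.abs(got - want).max() < 1e-8


class TestMapExtraction:
    def test_simple_map_site(self):
        row = np.full(20, 0.05 / 19)
        row[AA_INDEX["V"]] = 0.95
        row /= row.sum()
        rec = extract_map_ancestor(row[None, :])
        assert rec.map_sequence == "V"
        assert rec.site_pp[0] == pytest.approx(row[AA_INDEX["V"]])
        assert not rec.tie_mask[0]

    def test_exact_tie_breaks_alphabetically_and_flags(self):
        row = np.zeros(20)
        row[AA_INDEX["A"]] = 0.4
        row[AA_INDEX["C"]] = 0.4
        row[AA_INDEX["W"]] = 0.2
        rec = extract_map_ancestor(row[None, :])
        assert rec.map_sequence == "A"
        assert rec.tie_mask[0]
        assert rec.n_tied_sites == 1

    def test_gap_mask_excluded_from_mean_pp(self):
        rows = np.tile(np.eye(20)[AA_INDEX["K"]], (4, 1))
        rows[1] = np.full(20, 0.05)
        mask = np.array([False, True, False, False])
        rec = extract_map_ancestor(rows, mask)
        assert rec.map_sequence[1] == "-"
        assert rec.mean_pp == pytest.approx(1.0)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            extract_map_ancestor(np.ones((2, 20)))

    def test_map_accuracy_improves_on_shallower_trees(self, lg_model):
        accs = []
        for depth in [1.0, 0.5, 0.1]:
            hits = total = 0
            for rep in range(5):
                tree = simulate_tree(12, depth, seed=900 + rep)
                truth = simulate_evolution(tree, lg_model, 60, seed=950 + rep)
                res = AncestralReconstructionModel(
                    truth.alignment, truth.tree, lg_model, use_empirical_frequencies=False
                ).fit(fit_alpha=False)
                rec = res.reconstruct(tree.root)
                true_seq = truth.true_sequence(tree.root)
                hits += sum(a == b for a, b in zip(rec.map_sequence, true_seq))
                total += len(true_seq)
            accs.append(hits / total)
        assert accs[0] < accs[1] < accs[2]


class TestGapParsimony:
    def test_ungapped_column_all_false(self, lg_model):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        aln = ProteinAlignment(["A", "B", "C"], ["K", "K", "K"])
        masks = infer_gap_masks_all(tree, aln)
        assert not masks.any()

    def test_fully_gapped_column_all_true(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        aln = ProteinAlignment(["A", "B", "C"], ["-", "-", "-"])
        masks = infer_gap_masks_all(tree, aln)
        for nid in tree.internal_ids:
            assert masks[nid, 0]

    def test_x_counts_as_residue_not_gap(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        aln = ProteinAlignment(["A", "B", "C"], ["X", "-", "-"])
        masks = infer_gap_masks_all(tree, aln)
        # Fitch: AB node is {gap, residue}, C is {gap}; the root intersects
        # to {gap} unambiguously (the single change sits on A's edge), and
        # the X leaf itself is never gapped
        assert masks[tree.root, 0]
        ka = [k for k in tree.leaf_ids if tree.labels[k] == "A"][0]
        assert not masks[ka, 0]

    def test_hand_run_fitch_on_six_leaf_clade(self, lg_model):
        # gap confined to the (D,E,F) clade: internal nodes of that clade
        # are gapped, all other internals are not
        nwk = "(((A:1,B:1):1,C:1):1,((D:1,E:1):1,F:1):1);"
        tree = PhyloTree.from_newick(nwk)
        rows = {"A": "K", "B": "K", "C": "K", "D": "-", "E": "-", "F": "-"}
        aln = ProteinAlignment(list(rows), list(rows.values()))
        masks = infer_gap_masks_all(tree, aln)
        de = tree.mrca(["D", "E"])
        def_ = tree.mrca(["D", "E", "F"])
        ab = tree.mrca(["A", "B"])
        abc = tree.mrca(["A", "B", "C"])
        assert masks[de, 0] and masks[def_, 0]
        assert not masks[ab, 0] and not masks[abc, 0]
        # root is ambiguous ({gap} vs {residue} union) -> residue
        assert not masks[tree.root, 0]
        assert infer_gap_mask(tree, aln, de)[0]


class TestResultsObject:
    def test_summary_and_reconstruction_consistency(self, small_simulation):
        truth = small_simulation
        res = AncestralReconstructionModel(
            truth.alignment, truth.tree, truth.model
        ).fit(fit_alpha=False)
        summ = res.summary([truth.tree.root])
        rec = res.reconstruct(truth.tree.root)
        assert summ.loc[0, "mean_pp"] == pytest.approx(rec.mean_pp)
        assert summ.loc[0, "n_descendants"] == truth.tree.n_leaves
        assert 1 / 20 <= rec.mean_pp <= 1.0

    def test_posterior_table_roundtrip(self, tmp_path, small_simulation):
        truth = small_simulation
        res = AncestralReconstructionModel(
            truth.alignment, truth.tree, truth.model
        ).fit(fit_alpha=False)
        rec = res.reconstruct(truth.tree.root)
        out = tmp_path / "post.tsv"
        rec.to_tsv(out)
        import pandas as pd

        df = pd.read_csv(out, sep="\t")
        assert list(df.columns[:1]) == ["site"]
        assert len(df) == truth.alignment.length
        assert (df["pp"] <= 1.0).all()
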