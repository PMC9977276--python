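"""Design layer: identity, substitution mapping, conservation grading,
codon optimization."""

import numpy as np
import pytest
from scipy.stats import chisquare

from ancseq.alignment import ProteinAlignment
from ancseq.resurrection import (
    CodonUsageTable,
    codon_optimize,
    conservation_grades,
    identity_matrix,
    map_substitutions,
    pairwise_identity,
    translate_cds,
)
from ancseq.substitution import get_model
from ancseq.synthetic import simulate_codon_case, simulate_evolution, simulate_tree
from ancseq.tree import PhyloTree


@pytest.fixture(scope="module")
def usage():
    # skewed synthetic usage to make weighting visible
    rng = np.random.default_rng(5)
    from ancseq.resurrection import _SENSE_CODONS

    return CodonUsageTable({c: float(rng.uniform(0.1, 10.0)) for c in _SENSE_CODONS})


class TestIdentity:
    def test_identical_sequences_are_100(self):
        aln = ProteinAlignment(["a", "b"], ["MKLV", "MKLV"])
        assert pairwise_identity(aln, "a", "b") == 100.0

    def test_simple_arithmetic(self):
        aln = ProteinAlignment(["a", "b"], ["KKKKKKKKKV", "KKKKKKKKKI"])
        assert pairwise_identity(aln, "a", "b") == pytest.approx(90.0)

    def test_mutual_residue_denominator_ignores_gaps(self):
        # differ only where one side is gapped: identity stays 100
        a = "MK-LVDE--QWE"
        b = "MKALV-EPPQWE"
        aln = ProteinAlignment(["a", "b"], [a, b])
        assert pairwise_identity(aln, "a", "b") == pytest.approx(100.0)

    def test_disjoint_coverage_is_nan(self):
        aln = ProteinAlignment(["a", "b"], ["MK--", "--LV"])
        assert np.isnan(pairwise_identity(aln, "a", "b"))

    def test_matrix_symmetric_unit_diagonal(self):
        aln = ProteinAlignment(["a", "b", "c"], ["MKLV", "MKIV", "MALV"])
        M = identity_matrix(aln)
        assert np.allclose(np.diag(M.to_numpy()), 100.0)
        assert np.allclose(M.to_numpy(), M.to_numpy().T)


class TestSubstitutionMap:
    def test_identical_gives_empty_map(self):
        aln = ProteinAlignment(["wt"], ["MKLV"])
        m = map_substitutions("MKLV", "wt", aln)
        assert m.entries == [] and m.insertions == [] and m.deletions == []

    def test_hand_mapped_toy_with_insertion(self):
        aln = ProteinAlignment(["wt"], ["MK-LV"])
        m = map_substitutions("MKALI", "wt", aln)
        assert m.labels == ["V4I"]
        assert m.entries[0].alignment_column == 5
        assert m.insertions == [3]
        assert m.deletions == []

    def test_deletion_reported_separately(self):
        aln = ProteinAlignment(["wt"], ["MKLV"])
        m = map_substitutions("M-LV", "wt", aln)
        assert m.labels == []
        assert m.deletions == [2]

    def test_roundtrip_column_recovery(self):
        rng = np.random.default_rng(8)
        ref = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        anc = list(ref)
        flips = rng.choice(len(ref), size=6, replace=False)
        for f in flips:
            anc[f] = "W" if ref[f] != "W" else "Y"
        aln = ProteinAlignment(["wt"], [ref])
        m = map_substitutions("".join(anc), "wt", aln)
        for e in m.entries:
            col = e.alignment_column - 1
            assert ref[col] == e.reference_residue
            assert anc[col] == e.ancestral_residue
        assert [e.alignment_column - 1 for e in m.entries] == sorted(flips)

    def test_length_mismatch_rejected(self):
        aln = ProteinAlignment(["wt"], ["MKLV"])
        with pytest.raises(ValueError, match="length"):
            map_substitutions("MKL", "wt", aln)


class TestConservation:
    def test_invariant_sites_graded_most_conserved(self, lg_model):
        # a few invariant sites among scrambled ones across 50 leaves: the
        # invariant sites must occupy the slowest percentile bin (grade 9)
        tree = simulate_tree(50, 1.5, seed=61)
        rng = np.random.default_rng(62)
        n_slow, n_fast = 8, 82
        from ancseq.alphabet import AMINO_ACIDS

        rows = []
        for _ in range(tree.n_leaves):
            fast = "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, n_fast))
            rows.append("K" * n_slow + fast)
        aln = ProteinAlignment([tree.labels[k] for k in tree.leaf_ids], rows)
        profile = conservation_grades(tree, lg_model, aln)
        assert (profile.grades[:n_slow] == 9).all()
        assert profile.conserved[:n_slow].all()
        # scrambled sites are much faster than invariant ones
        assert profile.site_rates[n_slow:].min() > profile.site_rates[:n_slow].max()

    def test_grades_partition_evenly(self, small_simulation):
        truth = small_simulation
        profile = conservation_grades(truth.tree, truth.model, truth.alignment)
        counts = np.bincount(profile.grades, minlength=10)[1:]
        L = truth.alignment.length
        assert counts.min() >= L // 9 - 1 and counts.max() <= L // 9 + 2

    def test_rate_grade_monotone(self, small_simulation):
        truth = small_simulation
        p = conservation_grades(truth.tree, truth.model, truth.alignment)
        order = np.argsort(p.site_rates, kind="stable")
        g = p.grades[order]
        assert (np.diff(g.astype(int)) <= 0).all()

    def test_few_sites_warns(self, lg_model):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        aln = ProteinAlignment(["A", "B", "C"], ["KKW", "KAW", "KAW"])
        with pytest.warns(UserWarning, match="coarse"):
            conservation_grades(tree, lg_model, aln)


class TestCodonUsage:
    def test_per_aa_weights_normalized(self, usage):
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            codons, w = usage.synonymous_weights(aa)
            assert abs(w.sum() - 1.0) < 1e-12
            assert all(translate_cds(c) == aa for c in codons)

    def test_rna_codons_and_per_thousand_accepted(self, tmp_path):
        p = tmp_path / "usage.tsv"
        p.write_text("# codon usage\nUUU 17.6\nUUC 20.3\n" + "\n".join(
            f"{c} 1.0" for c in sorted(
                set(__import__('ancseq.resurrection', fromlist=['x'])._SENSE_CODONS)
                - {"TTT", "TTC"}
            )
        ) + "\n")
        table = CodonUsageTable.from_tsv(p)
        codons, w = table.synonymous_weights("F")
        assert codons == ["TTC", "TTT"]
        assert w[0] == pytest.approx(20.3 / 37.9)

    def test_missing_family_rejected(self):
        with pytest.raises(ValueError, match="no positive-weight"):
            CodonUsageTable({"ATG": 1.0})  # only Met covered


class TestCodonOptimize:
    def test_identical_proteins_reproduce_wt_cds(self, usage):
        case = simulate_codon_case(120, 0.0, usage, seed=9)
        gene = codon_optimize(
            case.ancestral_protein, case.reference_protein, case.reference_cds,
            usage, seed=1,
        )
        assert gene.nucleotide_sequence == case.reference_cds
        assert all(p == "copied" for p in gene.provenance)

    def test_translation_always_matches_ancestor(self, usage):
        for seed in range(10):
            case = simulate_codon_case(80, 0.15, usage, seed=seed)
            gene = codon_optimize(
                case.ancestral_protein, case.reference_protein, case.reference_cds,
                usage, seed=seed,
            )
            assert gene.translation == case.ancestral_protein

    def test_same_seed_same_gene(self, usage):
        case = simulate_codon_case(60, 0.2, usage, seed=3)
        args = (case.ancestral_protein, case.reference_protein, case.reference_cds, usage)
        assert codon_optimize(*args, seed=7).nucleotide_sequence == \
            codon_optimize(*args, seed=7).nucleotide_sequence
        assert codon_optimize(*args, seed=7).nucleotide_sequence != \
            codon_optimize(*args, seed=8).nucleotide_sequence

    def test_indels_and_stop_handling(self, usage):
        ref_aln = "MK-LV"
        anc_aln = "MKA-V"
        cds = "ATGAAACTGGTGTAA"  # MKLV + stop
        gene = codon_optimize(anc_aln, ref_aln, cds, usage, seed=1)
        assert gene.translation == "MKAV"
        assert gene.stop_codon == "TAA"
        assert gene.provenance == ["copied", "copied", "inserted", "copied"]
        assert gene.full_sequence.endswith("TAA")
        # copied codons are verbatim WT
        assert gene.nucleotide_sequence[:6] == "ATGAAA"
        assert gene.nucleotide_sequence[-3:] == "GTG"

    def test_mismatched_cds_rejected(self, usage):
        with pytest.raises(ValueError, match="codon 2"):
            codon_optimize("MKLV", "MKLV", "ATGTTTCTGGTG", usage, seed=1)

    def test_sampled_codons_follow_usage_weights(self, usage):
        # one differing site (ancestral L); sampled codon frequencies must
        # match the six leucine weights by chi-square GOF
        codons, w = usage.synonymous_weights("L")
        counts = {c: 0 for c in codons}
        n = 10000
        for seed in range(n):
            gene = codon_optimize("L", "V", "GTG", usage, seed=seed)
            counts[gene.nucleotide_sequence] += 1
        obs = np.array([counts[c] for c in codons])
        stat, p = chisquare(obs, f_exp=w * n)
        assert p > 0.01

    def test_copied_positions_maximize_wt_identity(self, usage):
        case = simulate_codon_case(50, 0.1, usage, seed=21)
        gene = codon_optimize(
            case.ancestral_protein, case.reference_protein, case.reference_cds,
            usage, seed=2,
        )
        for i, prov in enumerate(gene.provenance):
            codon = gene.nucleotide_sequence[3 * i : 3 * i + 3]
            wt = case.reference_cds[3 * i : 3 * i + 3]
            if prov == "copied":
                assert codon == wt  # flipping any copied codon lowers identity

    def test_tag_cassette_prepended(self, usage):
        gene = codon_optimize("MK", "MK", "ATGAAA", usage, seed=1, tag_cassette="GCTAGC")
        assert gene.nucleotide_sequence.startswith("GCTAGC")
        assert gene.provenance[:2] == ["tag", "tag"]
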