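"""Secondary-structure parsing, max-pairing fold, effective distances, rescues."""

import itertools

import pytest

from bp3scan import (
    FoldConfig,
    IntronRecord,
    StructureError,
    annotate_intron,
    apply_substitutions,
    compensatory_mutations,
    effective_distance,
    fold_and_measure,
    nussinov_fold,
    parse_dotbracket,
)
from bp3scan.structure_bridge import read_vienna
from conftest import bfs_distance_oracle, brute_max_pairs, random_rna


class TestParseDotbracket:
    def test_simple_hairpin_pairs(self):
        structure = parse_dotbracket("GGGAAAACCC", "(((....)))")
        assert structure.pairs == ((1, 10), (2, 9), (3, 8))
        assert structure.n_pairs == 3

    def test_unpaired_chain(self):
        structure = parse_dotbracket("AAAA", "....")
        assert structure.pairs == ()

    def test_pair_table_symmetry(self):
        structure = parse_dotbracket("GGGAAAACCC", "(((....)))")
        for i, j in structure.pairs:
            assert structure.pair_table[j] == i

    @pytest.mark.parametrize("sequence, dotbracket, pattern", [
        ("GC", "()", "hairpin"),                 # loop shorter than min_loop
        ("GGGAAAACCC", "(((....))", "length"),   # length mismatch
        ("AGGAAAACCC", "(((....)))", "disallowed"),  # A-C pair
        ("GAAAAC", ")....(", "unbalanced"),
        ("GAAAAC", "(.....", "unbalanced"),
        ("GAAAAC", "(..x.)", "invalid"),
    ])
    def test_invalid_structures_rejected(self, sequence, dotbracket, pattern):
        with pytest.raises(StructureError, match=pattern):
            parse_dotbracket(sequence, dotbracket)

    def test_vienna_two_line_format(self, tmp_path):
        path = tmp_path / "s.fold"
        path.write_text(">seg\nGGGAAAACCC\n(((....))) (-1.20)\n")
        sequence, dotbracket = read_vienna(str(path))
        assert (sequence, dotbracket) == ("GGGAAAACCC", "(((....)))")


class TestNussinovFold:
    def test_full_hairpin(self):
        structure = nussinov_fold("GGGAAAACCC")
        assert structure.n_pairs == 3

    def test_loop_constraint_forbids_short_range_pairs(self):
        assert nussinov_fold("GCGC").n_pairs == 0

    def test_deterministic_dotbracket(self):
        seq = "GGCGAAAUUCGCCAUGC"
        assert nussinov_fold(seq).dotbracket == nussinov_fold(seq).dotbracket

    def test_n_never_pairs(self):
        structure = nussinov_fold("NNNAAAANNN")
        assert structure.n_pairs == 0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            seq = random_rna(rng, int(rng.integers(1, 13)))
            assert nussinov_fold(seq).n_pairs == brute_max_pairs(seq)

    def test_matches_enumeration_with_other_min_loop(self, rng):
        config = FoldConfig(min_loop=1)
        for _ in range(50):
            seq = random_rna(rng, int(rng.integers(1, 11)))
            assert nussinov_fold(seq, config).n_pairs == brute_max_pairs(seq, 1)


class TestEffectiveDistance:
    def test_unpaired_chain_uses_backbone(self):
        structure = parse_dotbracket("A" * 10, "." * 10)
        assert effective_distance(structure, 1, 10) == 9

    def test_direct_pair_edge(self):
        structure = parse_dotbracket("GGGAAAACCC", "(((....)))")
        assert effective_distance(structure, 1, 10) == 1

    def test_long_hairpin_fixture_matches_bfs(self):
        sequence = "GGG" + "A" * 14 + "CCC"
        dotbracket = "(((" + "." * 14 + ")))"
        structure = parse_dotbracket(sequence, dotbracket)
        assert effective_distance(structure, 1, 20) == 1
        assert effective_distance(structure, 1, 20) == \
            bfs_distance_oracle(structure.pair_table, 1, 20)

    def test_matches_bfs_oracle_on_random_folds(self, rng):
        for _ in range(60):
            seq = random_rna(rng, int(rng.integers(5, 31)))
            structure = nussinov_fold(seq)
            n = len(seq)
            i = int(rng.integers(1, n + 1))
            j = int(rng.integers(1, n + 1))
            assert effective_distance(structure, i, j) == \
                bfs_distance_oracle(structure.pair_table, i, j)

    def test_metric_properties_on_fixture(self):
        structure = nussinov_fold("GGCGAAAUUCGCCAUGCAAGGGC")
        n = len(structure)
        for i, j in itertools.combinations(range(1, n + 1), 2):
            dij = effective_distance(structure, i, j)
            assert dij == effective_distance(structure, j, i)
            assert effective_distance(structure, i, i) == 0
        for i, j, k in [(1, 10, 20), (2, 5, 18), (1, 12, 23)]:
            assert effective_distance(structure, i, k) <= \
                effective_distance(structure, i, j) + \
                effective_distance(structure, j, k)

    def test_out_of_range_positions_rejected(self):
        structure = parse_dotbracket("AAAA", "....")
        with pytest.raises(ValueError):
            effective_distance(structure, 0, 3)


class TestCompensatoryMutations:
    HAIRPIN = parse_dotbracket("GGGAAAACCC", "(((....)))")

    def test_gc_pair_broken_by_g_to_a(self):
        # pair (1, 10) is G-C; G->A breaks it; A-U is the WC restoration
        proposals = compensatory_mutations(self.HAIRPIN, {1: "A"})
        assert proposals == {10: "U"}

    def test_au_pair_broken_by_a_to_g_prefers_wc_over_wobble(self):
        structure = parse_dotbracket("AGGAAAACCU", "(((....)))")
        proposals = compensatory_mutations(structure, {1: "G"})
        assert proposals == {10: "C"}  # G-U wobble rejected in favour of G-C

    def test_loop_substitution_yields_no_proposal(self):
        assert compensatory_mutations(self.HAIRPIN, {5: "G"}) == {}

    def test_wobble_after_substitution_still_draws_wc_proposal(self):
        # substituting C10 -> U leaves a valid G-U wobble, but the WC
        # restoration G1 -> A is still proposed
        assert compensatory_mutations(self.HAIRPIN, {10: "U"}) == {1: "A"}

    def test_jointly_substituted_wc_pair_needs_no_rescue(self):
        # both partners substituted to a fresh WC pair: nothing to restore
        assert compensatory_mutations(self.HAIRPIN, {1: "A", 10: "U"}) == {}

    def test_rescue_never_loses_original_pairs(self, rng):
        # weaken then rescue: refolding the rescued sequence pairs at least
        # as many bases as the original structure did
        for _ in range(30):
            seq = random_rna(rng, int(rng.integers(12, 26)))
            structure = nussinov_fold(seq)
            if structure.n_pairs == 0:
                continue
            i, _ = structure.pairs[0]
            current = seq[i - 1]
            new_base = {"A": "C", "C": "A", "G": "A", "U": "C"}[current]
            broken = apply_substitutions(seq, {i: new_base})
            rescue = compensatory_mutations(structure, {i: new_base})
            rescued = apply_substitutions(broken, rescue)
            assert nussinov_fold(rescued).n_pairs >= structure.n_pairs


class TestFoldAndMeasure:
    def intron(self, sequence):
        record = IntronRecord("x.1", "g", 1, "c", 1, len(sequence), "+", sequence)
        return record, annotate_intron(record)

    def test_unpaired_segment_reproduces_linear_distance(self):
        # segment letters {A, C, G-at-end only} admit no pair under min_loop 3
        seq = "GUAAGU" + "GGGG" + "CUAAA" + "A" * 12 + "CAG"
        record, annotation = self.intron(seq)
        report = fold_and_measure(record, annotation)
        assert report.linear_d3 == annotation.d3
        assert report.effective_d3 == report.linear_d3
        assert report.n_pairs == 0

    def test_hairpin_shortens_effective_distance(self):
        # stem between BP and 3'ss: GGGGGG....CCCCCC folds into a hairpin
        seq = "GUAAGU" + "AAAA" + "CUAAC" + "GGGGGGG" + "AAAA" + "CCCCCCC" + "CUAG"
        record, annotation = self.intron(seq)
        report = fold_and_measure(record, annotation)
        assert report.n_pairs > 0
        assert report.effective_d3 < report.linear_d3

    def test_effective_never_exceeds_linear(self, rng):
        from bp3scan import SimulationParams, simulate_dataset
        dataset = simulate_dataset(SimulationParams(n_dependent=15,
                                                    n_independent=15, seed=3))
        for intron in dataset.introns:
            annotation = annotate_intron(intron)
            report = fold_and_measure(intron, annotation)
            assert report.effective_d3 <= report.linear_d3

    def test_external_dotbracket_source(self):
        seq = "GUAAGU" + "GGGG" + "CUAAC" + "A" * 20 + "UAG"
        record, annotation = self.intron(seq)
        segment_len = len(seq) - annotation.selected_bp.branch_pos + 1
        report = fold_and_measure(record, annotation, "dotbracket-file",
                                  dotbracket="." * segment_len)
        assert report.effective_d3 == report.linear_d3

    def test_missing_branchpoint_is_error(self):
        record, annotation = self.intron("GUGGGGGGGGGGAG")
        with pytest.raises(ValueError, match="branchpoint"):
            fold_and_measure(record, annotation)
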