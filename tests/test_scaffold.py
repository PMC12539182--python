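import itertools
import random

import pytest

from obpcur.scaffold import (DEFAULT_CLASSIFIER, ClassifierConfig,
                             classify_scaffold, cysteine_positions,
                             find_classical_motifs, is_obp_candidate)
from obpcur.seqio import SequenceRecord
from obpcur.sigpep import SignalPeptideCall
from obpcur.synthetic import generate_scaffold, mutate_to_identity
from tests.conftest import random_protein, sequence_with_cysteines

CFG = DEFAULT_CLASSIFIER


def exhaustive_motifs(seq, cfg=CFG):
    """Independent oracle: check every 6-subset of cysteines, then apply
    the same leftmost-first greedy selection."""
    cys = cysteine_positions(seq)
    tol = cfg.gap_tolerance

    def ok(t):
        g = [t[i + 1] - t[i] - 1 for i in range(5)]
        return (cfg.c1_c2_window[0] <= g[0] <= cfg.c1_c2_window[1]
                and abs(g[1] - cfg.c2_c3_gap) <= tol
                and cfg.c3_c4_window[0] <= g[2] <= cfg.c3_c4_window[1]
                and cfg.c4_c5_window[0] <= g[3] <= cfg.c4_c5_window[1]
                and abs(g[4] - cfg.c5_c6_gap) <= tol)

    candidates = sorted(t for t in itertools.combinations(cys, 6) if ok(t))
    chosen, used = [], set()
    for t in candidates:
        if used.isdisjoint(t):
            chosen.append(t)
            used.update(t)
    return chosen


class TestFindMotifs:
    def test_hallmark_spacing_example(self):
        positions = (22, 50, 54, 95, 107, 116)
        seq = sequence_with_cysteines(positions, 140)
        assert find_classical_motifs(seq) == [positions]

    def test_cysteine_free_sequence(self):
        assert find_classical_motifs("A" * 150) == []

    def test_two_blocks_with_linker_give_two_motifs(self):
        block = sequence_with_cysteines((5, 25, 29, 55, 62, 71), 80)
        seq = block + "G" * 15 + block
        motifs = find_classical_motifs(seq)
        assert len(motifs) == 2
        assert motifs == exhaustive_motifs(seq)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        """Sequences with up to 12 cysteines, random and scaffold-derived."""
        rng = random.Random(seed)
        if seed % 3 == 0:
            n_cys = rng.randint(0, 12)
            length = rng.randint(80, 300)
            pos = sorted(rng.sample(range(1, length + 1), n_cys))
            seq = sequence_with_cysteines(pos, length)
        else:
            fam = rng.choice(["Classical", "Plus-C", "Minus-C", "Atypical"])
            seq = generate_scaffold(fam, rng=rng)
        assert find_classical_motifs(seq) == exhaustive_motifs(seq)


class TestClassify:
    def test_plus_c_template_counts_ten_conserved_cysteines(self):
        sc = classify_scaffold(generate_scaffold("Plus-C", seed=1))
        assert sc.subfamily == "Plus-C"
        assert sc.conserved_cysteine_count == 10
        assert sc.proline_after_c6

    def test_minus_c_template_counts_four(self):
        sc = classify_scaffold(generate_scaffold("Minus-C", seed=1))
        assert sc.subfamily == "Minus-C"
        assert sc.conserved_cysteine_count == 4

    def test_two_domains_are_atypical(self):
        sc = classify_scaffold(generate_scaffold("Atypical", seed=1))
        assert sc.subfamily == "Atypical"
        assert sc.motif_count == 2

    def test_gap_violation_is_unclassified_at_zero_tolerance(self):
        # C2-C3 gap of 8 instead of 3
        seq = sequence_with_cysteines((22, 50, 59, 95, 107, 116), 140)
        assert classify_scaffold(seq).subfamily == "Unclassified"
        relaxed = ClassifierConfig(gap_tolerance=5)
        assert classify_scaffold(seq, relaxed).subfamily == "Classical"

    def test_non_protein_alphabet_rejected(self):
        with pytest.raises(ValueError, match="non-protein"):
            classify_scaffold("ACGT1")

    def test_deleting_c2_and_c5_from_classical_gives_minus_c(self):
        for seed in range(10):
            seq = generate_scaffold("Classical", seed=seed)
            sc = classify_scaffold(seq)
            assert sc.subfamily == "Classical"
            c = sc.motif_positions[0]
            out = list(seq)
            out[c[1] - 1] = "A"
            out[c[4] - 1] = "A"
            assert classify_scaffold("".join(out)).subfamily == "Minus-C"

    def test_adding_extras_and_proline_to_classical_gives_plus_c(self):
        for seed in range(10):
            seq = generate_scaffold("Classical", seed=seed)
            sc = classify_scaffold(seq)
            c6 = sc.motif_positions[0][5]
            out = list("AGCCAG" + seq)       # two extra N-terminal cysteines
            out[c6 + 6] = "P"                # directly after (shifted) C6
            got = classify_scaffold("".join(out))
            assert got.subfamily == "Plus-C"
            assert got.conserved_cysteine_count >= 8

    def test_concatenating_two_classicals_gives_atypical(self):
        a = generate_scaffold("Classical", seed=3)
        b = generate_scaffold("Classical", seed=4)
        got = classify_scaffold(a + b)
        assert got.subfamily == "Atypical"
        assert got.motif_count == 2

    @pytest.mark.parametrize("fam", ["Classical", "Plus-C", "Minus-C", "Atypical"])
    def test_invariant_to_non_anchor_substitutions(self, fam):
        seq = generate_scaffold(fam, seed=6)
        mutated = mutate_to_identity(seq, 70.0, seed=6)
        assert classify_scaffold(mutated).subfamily == fam

    @pytest.mark.parametrize("fam", ["Classical", "Plus-C", "Minus-C", "Atypical"])
    def test_generator_round_trip_500_scaffolds_per_subfamily(self, fam):
        rng = random.Random(99)
        assert all(classify_scaffold(generate_scaffold(fam, rng=rng)).subfamily
                   == fam for _ in range(500))


class TestCandidateFilter:
    SP_YES = SignalPeptideCall(True, 20, 5.0)
    SP_NO = SignalPeptideCall(False, 0, 0.0)

    def test_classical_with_signal_peptide_accepted(self):
        seq = "M" * 20 + generate_scaffold("Classical", seed=2)
        rec = SequenceRecord("x", seq)
        sc = classify_scaffold(seq[20:])
        assert is_obp_candidate(rec, sc, self.SP_YES)

    def test_unclassified_decoy_rejected(self):
        rec = SequenceRecord("d", random_protein(random.Random(1), 120, "ADEG"))
        sc = classify_scaffold(rec.seq)
        assert not is_obp_candidate(rec, sc, self.SP_NO)

    def test_signal_peptide_not_required(self):
        seq = generate_scaffold("Classical", seed=8)
        rec = SequenceRecord("x", seq)
        assert is_obp_candidate(rec, classify_scaffold(seq), self.SP_NO)

    def test_mature_length_window_enforced(self):
        seq = generate_scaffold("Classical", seed=2)
        rec = SequenceRecord("x", seq + "A" * 400)
        sc = classify_scaffold(seq)
        assert not is_obp_candidate(rec, sc, self.SP_NO)
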