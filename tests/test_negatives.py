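import numpy as np
import pytest

from pirnacnn.errors import DataError
from pirnacnn.negatives import (
    FIXTURE_LENGTHS,
    LengthDistribution,
    MarkovModel1,
    assemble_negatives,
    cut_trna_fragments,
    fit_markov,
    make_fixture,
    sample_markov,
)
from pirnacnn.seqio import SmallRNASequence, write_fasta


def seqs(*residues):
    return [SmallRNASequence(f"s{i}", r) for i, r in enumerate(residues)]


class TestFitMarkov:
    def test_homopolymer_with_uniform_fallback(self):
        model = fit_markov(seqs("A" * 12))
        assert np.array_equal(model.initial, [1, 0, 0, 0])
        assert np.array_equal(model.transition[0], [1, 0, 0, 0])
        for row in model.transition[1:]:
            assert np.array_equal(row, [0.25] * 4)

    def test_alternating_pair_counts(self):
        model = fit_markov(seqs("AC" * 5, "CA" * 5))
        assert np.array_equal(model.initial, [0.5, 0.5, 0, 0])
        # A is followed by C in 9 of 9 observed A->x pairs, and vice versa
        assert np.array_equal(model.transition[0], [0, 1, 0, 0])
        assert np.array_equal(model.transition[1], [1, 0, 0, 0])

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            fit_markov([])

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            MarkovModel1(np.array([0.5, 0.5, 0.5, 0.5]), np.full((4, 4), 0.25))


class TestSampleMarkov:
    def test_degenerate_chain_is_deterministic(self):
        model = MarkovModel1(
            np.array([1.0, 0, 0, 0]),
            np.vstack([[1.0, 0, 0, 0]] * 4),
        )
        seq = sample_markov(model, 12, np.random.default_rng(0))
        assert seq.residues == "A" * 12

    def test_seed_reproducibility(self):
        model = fit_markov(seqs("ACGTACGTACGT", "TTTTTTTTTTTT"))
        a = sample_markov(model, 30, np.random.default_rng(42))
        b = sample_markov(model, 30, np.random.default_rng(42))
        c = sample_markov(model, 30, np.random.default_rng(43))
        assert a.residues == b.residues
        assert a.residues != c.residues  # astronomically unlikely to collide

    def test_length_below_minimum_rejected(self):
        model = fit_markov(seqs("A" * 12))
        with pytest.raises(ValueError):
            sample_markov(model, 9, np.random.default_rng(0))


class TestTrnaFragments:
    trnas = seqs("ACGT" * 18, "GGCC" * 18)  # length 72, tRNA-sized

    def test_fragments_are_substrings_of_sources(self):
        lengths = LengthDistribution(np.array([30]), np.array([1.0]))
        frags = cut_trna_fragments(self.trnas, 5, lengths, np.random.default_rng(1))
        assert len(frags) == 5
        for frag in frags:
            assert frag.length == 30
            assert any(frag.residues in t.residues for t in self.trnas)

    def test_reproducible_under_seed(self):
        lengths = LengthDistribution(np.array([20, 30]), np.array([0.5, 0.5]))
        a = cut_trna_fragments(self.trnas, 10, lengths, np.random.default_rng(5))
        b = cut_trna_fragments(self.trnas, 10, lengths, np.random.default_rng(5))
        assert [f.residues for f in a] == [f.residues for f in b]

    def test_impossible_lengths_rejected(self):
        short = seqs("ACGTACGTACGT")  # length 12
        lengths = LengthDistribution(np.array([30]), np.array([1.0]))
        with pytest.raises(DataError):
            cut_trna_fragments(short, 3, lengths, np.random.default_rng(0))

    def test_length_histogram_tracks_distribution(self):
        lengths = LengthDistribution(np.array([20, 25, 30]), np.array([0.5, 0.3, 0.2]))
        frags = cut_trna_fragments(self.trnas, 2000, lengths, np.random.default_rng(7))
        observed = np.array(
            [sum(1 for f in frags if f.length == l) for l in (20, 25, 30)]
        ) / 2000
        assert 0.5 * np.abs(observed - lengths.probs).sum() < 0.03  # total variation


class TestAssembleNegatives:
    mirnas = [SmallRNASequence(f"mir{i}", "ACGUACGUACGUACGUACGUAC".replace("U", "T")) for i in range(1200)]
    trnas = seqs(*["ACGT" * 18] * 20)

    def positives(self, n):
        rng = np.random.default_rng(11)
        return [
            SmallRNASequence(f"p{i}", "".join(rng.choice(list("ACGT"), size=28)))
            for i in range(n)
        ]

    def test_exact_division(self):
        negs, manifest = assemble_negatives(
            self.positives(3000), self.mirnas, self.trnas,
            (1 / 3, 1 / 3, 1 / 3), np.random.default_rng(0),
        )
        assert len(negs) == 3000
        assert manifest["counts"] == {"markov": 1000, "mirna": 1000, "trna_fragment": 1000}

    def test_largest_remainder_rounding(self):
        negs, manifest = assemble_negatives(
            self.positives(3001), self.mirnas, self.trnas,
            (1 / 3, 1 / 3, 1 / 3), np.random.default_rng(0),
        )
        assert len(negs) == 3001
        assert sorted(manifest["counts"].values(), reverse=True) == [1001, 1000, 1000]

    def test_pure_markov_proportions(self):
        negs, manifest = assemble_negatives(
            self.positives(100), [], [], (1, 0, 0), np.random.default_rng(0)
        )
        assert len(negs) == 100
        assert all(n.id.startswith("markov") for n in negs)

    def test_missing_pool_with_nonzero_proportion(self):
        with pytest.raises(DataError):
            assemble_negatives(self.positives(100), [], self.trnas,
                               (0.5, 0.25, 0.25), np.random.default_rng(0))

    def test_small_mirna_pool_sampled_with_replacement(self):
        negs, manifest = assemble_negatives(
            self.positives(300), self.mirnas[:50], self.trnas,
            (1 / 3, 1 / 3, 1 / 3), np.random.default_rng(0),
        )
        assert len(negs) == 300
        assert manifest["mirna_sampled_with_replacement"]


class TestFixture:
    def test_counts_and_labels(self):
        bundle = make_fixture(100, 120, seed=7)
        assert len(bundle.positives) == 100
        assert len(bundle.negatives) == 120
        lo, hi = FIXTURE_LENGTHS
        for seq in bundle.positives + bundle.negatives:
            assert lo <= seq.length <= hi

    def test_deterministic_fasta_output(self, tmp_path):
        for name in ("a", "b"):
            bundle = make_fixture(50, 50, seed=123)
            write_fasta(bundle.positives + bundle.negatives, tmp_path / f"{name}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_different_seeds_differ(self):
        a = make_fixture(30, 30, seed=1)
        b = make_fixture(30, 30, seed=2)
        assert [s.residues for s in a.positives] != [s.residues for s in b.positives]

    def test_planted_five_prime_t_fraction(self):
        bundle = make_fixture(5000, 20, seed=7)
        frac = sum(1 for s in bundle.positives if s.residues[0] == "T") / 5000
        assert 0.80 < frac < 0.90

    def test_tenth_position_a_enrichment(self):
        bundle = make_fixture(2000, 2000, seed=7)
        pos_frac = sum(1 for s in bundle.positives if s.residues[9] == "A") / 2000
        neg_frac = sum(1 for s in bundle.negatives if s.residues[9] == "A") / 2000
        assert pos_frac > 0.65
        assert neg_frac < 0.4

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            make_fixture(10, 100, seed=0)


class TestSplit:
    def test_stratified_ninety_ten(self):
        bundle = make_fixture(200, 300, seed=9)
        pos_train, neg_train, pos_val, neg_val = bundle.train_validation_split()
        assert len(pos_train) == 180 and len(pos_val) == 20
        assert len(neg_train) == 270 and len(neg_val) == 30
        # disjoint and exhaustive per class
        assert {s.id for s in pos_train} | {s.id for s in pos_val} == {
            s.id for s in bundle.positives
        }
        assert {s.id for s in pos_train} & {s.id for s in pos_val} == set()

    def test_split_is_deterministic(self):
        bundle = make_fixture(100, 100, seed=9)
        first = bundle.train_validation_split()
        second = bundle.train_validation_split()
        assert [s.id for s in first[0]] == [s.id for s in second[0]]
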