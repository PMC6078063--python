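"""Negative-set construction and the synthetic benchmark fixture.

The negative dataset matches the positive set in size and consists of
three parts: (1) "fake piRNAs" sampled from a first-order Markov chain
fitted on the positives, (2) mature miRNAs taken verbatim (U -> T
normalized), and (3) fragments cut at random positions from tRNA
sequences.  Markov-fake and tRNA-fragment lengths are drawn from the
positives' empirical length distribution so that the classifier cannot
separate the classes on length alone.

:func:`make_fixture` generates a fully synthetic labelled dataset that
plants the statistical signals real piRNA sets carry — a 5' T/U bias,
an A at position 10 and a distinctive local base composition — against
negatives drawn from a compositionally different chain.  It exists so
the whole pipeline is testable without any database download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pirnacnn.errors import DataError
from pirnacnn.seqio import SmallRNASequence, normalize_residues

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class MarkovModel1:
    """First-order Markov chain over {A,C,G,T}.

    ``initial[b]`` is the probability of base b at position 1;
    ``transition[b, c]`` the probability that base c follows base b.
    """

    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        initial = np.asarray(self.initial, dtype=float)
        transition = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "transition", transition)
        if initial.shape != (4,) or transition.shape != (4, 4):
            raise ValueError("initial must be (4,), transition (4,4)")
        if (initial < 0).any() or (transition < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if not np.isclose(initial.sum(), 1.0):
            raise ValueError("initial must sum to 1")
        if not np.allclose(transition.sum(axis=1), 1.0):
            raise ValueError("every transition row must sum to 1")


@dataclass(frozen=True)
class LengthDistribution:
    """Discrete distribution over sequence lengths in [10, 50]."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        if support.min() < 10 or support.max() > 50:
            raise ValueError("lengths must lie in [10, 50]")
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("probs must be nonnegative and sum to 1")

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "LengthDistribution":
        """Empirical distribution of observed lengths."""
        values, counts = np.unique(np.asarray(lengths, dtype=int), return_counts=True)
        return cls(values, counts / counts.sum())

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.choice(self.support, size=n, p=self.probs)


def fit_markov(positives: Sequence[SmallRNASequence]) -> MarkovModel1:
    """Fit initial and transition probabilities on a sequence set.

    Rows of the transition matrix with zero observed successors fall
    back to uniform (0.25 each) so the model is always proper.
    """
    if not positives:
        raise DataError("cannot fit a Markov model on an empty set")
    initial_counts = np.zeros(4)
    pair_counts = np.zeros((4, 4))
    for seq in positives:
        codes = [_CODE[c] for c in seq.residues]
        initial_counts[codes[0]] += 1
        for a, b in zip(codes, codes[1:]):
            pair_counts[a, b] += 1
    initial = initial_counts / initial_counts.sum()
    row_sums = pair_counts.sum(axis=1, keepdims=True)
    transition = np.where(row_sums > 0, pair_counts / np.where(row_sums == 0, 1, row_sums), 0.25)
    return MarkovModel1(initial, transition)


def sample_markov(
    model: MarkovModel1,
    length: int,
    rng: np.random.Generator,
    seq_id: str = "markov",
) -> SmallRNASequence:
    """Draw one sequence of exactly ``length`` nt from the chain.

    Sampling inverts the cumulative distributions (one uniform draw per
    base), so a fixed generator state yields a fixed sequence.
    """
    if length < 10:
        raise ValueError(f"length must be >= 10, got {length}")
    cum_initial = np.cumsum(model.initial)
    cum_rows = np.cumsum(model.transition, axis=1)
    uniforms = rng.random(length)
    codes = np.empty(length, dtype=np.intp)
    codes[0] = min(int(np.searchsorted(cum_initial, uniforms[0], side="right")), 3)
    for i in range(1, length):
        row = cum_rows[codes[i - 1]]
        codes[i] = min(int(np.searchsorted(row, uniforms[i], side="right")), 3)
    return SmallRNASequence(seq_id, "".join(_BASES[c] for c in codes))


def cut_trna_fragments(
    trnas: Sequence[SmallRNASequence],
    n: int,
    lengths: LengthDistribution,
    rng: np.random.Generator,
    id_prefix: str = "trnafrag",
) -> list[SmallRNASequence]:
    """Cut ``n`` random fragments from tRNA sequences.

    Each fragment is a contiguous substring of a uniformly chosen tRNA
    (among those long enough for the drawn length), with the start
    position uniform over valid starts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not trnas:
        raise DataError("tRNA pool is empty")
    max_len = max(t.length for t in trnas)
    if lengths.support.min() > max_len:
        raise DataError("every tRNA is shorter than the smallest fragment length")
    fragments: list[SmallRNASequence] = []
    for i in range(n):
        # resample the length until some tRNA can host it
        while True:
            frag_len = int(lengths.sample(rng, 1)[0])
            eligible = [t for t in trnas if t.length >= frag_len]
            if eligible:
                break
        source = eligible[rng.integers(len(eligible))]
        start = int(rng.integers(source.length - frag_len + 1))
        fragments.append(
            SmallRNASequence(f"{id_prefix}_{i + 1}", source.residues[start : start + frag_len])
        )
    return fragments


def _largest_remainder(total: int, proportions: Sequence[float]) -> list[int]:
    """Split ``total`` into integer counts matching ``proportions``."""
    raw = [total * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    shortfall = total - sum(counts)
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def assemble_negatives(
    positives: Sequence[SmallRNASequence],
    mirnas: Sequence[SmallRNASequence] | None,
    trnas: Sequence[SmallRNASequence] | None,
    proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    rng: np.random.Generator | None = None,
) -> tuple[list[SmallRNASequence], dict]:
    """Build a negative set the same size as the positive set.

    ``proportions`` gives the (Markov fakes, miRNAs, tRNA fragments)
    mixture; counts come from largest-remainder rounding so they sum
    exactly to ``len(positives)``.  Returns the negatives plus a
    manifest of the component counts.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not np.isclose(sum(proportions), 1.0):
        raise ValueError("proportions must sum to 1")
    n_markov, n_mirna, n_trna = _largest_remainder(len(positives), proportions)
    if n_mirna > 0 and not mirnas:
        raise DataError("miRNA proportion is nonzero but the miRNA pool is empty")
    if n_trna > 0 and not trnas:
        raise DataError("tRNA proportion is nonzero but the tRNA pool is empty")

    length_dist = LengthDistribution.from_lengths([s.length for s in positives])
    negatives: list[SmallRNASequence] = []

    if n_markov:
        model = fit_markov(positives)
        for i, length in enumerate(length_dist.sample(rng, n_markov)):
            negatives.append(sample_markov(model, int(length), rng, f"markov_{i + 1}"))

    replaced = False
    if n_mirna:
        pool = list(mirnas)
        if len(pool) >= n_mirna:
            picks = rng.choice(len(pool), size=n_mirna, replace=False)
        else:
            picks = rng.choice(len(pool), size=n_mirna, replace=True)
            replaced = True
            logger.warning("miRNA pool (%d) smaller than requested %d; sampling with replacement",
                           len(pool), n_mirna)
        negatives.extend(pool[int(i)] for i in picks)

    if n_trna:
        negatives.extend(cut_trna_fragments(trnas, n_trna, length_dist, rng))

    manifest = {
        "counts": {"markov": n_markov, "mirna": n_mirna, "trna_fragment": n_trna},
        "proportions": list(proportions),
        "mirna_sampled_with_replacement": replaced,
    }
    return negatives, manifest


# ---------------------------------------------------------------------------
# Synthetic fixture

#: Chain behind the synthetic "piRNA-like" positives: A/T-rich with
#: mild autocorrelation, the composition piRNA sets tend to show.
FIXTURE_POSITIVE_MODEL = MarkovModel1(
    initial=np.array([0.30, 0.15, 0.15, 0.40]),
    transition=np.array(
        [
            [0.40, 0.12, 0.13, 0.35],
            [0.35, 0.15, 0.10, 0.40],
            [0.30, 0.15, 0.20, 0.35],
            [0.35, 0.10, 0.15, 0.40],
        ]
    ),
)

#: Chain behind the synthetic negatives: GC-leaning, compositionally
#: distinct from the positives, no positional structure.
FIXTURE_NEGATIVE_MODEL = MarkovModel1(
    initial=np.array([0.25, 0.25, 0.25, 0.25]),
    transition=np.array(
        [
            [0.15, 0.35, 0.35, 0.15],
            [0.20, 0.30, 0.30, 0.20],
            [0.20, 0.30, 0.30, 0.20],
            [0.15, 0.35, 0.35, 0.15],
        ]
    ),
)

#: Fraction of synthetic positives forced to start with T (5' U bias).
FIXTURE_FIVE_PRIME_T = 0.85
#: Fraction of synthetic positives forced to carry A at position 10.
FIXTURE_TENTH_A = 0.70
#: Length range (inclusive) of all fixture sequences, ~piRNA-sized.
FIXTURE_LENGTHS = (26, 32)


@dataclass
class DatasetBundle:
    """Labelled positives/negatives plus the 90/10 split convention."""

    positives: list[SmallRNASequence]
    negatives: list[SmallRNASequence]
    seed: int
    train_fraction: float = 0.9
    manifest: dict = field(default_factory=dict)

    def train_validation_split(
        self,
    ) -> tuple[list[SmallRNASequence], list[SmallRNASequence], list[SmallRNASequence], list[SmallRNASequence]]:
        """Stratified 90/10 split: (pos_train, neg_train, pos_val, neg_val).

        The split is a deterministic function of the bundle seed and is
        made once, before any cross validation.
        """
        rng = np.random.default_rng((self.seed, 90, 10))
        out = []
        for group in (self.positives, self.negatives):
            order = rng.permutation(len(group))
            n_train = round(self.train_fraction * len(group))
            out.append([group[i] for i in order[:n_train]])
            out.append([group[i] for i in order[n_train:]])
        pos_train, pos_val, neg_train, neg_val = out
        return pos_train, neg_train, pos_val, neg_val


def make_fixture(n_pos: int, n_neg: int, seed: int) -> DatasetBundle:
    """Generate the synthetic labelled dataset used for all testing.

    Positives are drawn from :data:`FIXTURE_POSITIVE_MODEL` at lengths
    uniform on 26..32 nt, then forced to start with T with probability
    0.85 and to carry an A at position 10 with probability 0.70 — the
    positional signals real piRNAs show.  Negatives come from the
    compositionally distinct :data:`FIXTURE_NEGATIVE_MODEL` with no
    positional forcing.  Deterministic under ``seed``.
    """
    if n_pos < 20 or n_neg < 20:
        raise ValueError("need at least 20 sequences per class")
    rng = np.random.default_rng(seed)
    lo, hi = FIXTURE_LENGTHS

    positives: list[SmallRNASequence] = []
    non_t = "ACG"
    non_a = "CGT"
    for i in range(n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = sample_markov(FIXTURE_POSITIVE_MODEL, length, rng, f"pos_{i + 1:05d}")
        residues = list(seq.residues)
        # force the positional signals so the marginal rates are exact
        if rng.random() < FIXTURE_FIVE_PRIME_T:
            residues[0] = "T"
        elif residues[0] == "T":
            residues[0] = non_t[rng.integers(3)]
        if rng.random() < FIXTURE_TENTH_A:
            residues[9] = "A"
        elif residues[9] == "A":
            residues[9] = non_a[rng.integers(3)]
        positives.append(SmallRNASequence(seq.id, "".join(residues)))

    negatives: list[SmallRNASequence] = []
    for i in range(n_neg):
        length = int(rng.integers(lo, hi + 1))
        negatives.append(
            sample_markov(FIXTURE_NEGATIVE_MODEL, length, rng, f"neg_{i + 1:05d}")
        )

    manifest = {
        "generator": "make_fixture",
        "seed": seed,
        "n_pos": n_pos,
        "n_neg": n_neg,
        "five_prime_t_prob": FIXTURE_FIVE_PRIME_T,
        "tenth_a_prob": FIXTURE_TENTH_A,
        "length_range": list(FIXTURE_LENGTHS),
    }
    return DatasetBundle(positives, negatives, seed=seed, manifest=manifest)
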