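"""Two-part k-mer featurization of small-RNA sequences.

Part one: frequencies of every k-mer for k = 1..5, giving
4 + 16 + 64 + 256 + 1024 = 1,364 values per sequence.  A k-mer's
frequency is its sliding-window count divided by the number of windows
(L - k + 1), so each k-block sums to one regardless of sequence length.

Part two ("positional enhancement"): piRNAs tend to start with a T/U
and carry an A at position 10, so k-mers occupying those positions get
extra weight, added into the same 1,364-entry vector:

* if base 1 is T, the k-mer starting at position 1 gains an extra
  1/(L-k+1) for each k;
* if base 10 is A, every k-window covering position 10 (clipped to the
  sequence bounds) gains an extra 1/(L-k+1).

Both rules may fire; a sequence matching neither is left unchanged.
The vector is reshaped row-major into a 4 x 341 matrix for the network.

Catalog order is canonical: k ascending, lexicographic (A<C<G<T) within
each k.  It is hashed into a fingerprint recorded in saved models so a
model can refuse features produced under a different ordering.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from pirnacnn.seqio import SmallRNASequence

BASES = "ACGT"
KS = (1, 2, 3, 4, 5)
N_FEATURES = 1364  # sum of 4**k for k in 1..5
MATRIX_SHAPE = (4, 341)

_CODE = {base: i for i, base in enumerate(BASES)}
_OFFSETS = {}
_off = 0
for _k in KS:
    _OFFSETS[_k] = _off
    _off += 4 ** _k
del _off, _k


@dataclass(frozen=True)
class KmerCatalog:
    """Canonical ordering of all k-mers for k = 1..5."""

    entries: tuple[str, ...]
    index: dict  # k-mer -> position in [0, 1363]

    @property
    def fingerprint(self) -> str:
        """SHA-256 of the ordered k-mer list; identifies the encoding."""
        return hashlib.sha256("\n".join(self.entries).encode()).hexdigest()

    def __len__(self) -> int:
        return len(self.entries)


@lru_cache(maxsize=1)
def build_catalog() -> KmerCatalog:
    """Build the 1,364-entry catalog (deterministic, cached)."""
    entries: list[str] = []
    for k in KS:
        entries.extend("".join(p) for p in product(BASES, repeat=k))
    assert len(entries) == N_FEATURES
    return KmerCatalog(tuple(entries), {m: i for i, m in enumerate(entries)})


def kmer_index(kmer: str) -> int:
    """Catalog position of a k-mer, computed arithmetically."""
    k = len(kmer)
    if k not in KS:
        raise ValueError(f"k={k} outside {KS}")
    value = 0
    for base in kmer:
        value = value * 4 + _CODE[base]
    return _OFFSETS[k] + value


def _encode(residues: str) -> np.ndarray:
    return np.frombuffer(
        residues.encode().translate(bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))),
        dtype=np.uint8,
    ).astype(np.int64)


def kmer_frequencies(seq: SmallRNASequence, k: int) -> dict[str, float]:
    """Sliding-window k-mer frequencies of one sequence.

    Returns a map of each *observed* k-mer to count/(L-k+1); absent
    k-mers have frequency 0.  Frequencies over all 4**k k-mers sum to 1.
    """
    if k not in KS:
        raise ValueError(f"k={k} outside {KS}")
    L = seq.length
    if L < k:
        raise ValueError(f"sequence shorter than k={k}")
    n_windows = L - k + 1
    counts: dict[str, int] = {}
    for start in range(n_windows):
        motif = seq.residues[start : start + k]
        counts[motif] = counts.get(motif, 0) + 1
    return {motif: count / n_windows for motif, count in counts.items()}


def base_feature_vector(seq: SmallRNASequence) -> np.ndarray:
    """Part-one vector: concatenated k=1..5 frequency blocks (1,364)."""
    codes = _encode(seq.residues)
    L = codes.size
    vec = np.zeros(N_FEATURES)
    for k in KS:
        n_windows = L - k + 1
        powers = 4 ** np.arange(k - 1, -1, -1)
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        idx = windows @ powers
        counts = np.bincount(idx, minlength=4**k)
        vec[_OFFSETS[k] : _OFFSETS[k] + 4**k] = counts / n_windows
    return vec


def positional_enhancement(seq: SmallRNASequence, base_vector: np.ndarray) -> np.ndarray:
    """Add part-two weight for a 5' T and/or an A at position 10.

    Positions are 1-based.  Returns a new vector; the input is not
    modified.  Sequences with neither signal come back unchanged.
    """
    out = np.asarray(base_vector, dtype=float).copy()
    residues = seq.residues
    L = len(residues)
    if residues[0] == "T":
        for k in KS:
            if k <= L:
                out[kmer_index(residues[:k])] += 1.0 / (L - k + 1)
    if L >= 10 and residues[9] == "A":
        for k in KS:
            n_windows = L - k + 1
            # 1-based starts of k-windows covering position 10
            for start in range(max(1, 10 - k + 1), 11):
                if start + k - 1 <= L:
                    motif = residues[start - 1 : start - 1 + k]
                    out[kmer_index(motif)] += 1.0 / n_windows
    return out


def feature_vector(seq: SmallRNASequence) -> np.ndarray:
    """Full 1,364-entry feature vector (frequencies + enhancement)."""
    return positional_enhancement(seq, base_feature_vector(seq))


def featurize(seq: SmallRNASequence) -> np.ndarray:
    """Encode one sequence as the 4 x 341 input matrix (row-major)."""
    return feature_vector(seq).reshape(MATRIX_SHAPE)


def featurize_many(seqs: Sequence[SmallRNASequence]) -> np.ndarray:
    """Stack featurizations into an (N, 4, 341) array."""
    return np.stack([featurize(s) for s in seqs])


def export_features_tsv(seqs: Iterable[SmallRNASequence], path: str | Path) -> None:
    """Debug export: one row per sequence, 1,364 catalog-ordered columns."""
    catalog = build_catalog()
    with open(path, "w") as handle:
        handle.write("id\t" + "\t".join(catalog.entries) + "\n")
        for seq in seqs:
            vec = feature_vector(seq)
            handle.write(seq.id + "\t" + "\t".join(f"{v:.6g}" for v in vec) + "\n")
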