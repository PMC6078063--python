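"""Reading, validating and writing small-RNA sequences and predictions.

Sequences are normalized to the DNA alphabet (U -> T, upper case) so a
single k-mer catalog serves both RNA and DNA input.  Records shorter
than the minimum length (position 10 must exist for the positional
feature) or containing ambiguity codes are skipped and counted, not
fatal: real small-RNA FASTA files contain occasional Ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser

from pirnacnn.errors import DataError, EmptyDatasetError

ALPHABET = frozenset("ACGT")

#: piRNAs are ~24-32 nt; above this we warn but keep the record.
DEFAULT_MIN_LENGTH = 10
DEFAULT_MAX_LENGTH = 50


@dataclass(frozen=True)
class SmallRNASequence:
    """A validated, alphabet-normalized small-RNA record."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence id must be non-empty")
        if len(self.residues) < DEFAULT_MIN_LENGTH:
            raise DataError(
                f"{self.id}: length {len(self.residues)} < {DEFAULT_MIN_LENGTH}"
            )
        if not ALPHABET.issuperset(self.residues):
            bad = sorted(set(self.residues) - ALPHABET)
            raise DataError(f"{self.id}: non-ACGT symbols {bad}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PredictionRecord:
    """Classifier output for one query sequence.

    ``call`` is derived: piRNA iff ``prob_pirna >= threshold``
    (inclusive at the boundary).
    """

    id: str
    prob_pirna: float
    threshold: float = 0.5

    @property
    def call(self) -> str:
        return "piRNA" if self.prob_pirna >= self.threshold else "non-piRNA"


def normalize_residues(raw: str) -> str:
    """Upper-case and map U to T.  Idempotent."""
    return raw.upper().replace("U", "T")


@dataclass
class SkipReport:
    """Counts of records dropped during FASTA reading."""

    too_short: int = 0
    bad_alphabet: int = 0
    skipped_ids: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.too_short + self.bad_alphabet

    def as_dict(self) -> dict:
        return {"too_short": self.too_short, "bad_alphabet": self.bad_alphabet}


def read_fasta(
    path: str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> tuple[list[SmallRNASequence], SkipReport]:
    """Read a FASTA file into normalized records, skipping invalid ones.

    Parameters
    ----------
    path:
        FASTA file (multi-line records allowed; RNA or DNA alphabet).
    min_length:
        Records shorter than this are skipped (never below 10: the
        positional feature needs a 10th base and k=5 windows).
    max_length:
        Records longer than this trigger a warning but are kept.

    Returns
    -------
    (records, skip_report) with input order preserved.

    Raises
    ------
    EmptyDatasetError
        If no record survives filtering.
    DataError
        On duplicate ids.
    """
    min_length = max(min_length, DEFAULT_MIN_LENGTH)
    records: list[SmallRNASequence] = []
    report = SkipReport()
    seen: set[str] = set()
    n_long = 0
    with open(path) as handle:
        for header, raw in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else ""
            residues = normalize_residues(raw.replace(" ", ""))
            if not ALPHABET.issuperset(residues):
                report.bad_alphabet += 1
                report.skipped_ids.append(rec_id)
                continue
            if len(residues) < min_length:
                report.too_short += 1
                report.skipped_ids.append(rec_id)
                continue
            if rec_id in seen:
                raise DataError(f"duplicate sequence id {rec_id!r} in {path}")
            seen.add(rec_id)
            if len(residues) > max_length:
                n_long += 1
            records.append(SmallRNASequence(rec_id, residues))
    if n_long:
        warnings.warn(
            f"{path}: {n_long} record(s) longer than {max_length} nt "
            "(piRNAs are typically ~24-32 nt); kept anyway",
            stacklevel=2,
        )
    if not records:
        raise EmptyDatasetError(f"no valid sequences in {path}")
    return records, report


def write_fasta(records: Iterable[SmallRNASequence], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping lines at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                handle.write(rec.residues[i : i + width] + "\n")


def write_predictions(records: list[PredictionRecord], path: str | Path,
                      skipped: Iterable[str] = ()) -> None:
    """Write predictions as TSV: id, prob_piRNA (4 decimals), call.

    A ``# threshold=`` comment line makes the file self-describing;
    skipped query ids (e.g. too short to featurize) are appended as
    comment rows so they are visible, not silently dropped.
    """
    records = list(records)
    if not records:
        raise DataError("no prediction records to write")
    threshold = records[0].threshold
    with open(path, "w") as handle:
        handle.write(f"# threshold={threshold}\n")
        handle.write("id\tprob_piRNA\tcall\n")
        for rec in records:
            handle.write(f"{rec.id}\t{rec.prob_pirna:.4f}\t{rec.call}\n")
        for sid in skipped:
            handle.write(f"# skipped\t{sid}\n")


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    """Parse a predictions TSV written by :func:`write_predictions`."""
    records: list[PredictionRecord] = []
    threshold = 0.5
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("# threshold="):
                threshold = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#") or line.startswith("id\t"):
                continue
            rec_id, prob, _call = line.split("\t")
            records.append(PredictionRecord(rec_id, float(prob), threshold))
    return records
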