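"""Reading, validating, and summarizing labeled peptide datasets.

Peptides are short (typically 5-50 residues) sequences over the 20 natural
amino acids. Benchmark collections arrive either as a pair of FASTA files
(positives / negatives) or as one FASTA plus a two-column id->label table;
sequences containing any non-natural letter are eliminated before feature
extraction, with every removal reported.

Positions are 1-based in all formula descriptions (R1..RL) and 0-based in
storage; encoders document the shift where it matters.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AMINO_ACIDS, NON_NATURAL

logger = logging.getLogger(__name__)

_VALID = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: an identifier and a validated sequence R1..RL."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"{self.id}: non-natural characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Parallel peptides and binary labels (1 = anticancer peptide)."""

    records: list[PeptideRecord]
    labels: np.ndarray
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != self.labels.size:
            raise ValueError("records and labels differ in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self) - self.labels.sum())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError(
                f"{self.name}: training requires both classes "
                f"(have {self.n_pos} positive, {self.n_neg} negative)"
            )


@dataclass(frozen=True)
class RawRecord:
    """An unvalidated FASTA entry; may contain non-natural characters."""

    id: str
    sequence: str


@dataclass
class RejectionReport:
    """Which records validation removed, and the offending characters."""

    rejected: list[tuple[str, str]] = field(default_factory=list)

    def add(self, record_id: str, bad_chars: Iterable[str]) -> None:
        self.rejected.append((record_id, "".join(sorted(set(bad_chars)))))

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __bool__(self) -> bool:
        return bool(self.rejected)


def read_fasta(path: str | Path) -> list[RawRecord]:
    """Parse a FASTA file into raw records, order preserved.

    Whitespace inside sequence lines is stripped and letters upper-cased.
    No validation happens here: records with non-natural characters are kept
    so that :func:`validate_dataset` can report them. Raises ``ValueError``
    on sequence data before the first header, ``OSError`` if unreadable.
    """
    path = Path(path)
    with open(path) as handle:
        first = None
        for line in handle:
            if line.strip():
                first = line
                break
        if first is not None and not first.startswith(">"):
            raise ValueError(f"{path}: sequence data before first FASTA header")
    records = []
    seen: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        records.append(RawRecord(id=rec.id, sequence=seq))
        seen[rec.id] += 1
    dupes = [rid for rid, n in seen.items() if n > 1]
    if dupes:
        logger.warning("%s: duplicate ids %s", path, dupes[:10])
    return records


def write_fasta(records: Sequence[PeptideRecord | RawRecord], path: str | Path) -> None:
    """Write records as single-line-sequence FASTA."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta-2line")


def validate_dataset(
    records: Sequence[RawRecord | PeptideRecord],
    labels: Sequence[int],
    name: str = "dataset",
) -> tuple[LabeledDataset, RejectionReport]:
    """Drop records with non-natural characters, keeping labels aligned.

    Ambiguity codes (B, J, O, U, X, Z), digits, gaps — anything outside the
    20-letter alphabet — disqualify a record. Every removal is listed in the
    report with its id and the offending characters. Raises ``ValueError``
    if the lists differ in length or no record survives.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels differ in length")
    report = RejectionReport()
    kept: list[PeptideRecord] = []
    kept_labels: list[int] = []
    for rec, label in zip(records, labels):
        bad = set(rec.sequence) - _VALID
        if bad or not rec.sequence:
            report.add(rec.id, bad if bad else {"<empty>"})
            continue
        kept.append(PeptideRecord(id=rec.id, sequence=rec.sequence))
        kept_labels.append(int(label))
    if not kept:
        raise ValueError(f"{name}: all records rejected during validation")
    if report:
        logger.info("%s: removed %d records with non-natural characters",
                    name, report.n_rejected)
    return LabeledDataset(records=kept, labels=np.array(kept_labels), name=name), report


def load_labeled_fasta(
    pos_path: str | Path, neg_path: str | Path, name: str = "dataset"
) -> tuple[LabeledDataset, RejectionReport]:
    """Read a positive/negative FASTA pair and validate the union."""
    pos = read_fasta(pos_path)
    neg = read_fasta(neg_path)
    records = list(pos) + list(neg)
    labels = [1] * len(pos) + [0] * len(neg)
    return validate_dataset(records, labels, name=name)


def load_label_table(
    fasta_path: str | Path, table_path: str | Path, name: str = "dataset"
) -> tuple[LabeledDataset, RejectionReport]:
    """Read one FASTA plus a TSV of (id, label) rows."""
    id_to_label: dict[str, int] = {}
    with open(table_path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{table_path}:{lineno}: expected id<TAB>label")
            id_to_label[parts[0]] = int(parts[1])
    records = read_fasta(fasta_path)
    missing = [r.id for r in records if r.id not in id_to_label]
    if missing:
        raise ValueError(f"{table_path}: no label for ids {missing[:10]}")
    labels = [id_to_label[r.id] for r in records]
    return validate_dataset(records, labels, name=name)


@dataclass
class DatasetSummary:
    """Per-class composition and length statistics."""

    aa_counts: dict[int, dict[str, int]]
    length_hist: dict[int, Counter]
    fraction_in_5_50: dict[int, float]
    n_per_class: dict[int, int]


def dataset_summary(dataset: LabeledDataset) -> DatasetSummary:
    """Summarize per-class amino-acid counts and length distribution.

    Reports, per class, the tally of each of the 20 letters, a length
    histogram, and the fraction of sequences with 5 <= L <= 50 (the range
    containing most benchmark peptides). Length outliers are kept in the
    dataset; only the fraction is reported.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    aa_counts: dict[int, dict[str, int]] = {}
    length_hist: dict[int, Counter] = {}
    frac: dict[int, float] = {}
    n_per: dict[int, int] = {}
    for cls in (0, 1):
        recs = [r for r, y in zip(dataset.records, dataset.labels) if y == cls]
        n_per[cls] = len(recs)
        tally: Counter[str] = Counter()
        lengths: Counter[int] = Counter()
        for r in recs:
            tally.update(r.sequence)
            lengths[r.length] += 1
        aa_counts[cls] = {aa: tally.get(aa, 0) for aa in AMINO_ACIDS}
        length_hist[cls] = lengths
        if recs:
            in_range = sum(1 for r in recs if 5 <= r.length <= 50)
            frac[cls] = in_range / len(recs)
        else:
            frac[cls] = float("nan")
    return DatasetSummary(
        aa_counts=aa_counts,
        length_hist=length_hist,
        fraction_in_5_50=frac,
        n_per_class=n_per,
    )
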