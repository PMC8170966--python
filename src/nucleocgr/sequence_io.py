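"""FASTA reading/writing and validated, labeled DNA sequence sets.

Sequences are restricted to the four-letter alphabet {A, C, G, T}: the chaos
game corners are defined only for those bases, so ambiguity codes must either
abort the run (``policy="reject"``, the default) or be dropped with a logged
count (``policy="drop"``) before any feature extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

AmbiguityPolicy = Literal["reject", "drop"]


@dataclass(frozen=True)
class SequenceRecord:
    """A validated DNA sequence with an optional binary label.

    label 1 = nucleosome-forming (positive, core DNA),
    label 0 = nucleosome-inhibiting (negative, linker DNA).
    """

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A/C/G/T)"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """An ordered two-class collection of labeled sequence records."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.label is None:
                raise ValueError(f"record {r.id!r} is unlabeled")

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]  # type: ignore[misc]

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_fasta(path: str | Path, policy: AmbiguityPolicy = "reject") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are upper-cased.  Records containing characters outside
    {A, C, G, T} abort the read under ``policy="reject"`` (naming the
    offending record) or are removed and counted in a log message under
    ``policy="drop"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    n_dropped = 0
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        seq = str(bio_rec.seq).upper()
        if not seq:
            raise ValueError(f"record {bio_rec.id!r} in {path} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            if policy == "reject":
                raise ValueError(
                    f"record {bio_rec.id!r} in {path} contains non-ACGT "
                    f"characters {sorted(bad)!r}; use policy='drop' to skip"
                )
            n_dropped += 1
            continue
        records.append(SequenceRecord(id=bio_rec.id, seq=seq))
    if n_dropped:
        logger.warning("dropped %d record(s) with ambiguous bases from %s", n_dropped, path)
    if not records and n_dropped == 0:
        raise ValueError(f"{path} contains no FASTA records")
    return records


def load_labeled_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    policy: AmbiguityPolicy = "reject",
) -> LabeledDataset:
    """Load positive (nucleosome-forming) and negative (linker) FASTA files.

    Records from ``pos_path`` receive label 1, from ``neg_path`` label 0;
    order is positives first, in file order.  Either class being empty is an
    error, since a one-class set cannot be stratified or scored.
    """
    pos = read_fasta(pos_path, policy=policy)
    neg = read_fasta(neg_path, policy=policy)
    if not pos:
        raise ValueError(f"empty class: no usable records in positive file {pos_path}")
    if not neg:
        raise ValueError(f"empty class: no usable records in negative file {neg_path}")
    records = [SequenceRecord(r.id, r.seq, 1) for r in pos] + [
        SequenceRecord(r.id, r.seq, 0) for r in neg
    ]
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        logger.warning(
            "sequences have unequal lengths %s; features are length-normalized "
            "but benchmark sets are fixed-length",
            sorted(lengths),
        )
    ds = LabeledDataset(records)
    logger.info("loaded %d positive + %d negative records", ds.n_pos, ds.n_neg)
    return ds


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to ``path`` so that ``read_fasta`` round-trips (id, seq)."""
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta-2line")


def split_dataset(ds: LabeledDataset) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split a labeled dataset back into (positive, negative) record lists."""
    return (
        [r for r in ds.records if r.label == 1],
        [r for r in ds.records if r.label == 0],
    )
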