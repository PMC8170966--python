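"""Two-class synthetic sequence generators with tunable k-mer composition bias.

Stands in for benchmark nucleosome datasets so every downstream stage is
testable offline.  Two modes:

* ``markov`` -- both classes are order-1 Markov chains over {A, C, G, T}.
  The negative (linker-like) class uses uniform transition rows.  In the
  positive class, the row following C or G is tilted toward C/G and the row
  following A or T toward A/T, each by mixing the uniform row with a bias
  row at weight ``effect``.  The tilt is symmetric, so mononucleotide
  composition stays near uniform and the class signal lives in dinucleotides
  and longer k-mers: FCGR at K >= 2 carries far more signal than K = 1.

* ``periodic`` -- the negative class is i.i.d. uniform; the positive class
  receives an AA or TT dinucleotide planted at every 10th position with
  probability ``effect`` per site, mimicking the ~10 bp helical periodicity
  of bendability dinucleotides in nucleosomal DNA.

``effect = 0`` makes the two classes identically distributed in both modes.
Everything is deterministic given the seed, down to the FASTA bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucleocgr.sequence_io import LabeledDataset, SequenceRecord

_BASES = np.array(list("ACGT"))

# bias rows for the markov mode, order A, C, G, T
_CG_RICH = np.array([0.05, 0.45, 0.45, 0.05])
_AT_RICH = np.array([0.45, 0.05, 0.05, 0.45])
_UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class GeneratorSpec:
    n_pos: int
    n_neg: int
    L: int = 147
    mode: str = "markov"
    effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 10:
            raise ValueError("L must be >= 10")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must be in [0, 1]")
        if self.mode not in ("markov", "periodic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one sequence")


def _markov_sequences(n: int, L: int, trans: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Sample n length-L chains from a 4x4 transition matrix (uniform start)."""
    cum = trans.cumsum(axis=1)
    seqs = []
    for _ in range(n):
        states = np.empty(L, dtype=int)
        states[0] = rng.integers(4)
        u = rng.random(L - 1)
        for i in range(1, L):
            states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1], side="right")
        seqs.append("".join(_BASES[states]))
    return seqs


def _positive_transition(effect: float) -> np.ndarray:
    rows = np.empty((4, 4))
    rows[0] = rows[3] = (1 - effect) * _UNIFORM + effect * _AT_RICH  # after A or T
    rows[1] = rows[2] = (1 - effect) * _UNIFORM + effect * _CG_RICH  # after C or G
    return rows


def _periodic_sequences(
    n: int, L: int, effect: float, rng: np.random.Generator
) -> list[str]:
    seqs = []
    for _ in range(n):
        states = rng.integers(4, size=L)
        for p in range(0, L - 1, 10):
            if rng.random() < effect:
                dinuc = "AA" if rng.random() < 0.5 else "TT"
                states[p] = "ACGT".index(dinuc[0])
                states[p + 1] = "ACGT".index(dinuc[1])
        seqs.append("".join(_BASES[states]))
    return seqs


def generate_dataset(spec: GeneratorSpec) -> LabeledDataset:
    """Generate a labeled two-class dataset per the spec (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "markov":
        pos = _markov_sequences(spec.n_pos, spec.L, _positive_transition(spec.effect), rng)
        neg = _markov_sequences(spec.n_neg, spec.L, np.tile(_UNIFORM, (4, 1)), rng)
    else:
        pos = _periodic_sequences(spec.n_pos, spec.L, spec.effect, rng)
        neg = _periodic_sequences(spec.n_neg, spec.L, 0.0, rng)
    records = [
        SequenceRecord(id=f"pos_{i}", seq=s, label=1) for i, s in enumerate(pos)
    ] + [SequenceRecord(id=f"neg_{i}", seq=s, label=0) for i, s in enumerate(neg)]
    return LabeledDataset(records)


def permute_labels(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Randomly reassign labels, preserving class counts and sequences."""
    rng = np.random.default_rng(seed)
    labels = np.array(dataset.labels)
    rng.shuffle(labels)
    return LabeledDataset(
        [
            SequenceRecord(id=r.id, seq=r.seq, label=int(lbl))
            for r, lbl in zip(dataset.records, labels)
        ]
    )
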