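"""Physicochemical sequence features: autocovariance and pseudo composition.

Two feature families defined on a table of per-oligonucleotide
physicochemical index values P_u (standardized to mean 0 / SD 1 over the
4^order oligos):

* **Autocovariance** (DAC for dinucleotides, TAC for trinucleotides): for
  each index u and lag d, the covariance of the index profile of the
  sequence with itself shifted by d positions.  With cross terms between
  index pairs (DCC/TCC) appended, the concatenations are called DACC/TACC.

* **Parallel-correlation pseudo composition** (PC-PseDNC / PC-PseTNC): the
  normalized oligomer frequencies f_k extended by lambda sequence-order
  correlation factors theta_j, weighted by w and jointly normalized so the
  whole vector sums to 1.

The built-in tables ship as TSV data files (six dinucleotide helical step
parameters; a trinucleotide bendability scale plus a derived step-averaged
Roll) and can be replaced by any user table covering all 4^order oligos.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = "ACGT"

_BUILTIN = {
    (2, "helical-steps"): "dinucleotide_indices.tsv",
    (3, "bendability"): "trinucleotide_indices.tsv",
}


def all_oligos(order: int) -> list[str]:
    """Lexicographic list of the 4^order oligonucleotides."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=order)]


@dataclass(frozen=True)
class PhysChemIndexTable:
    """Standardized oligo -> value map for one or more named indices.

    ``values`` has shape (4^order, n_indices), rows in lexicographic oligo
    order; each column has mean 0 and population SD 1.
    """

    order: int
    index_names: tuple[str, ...]
    values: np.ndarray

    @property
    def n_indices(self) -> int:
        return len(self.index_names)

    def lookup(self, seq: str) -> np.ndarray:
        """Index profile of a sequence: shape (L - order + 1, n_indices)."""
        k = self.order
        idx = np.array([_oligo_rank(seq[i : i + k]) for i in range(len(seq) - k + 1)])
        return self.values[idx]


@dataclass(frozen=True)
class AutocovParams:
    lag: int = 2
    order: int = 2
    include_cross: bool = False

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")


@dataclass(frozen=True)
class PseKNCParams:
    lam: int = 8
    w: float = 0.5
    order: int = 2

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")


def _oligo_rank(oligo: str) -> int:
    r = 0
    for b in oligo:
        r = r * 4 + _BASES.index(b)
    return r


def load_index_table(source: str | Path, order: int) -> PhysChemIndexTable:
    """Load and standardize an index table.

    ``source`` is either a built-in name (``"helical-steps"`` for
    dinucleotides, ``"bendability"`` for trinucleotides) or a path to a
    tab-delimited file whose first column is the oligo and whose remaining
    named columns are raw index values.  Each index is standardized to mean 0
    and population SD 1 over the 4^order oligos; a missing oligo or a
    constant index is an error.
    """
    key = (order, str(source))
    if key in _BUILTIN:
        ref = resources.files("nucleocgr.data") / _BUILTIN[key]
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"{source!r} is neither a built-in table name for order {order} "
                f"nor an existing file"
            )
        df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    oligos = all_oligos(order)
    missing = [o for o in oligos if o not in df.index]
    if missing:
        raise ValueError(f"index table is missing oligo(s) {missing}")
    raw = df.loc[oligos].to_numpy(dtype=float)
    sd = raw.std(axis=0)  # population SD
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = [df.columns[i] for i in const]
        raise ValueError(f"constant index (SD = 0): {names}")
    values = (raw - raw.mean(axis=0)) / sd
    return PhysChemIndexTable(
        order=order, index_names=tuple(df.columns), values=values
    )


def autocovariance_features(
    seq: str, table: PhysChemIndexTable, params: AutocovParams
) -> np.ndarray:
    """DAC/TAC (and with ``include_cross`` the DACC/TACC) feature vector.

    For each index u and lag d in 1..lag,

        AC(u, d) = (1 / (M - d)) * sum_{i=1}^{M-d} (P_u(o_i) - mean_u)
                                                  * (P_u(o_{i+d}) - mean_u)

    where M = L - order + 1 order-mers o_i and mean_u is the per-sequence
    mean of the index profile.  Cross covariances CC(u1, u2, d) for ordered
    pairs u1 != u2 are appended when ``include_cross``.  Ordering is
    index-major then lag-major; dimensions N*lag and N*lag + N*(N-1)*lag.
    """
    if params.order != table.order:
        raise ValueError("params.order does not match table.order")
    L = len(seq)
    M = L - table.order + 1
    if M - params.lag < 1:
        raise ValueError(
            f"sequence length {L} too short for order {table.order}, lag {params.lag}"
        )
    prof = table.lookup(seq)  # (M, N)
    dev = prof - prof.mean(axis=0)
    N = table.n_indices
    ac = np.empty((N, params.lag))
    for d in range(1, params.lag + 1):
        ac[:, d - 1] = (dev[:-d] * dev[d:]).sum(axis=0) / (M - d)
    out = [ac.ravel()]  # index-major, lag-minor
    if params.include_cross:
        cc = np.empty((N, N, params.lag))
        for d in range(1, params.lag + 1):
            cc[:, :, d - 1] = dev[:-d].T @ dev[d:] / (M - d)
        pairs = [(u1, u2) for u1 in range(N) for u2 in range(N) if u1 != u2]
        out.append(np.array([cc[u1, u2, :] for u1, u2 in pairs]).ravel())
    return np.concatenate(out)


def autocovariance_feature_names(
    table: PhysChemIndexTable, params: AutocovParams
) -> list[str]:
    prefix = {2: "d", 3: "t"}[table.order]
    names = [
        f"{prefix}ac_{u}_lag{d}"
        for u in table.index_names
        for d in range(1, params.lag + 1)
    ]
    if params.include_cross:
        names += [
            f"{prefix}cc_{u1}_{u2}_lag{d}"
            for u1 in table.index_names
            for u2 in table.index_names
            if u1 != u2
            for d in range(1, params.lag + 1)
        ]
    return names


def pse_knc_parallel(
    seq: str, table: PhysChemIndexTable, params: PseKNCParams
) -> np.ndarray:
    """PC-PseDNC / PC-PseTNC vector of length 4^order + lambda.

    The first 4^order components are normalized order-mer frequencies f_k
    and the trailing lambda components are weighted correlation factors

        theta_j = (1 / (M - j)) * sum_i Theta(o_i, o_{i+j}),
        Theta(a, b) = (1 / N) * sum_u (P_u(a) - P_u(b))^2,

    combined as d_k = f_k / (1 + w * sum theta) and
    d_{4^order + j} = w * theta_j / (1 + w * sum theta); the vector sums
    to 1.  At w = 0 it reduces to the raw frequencies.
    """
    if params.order != table.order:
        raise ValueError("params.order does not match table.order")
    L = len(seq)
    k = table.order
    M = L - k + 1
    if params.lam > 0 and M - params.lam < 1:
        raise ValueError(f"lambda = {params.lam} too large for sequence length {L}")
    n_oligo = 4**k
    freqs = np.zeros(n_oligo)
    ranks = np.array([_oligo_rank(seq[i : i + k]) for i in range(M)])
    np.add.at(freqs, ranks, 1.0)
    freqs /= M
    prof = table.values[ranks]  # (M, N)
    thetas = np.empty(params.lam)
    for j in range(1, params.lam + 1):
        diff = prof[:-j] - prof[j:]
        thetas[j - 1] = (diff**2).mean(axis=1).sum() / (M - j)
    denom = 1.0 + params.w * thetas.sum()
    return np.concatenate([freqs / denom, params.w * thetas / denom])


def pse_knc_feature_names(params: PseKNCParams) -> list[str]:
    tag = {2: "pcpsednc", 3: "pcpsetnc"}[params.order]
    return [f"{tag}_{o}" for o in all_oligos(params.order)] + [
        f"{tag}_theta{j}" for j in range(1, params.lam + 1)
    ]
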