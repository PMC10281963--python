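"""Evolutionary node features: normalized effective sequence counts.

The effective number of sequences (Neff) of a multiple sequence alignment
down-weights near-duplicate rows: each row contributes the reciprocal of
the number of rows more than 80% identical to it (itself included), so N
identical rows count as a single effective sequence. Neff is normalized by
the square root of the query length, Neff / sqrt(L). Every node receives
the normalized Neff of its own chain's monomer MSA and of the paired
(concatenated chain1+chain2) MSA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("ifaceqe")

IDENTITY_THRESHOLD = 0.8

_GAP = "-"


@dataclass
class MultipleSequenceAlignment:
    """Aligned rows over the amino-acid + gap alphabet; row 0 is the query."""

    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("MSA must contain at least one sequence")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("ragged alignment: rows differ in length")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def query_length(self) -> int:
        return sum(1 for c in self.sequences[0] if c != _GAP)


def read_msa(path: str) -> MultipleSequenceAlignment:
    """Read a FASTA or A3M alignment.

    A3M lowercase (insertion relative to query) columns are removed so all
    rows align on query columns; duplicate rows are retained. '.' gaps are
    normalized to '-'.
    """
    sequences: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith(("#", ";")):
                continue
            if line.startswith(">"):
                if current:
                    sequences.append("".join(current))
                    current = []
            else:
                current.append(line)
    if current:
        sequences.append("".join(current))
    if not sequences:
        raise ValueError(f"{path}: no sequences found")
    # a3m convention: lowercase letters are insertions, dropped from all rows
    cleaned = ["".join(c for c in s if not c.islower()).replace(".", _GAP)
               for s in sequences]
    return MultipleSequenceAlignment(cleaned)


def pairwise_identity_matrix(msa: MultipleSequenceAlignment) -> np.ndarray:
    """Fraction of identical alignment positions (gap-gap counts as a
    match), so self-identity is always exactly 1."""
    arr = np.array([list(s) for s in msa.sequences])
    n = msa.n_rows
    L = arr.shape[1]
    ident = np.empty((n, n))
    for i in range(n):
        ident[i] = (arr == arr[i]).sum(axis=1) / L
    return ident


def effective_sequence_count(msa: MultipleSequenceAlignment,
                             identity_threshold: float = IDENTITY_THRESHOLD,
                             ) -> float:
    """Neff: sum over rows of 1 / (cluster size at > threshold identity).

    The cluster of a row always includes the row itself, so each term is at
    most 1 and Neff lies in [1, n_rows].
    """
    ident = pairwise_identity_matrix(msa)
    cluster_sizes = (ident > identity_threshold).sum(axis=1)
    # self-identity is 1 > threshold, so every cluster size is >= 1
    return float((1.0 / cluster_sizes).sum())


def normalized_neff(neff: float, query_length: int) -> float:
    """Neff / sqrt(L)."""
    if query_length < 1:
        raise ValueError("query length must be >= 1")
    return neff / np.sqrt(query_length)


def msa_normalized_neff(msa: MultipleSequenceAlignment,
                        identity_threshold: float = IDENTITY_THRESHOLD,
                        ) -> float:
    return normalized_neff(
        effective_sequence_count(msa, identity_threshold), msa.query_length
    )


def node_evolutionary_features(
    msa_chain1: MultipleSequenceAlignment | None,
    msa_chain2: MultipleSequenceAlignment | None,
    msa_paired: MultipleSequenceAlignment | None,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> tuple[float, float, float]:
    """(chain-1 monomer, chain-2 monomer, paired) normalized Neff values.

    An absent MSA yields 0 for its slot with a logged warning; chain-c nodes
    broadcast slot c as their monomer feature and every node shares the
    paired slot.
    """
    out = []
    for name, msa in (("chain 1", msa_chain1), ("chain 2", msa_chain2),
                      ("paired", msa_paired)):
        if msa is None:
            logger.warning("no %s MSA supplied; Neff feature set to 0", name)
            out.append(0.0)
        else:
            out.append(msa_normalized_neff(msa, identity_threshold))
    return tuple(out)
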