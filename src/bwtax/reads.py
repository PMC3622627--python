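"""BWT index of the sequencing reads.

Indexing the reads (rather than searching them one by one) means every
distinct k-mer of the read set appears exactly once in the synchronized
traversal, with its multiplicity across reads recoverable as the size of
its Q-interval.  Reads are indexed exactly as given — no reverse
complementing or canonicalization — because the reference index already
carries both strands of every genome.  Paired-end structure is ignored;
mates are independent reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

from .bwt import ALPHABET, GeneralizedBWT, SequenceCollection, build_gsa_bwt

_VALID = set(ALPHABET)


@dataclass
class ReadSet:
    """Uniform-length reads (shorter reads may be right-padded with N)."""

    reads: list[tuple[str, str]]
    read_length: int

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("read set is empty")
        for name, seq in self.reads:
            if len(seq) != self.read_length:
                raise ValueError(
                    f"read {name!r} has length {len(seq)}, expected "
                    f"{self.read_length}"
                )

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.reads)

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.reads]


def from_sequences(
    sequences: Sequence[str],
    ids: Sequence[str] | None = None,
    pad_to_uniform: bool = False,
) -> ReadSet:
    """Build a :class:`ReadSet` from bare sequences (test/simulation entry)."""
    if ids is None:
        width = len(str(max(len(sequences) - 1, 0)))
        ids = [f"read_{i:0{width}d}" for i in range(len(sequences))]
    return _assemble(list(zip(ids, sequences)), pad_to_uniform)


def _assemble(pairs: list[tuple[str, str]], pad_to_uniform: bool) -> ReadSet:
    if not pairs:
        raise ValueError("no reads found")
    lengths = {len(s) for _, s in pairs}
    target = max(lengths)
    if len(lengths) > 1:
        if not pad_to_uniform:
            raise ValueError(
                f"reads have non-uniform lengths {sorted(lengths)}; "
                "pass pad_to_uniform=True to right-pad with N"
            )
        pairs = [(n, s + "N" * (target - len(s))) for n, s in pairs]
    return ReadSet(pairs, target)


def load_reads(path: str | Path, pad_to_uniform: bool = False) -> ReadSet:
    """Load FASTQ or FASTA reads; qualities are ignored.

    Format is chosen by first byte ('@' FASTQ, '>' FASTA).  Sequences are
    uppercased; any symbol outside {A,C,G,T} becomes N.  Duplicate read
    names (e.g. mate pairs sharing an id) are disambiguated with a
    ``#<ordinal>`` suffix so each read stays a distinct index member.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if not first:
        raise ValueError(f"{path} is empty")
    fmt = "fastq" if first == "@" else "fasta"
    pairs: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), fmt):
        seq = str(rec.seq).upper()
        seq = "".join(c if c in _VALID else "N" for c in seq)
        name = rec.id
        n_prev = seen.get(name)
        if n_prev is not None:
            seen[name] = n_prev + 1
            name = f"{name}#{n_prev + 1}"
        else:
            seen[name] = 0
        pairs.append((name, seq))
    return _assemble(pairs, pad_to_uniform)


def build_read_index(reads: ReadSet) -> GeneralizedBWT:
    """Generalized BWT over the reads as given (single strand).

    For any k-mer Q, the Q-interval size in this index equals the total
    occurrence count of Q across all reads.
    """
    return build_gsa_bwt(SequenceCollection(reads.reads))
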