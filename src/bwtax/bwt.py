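"""Generalized Burrows-Wheeler transform of a sequence collection.

Each member of a collection is conceptually terminated by its own sentinel
``$1 < $2 < ... < $n``, all of which sort below the nucleotide alphabet
``A < C < G < N < T``.  Sorting every suffix of every member under this
order yields a generalized suffix array; reading off, for each suffix, the
symbol that precedes it *within its own member* (wrapping to the member's
sentinel at offset 0) yields the generalized BWT.  The arrays ``A`` (suffix
offset within member) and ``C`` (member index) recover the provenance of
every BWT position, which is what the taxonomic classifier consumes.

Construction sorts the sentinel-augmented concatenation in memory with
numpy prefix doubling; because every sentinel is unique, suffix comparisons
never cross a member boundary and the concatenation order equals the
per-member order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Nucleotide alphabet in sort order (sentinels sort below all of these).
ALPHABET = "ACGNT"

#: Internal symbol codes: 0 = sentinel/terminator, 1..5 = A,C,G,N,T.
TERMINATOR_CODE = 0
SYMBOL_CODES = {c: i + 1 for i, c in enumerate(ALPHABET)}
N_CODES = len(ALPHABET) + 1
_DECODE = np.frombuffer(("$" + ALPHABET).encode("ascii"), dtype=np.uint8)

GBWT_FORMAT = "bwtax-gbwt-v1"


class AlphabetError(ValueError):
    """A sequence contains a symbol outside {A,C,G,T,N}."""


class MalformedIndexError(ValueError):
    """A BWT/GSA structure or its serialization is internally inconsistent."""


def encode_sequence(seq: str, identifier: str = "?") -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes 1..5.

    Raises :class:`AlphabetError` naming the offending identifier and
    0-based position on the first invalid symbol.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = np.zeros(raw.size, dtype=np.uint8)
    for sym, code in SYMBOL_CODES.items():
        codes[raw == ord(sym)] = code
    if (codes == 0).any():
        pos = int(np.flatnonzero(codes == 0)[0])
        raise AlphabetError(
            f"sequence {identifier!r} position {pos}: symbol {seq[pos]!r} "
            f"not in alphabet {ALPHABET!r}"
        )
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class QInterval:
    """Closed, 0-based range [b, e] of index positions whose suffixes start
    with some query Q; empty intervals are encoded as ``e = b - 1``."""

    b: int
    e: int

    @property
    def size(self) -> int:
        return max(0, self.e - self.b + 1)

    @property
    def is_empty(self) -> bool:
        return self.e < self.b

    @classmethod
    def empty(cls, b: int = 0) -> "QInterval":
        return cls(b, b - 1)


class SequenceCollection:
    """Ordered collection of uniquely named nucleotide sequences."""

    def __init__(self, members: Sequence[tuple[str, str]]):
        members = list(members)
        seen: set[str] = set()
        for name, seq in members:
            if name in seen:
                raise ValueError(f"duplicate member identifier {name!r}")
            seen.add(name)
            if not seq:
                raise ValueError(f"member {name!r} is empty")
        self.members: list[tuple[str, str]] = members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.members)

    def __getitem__(self, i: int) -> tuple[str, str]:
        return self.members[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SequenceCollection) and self.members == other.members

    @property
    def identifiers(self) -> list[str]:
        return [name for name, _ in self.members]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.members]

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.members)


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling (numpy lexsort).

    The caller guarantees a unique, strictly smallest terminator region per
    member so comparisons resolve before crossing member boundaries; the
    loop terminates as soon as all ranks are distinct, which for
    sentinel-augmented collections happens after O(log(max member length))
    rounds.
    """
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    sa = np.argsort(rank, kind="stable").astype(np.int64)
    k = 1
    while rank[sa[-1]] != n - 1:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1 = rank[sa]
        r2 = key2[sa]
        boundary = np.empty(n, dtype=np.int64)
        boundary[0] = 0
        boundary[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = np.cumsum(boundary)
        k *= 2
    return sa


@dataclass
class GeneralizedBWT:
    """Generalized BWT plus generalized suffix array of a collection.

    Attributes
    ----------
    bwt : uint8 array, length ``total sequence length + member count``;
        code 0 marks a sentinel (the sentinel at position i belongs to
        member ``member_ids[i]``), codes 1..5 are A,C,G,N,T.
    suffix_offsets : the array ``A`` — start offset of the i-th smallest
        suffix within its member (0 .. member length, inclusive; offset
        equal to the member length is the pure-sentinel suffix).
    member_ids : the array ``C`` — member index of the i-th smallest suffix.
    member_lengths : sequence length (without sentinel) per member.
    """

    bwt: np.ndarray
    suffix_offsets: np.ndarray
    member_ids: np.ndarray
    member_lengths: np.ndarray
    _sym_pos: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _first: np.ndarray | None = field(default=None, repr=False)

    @property
    def member_count(self) -> int:
        return int(self.member_lengths.size)

    def __len__(self) -> int:
        return int(self.bwt.size)

    # -- rank machinery -------------------------------------------------

    def symbol_positions(self, code: int) -> np.ndarray:
        """Sorted BWT positions holding symbol ``code`` (cached)."""
        pos = self._sym_pos.get(code)
        if pos is None:
            pos = np.flatnonzero(self.bwt == code)
            self._sym_pos[code] = pos
        return pos

    def rank(self, code: int, i: int) -> int:
        """Occurrences of ``code`` in ``bwt[0:i]``."""
        return int(np.searchsorted(self.symbol_positions(code), i))

    @property
    def first_column(self) -> np.ndarray:
        """``F[c]`` = index of the first suffix starting with symbol code c;
        F has length N_CODES + 1 so ``F[c+1] - F[c]`` is the symbol count."""
        if self._first is None:
            counts = np.bincount(self.bwt, minlength=N_CODES)
            first = np.zeros(N_CODES + 1, dtype=np.int64)
            first[1:] = np.cumsum(counts)
            self._first = first
        return self._first

    # -- search ---------------------------------------------------------

    def symbol_interval(self, code: int) -> QInterval:
        first = self.first_column
        return QInterval(int(first[code]), int(first[code + 1]) - 1)

    def extend_left(self, interval: QInterval, code: int) -> QInterval:
        if not 1 <= code < N_CODES:
            raise AlphabetError(f"symbol code {code} outside nucleotide alphabet")
        if interval.is_empty:
            return QInterval.empty()
        f = int(self.first_column[code])
        b = f + self.rank(code, interval.b)
        e = f + self.rank(code, interval.e + 1) - 1
        return QInterval(b, e) if b <= e else QInterval.empty(b)

    def extend_left_batch(
        self, bs: np.ndarray, es: np.ndarray, code: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`extend_left` over arrays of non-empty intervals."""
        pos = self.symbol_positions(code)
        f = int(self.first_column[code])
        nb = f + np.searchsorted(pos, bs)
        ne = f + np.searchsorted(pos, es + 1) - 1
        return nb, ne


def build_gsa_bwt(collection: SequenceCollection) -> GeneralizedBWT:
    """Build the generalized BWT and generalized suffix array of a collection.

    Suffixes are ordered under ``$1 < ... < $n < A < C < G < N < T`` with
    sentinels ordered by member index; ``bwt[i]`` is the symbol preceding
    the i-th smallest suffix within its member (a member's sentinel
    precedes its full-sequence suffix).
    """
    if len(collection) == 0:
        raise ValueError("cannot build a BWT of an empty collection")
    m = len(collection)
    encoded = [
        encode_sequence(seq, name).astype(np.int64) for name, seq in collection
    ]
    lengths = np.array([c.size for c in encoded], dtype=np.int64)
    total = int(lengths.sum()) + m

    # Global sort codes: sentinel of member j -> j; nucleotide code c -> m+c.
    concat = np.empty(total, dtype=np.int64)
    member_of = np.empty(total, dtype=np.int32)
    offset_of = np.empty(total, dtype=np.int64)
    pos = 0
    for j, codes in enumerate(encoded):
        end = pos + codes.size
        concat[pos:end] = codes + m
        concat[end] = j
        member_of[pos : end + 1] = j
        offset_of[pos : end + 1] = np.arange(codes.size + 1)
        pos = end + 1

    sa = _suffix_array(concat)
    A = offset_of[sa]
    C = member_of[sa]

    bwt = np.empty(total, dtype=np.uint8)
    at_start = A == 0
    bwt[at_start] = TERMINATOR_CODE
    inner = ~at_start
    bwt[inner] = (concat[sa[inner] - 1] - m).astype(np.uint8)
    return GeneralizedBWT(bwt, A, C, lengths)


def invert_bwt(gbwt: GeneralizedBWT) -> list[str]:
    """Recover the member sequences (without sentinels) in original order.

    Only the BWT string, the sentinel-position member labels and the member
    count are consulted; ``A`` is not needed.
    """
    m = gbwt.member_count
    n_term = int((gbwt.bwt == TERMINATOR_CODE).sum())
    if n_term != m:
        raise MalformedIndexError(
            f"BWT holds {n_term} sentinels but declares {m} members"
        )
    first = gbwt.first_column
    out: list[str] = []
    for j in range(m):
        # Row j of the suffix array is the pure-sentinel suffix "$j" of
        # member j; its BWT symbol is the member's last character.
        chars: list[int] = []
        i = j
        while True:
            c = int(gbwt.bwt[i])
            if c == TERMINATOR_CODE:
                break
            chars.append(c)
            i = int(first[c]) + gbwt.rank(c, i)
        out.append(decode_sequence(np.array(chars[::-1], dtype=np.uint8)))
    return out


def backward_search(gbwt: GeneralizedBWT, query: str) -> QInterval:
    """Q-interval of ``query``: the range of suffixes prefixed by it.

    The interval size equals the total occurrence count of the query across
    all members (occurrences never span member boundaries).
    """
    if not query:
        raise ValueError("query must be non-empty")
    codes = encode_sequence(query, "<query>")
    interval = gbwt.symbol_interval(int(codes[-1]))
    for c in codes[-2::-1]:
        if interval.is_empty:
            return QInterval.empty()
        interval = gbwt.extend_left(interval, int(c))
    return interval


def extend_interval_left(
    gbwt: GeneralizedBWT, interval: QInterval, symbol: str
) -> QInterval:
    """Map the Q-interval of Q to the interval of ``symbol + Q``."""
    code = SYMBOL_CODES.get(symbol)
    if code is None:
        raise AlphabetError(f"symbol {symbol!r} not in alphabet {ALPHABET!r}")
    return gbwt.extend_left(interval, code)


def interval_members(
    gbwt: GeneralizedBWT, interval: QInterval
) -> list[tuple[int, int]]:
    """``(C[i], A[i])`` for every position i in the interval."""
    if interval.is_empty:
        return []
    if interval.b < 0 or interval.e >= len(gbwt):
        raise ValueError(
            f"interval [{interval.b}, {interval.e}] out of bounds for index "
            f"of length {len(gbwt)}"
        )
    sl = slice(interval.b, interval.e + 1)
    return list(
        zip(
            (int(x) for x in gbwt.member_ids[sl]),
            (int(x) for x in gbwt.suffix_offsets[sl]),
        )
    )


# -- serialization ------------------------------------------------------
#
# On-disk layout (all plain text, deterministic):
#   meta.json  {"format", "member_count", "member_lengths", "length"}
#   bwt.txt    the BWT string, one symbol per byte, sentinels as '$',
#              terminated by a newline
#   gsa.tsv    header "offset\tmember"; one row per BWT position (A, C)
#   sentinels.tsv  header "position\tmember"; member label of each '$'
#              (the member-boundary table; recomputable from gsa.tsv but
#              stored so bwt.txt + sentinels.tsv alone describe the BWT)


def save_gbwt(gbwt: GeneralizedBWT, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": GBWT_FORMAT,
        "length": len(gbwt),
        "member_count": gbwt.member_count,
        "member_lengths": [int(x) for x in gbwt.member_lengths],
    }
    (path / "meta.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n"
    )
    (path / "bwt.txt").write_text(decode_sequence(gbwt.bwt) + "\n")
    pd.DataFrame(
        {"offset": gbwt.suffix_offsets, "member": gbwt.member_ids}
    ).to_csv(path / "gsa.tsv", sep="\t", index=False)
    term_pos = np.flatnonzero(gbwt.bwt == TERMINATOR_CODE)
    pd.DataFrame(
        {"position": term_pos, "member": gbwt.member_ids[term_pos]}
    ).to_csv(path / "sentinels.tsv", sep="\t", index=False)


def load_gbwt(path: str | Path) -> GeneralizedBWT:
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise MalformedIndexError(f"cannot read index metadata: {exc}") from exc
    if meta.get("format") != GBWT_FORMAT:
        raise MalformedIndexError(
            f"unsupported index format {meta.get('format')!r}; "
            f"expected {GBWT_FORMAT!r}"
        )
    text = (path / "bwt.txt").read_text().rstrip("\n")
    if len(text) != meta["length"]:
        raise MalformedIndexError(
            f"bwt.txt length {len(text)} != declared length {meta['length']}"
        )
    raw = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    bwt = np.zeros(raw.size, dtype=np.uint8)
    for sym, code in SYMBOL_CODES.items():
        bwt[raw == ord(sym)] = code
    bad = (bwt == 0) & (raw != ord("$"))
    if bad.any():
        raise MalformedIndexError("bwt.txt holds symbols outside $ACGNT")
    gsa = pd.read_csv(path / "gsa.tsv", sep="\t")
    if len(gsa) != meta["length"]:
        raise MalformedIndexError("gsa.tsv row count does not match BWT length")
    lengths = np.array(meta["member_lengths"], dtype=np.int64)
    if lengths.size != meta["member_count"]:
        raise MalformedIndexError("member_lengths does not match member_count")
    gbwt = GeneralizedBWT(
        bwt,
        gsa["offset"].to_numpy(dtype=np.int64),
        gsa["member"].to_numpy(dtype=np.int32),
        lengths,
    )
    if int((bwt == TERMINATOR_CODE).sum()) != gbwt.member_count:
        raise MalformedIndexError("sentinel count does not match member count")
    return gbwt


def gbwt_equal(a: GeneralizedBWT, b: GeneralizedBWT) -> bool:
    return (
        np.array_equal(a.bwt, b.bwt)
        and np.array_equal(a.suffix_offsets, b.suffix_offsets)
        and np.array_equal(a.member_ids, b.member_ids)
        and np.array_equal(a.member_lengths, b.member_lengths)
    )
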