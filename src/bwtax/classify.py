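"""Synchronized k-mer traversal and taxonomic classification.

The classifier walks the reference index and the read index in lockstep:
stage s holds the Q-intervals, in lexicographic order, of every s-mer that
occurs in both indexes.  Extending every live interval on the left by each
nucleotide (backward search) produces stage s+1, still in lexicographic
order; because every substring of a shared k-mer is itself shared, pruning
to intervals alive in both indexes loses nothing.  K-mers never span
sequence boundaries — sentinel symbols are simply never extension
candidates.

At stage k each shared k-mer is:

* classified at the deepest taxonomic rank on which *all* reference genomes
  occurring in its interval agree (disagreement already at superkingdom
  leaves it unclassified);
* dropped if it occurs more than once in any single genome, pooling a
  genome's forward and reverse-complement members (the copy-number filter,
  which keeps repeats from inflating abundances — note an even-length
  self-reverse-complementary k-mer at a single site counts once per strand
  and is therefore filtered);
* weighted by its occurrence count across the reads (its read-interval
  size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .bwt import (
    GeneralizedBWT,
    N_CODES,
    QInterval,
    decode_sequence,
    interval_members,
)
from .reference import LEVELS, N_LEVELS, ReferenceIndex

logger = logging.getLogger(__name__)

UNCLASSIFIED = -1


@dataclass(frozen=True)
class SharedKmer:
    """A k-mer present in both the reference and the read index."""

    kmer: str
    ref_interval: QInterval
    read_interval: QInterval


@dataclass(frozen=True)
class KmerClassification:
    """A shared k-mer with its taxonomic assignment and counts.

    ``level`` is the rank index (0 = superkingdom .. 7 = strain);
    ``genome_counts`` pools each genome's forward and reverse-complement
    occurrences.
    """

    kmer: str
    taxon: int
    level: int
    read_count: int
    genome_counts: dict[int, int]


class _Traversal:
    """Arrays describing the shared k-mers of one synchronized traversal."""

    def __init__(
        self,
        k: int,
        ref_b: np.ndarray,
        ref_e: np.ndarray,
        read_b: np.ndarray,
        read_e: np.ndarray,
        syms: list[np.ndarray],
        parents: list[np.ndarray],
    ):
        self.k = k
        self.ref_b = ref_b
        self.ref_e = ref_e
        self.read_b = read_b
        self.read_e = read_e
        self.syms = syms  # per stage, uint8 symbol prepended
        self.parents = parents  # per stage, int64 row in previous stage

    def __len__(self) -> int:
        return int(self.ref_b.size)

    def decode(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Symbol-code matrix (n, k) of the k-mers for ``rows``."""
        if rows is None:
            rows = np.arange(len(self), dtype=np.int64)
        codes = np.empty((rows.size, self.k), dtype=np.uint8)
        idx = rows
        for j in range(self.k - 1, -1, -1):
            codes[:, self.k - 1 - j] = self.syms[j][idx]
            if j > 0:
                idx = self.parents[j][idx]
        return codes


def _traverse_shared(
    ref_gbwt: GeneralizedBWT, read_gbwt: GeneralizedBWT, k: int
) -> _Traversal:
    nucleotides = range(1, N_CODES)
    ref_b = np.empty(0, np.int64)
    ref_e = np.empty(0, np.int64)
    read_b = np.empty(0, np.int64)
    read_e = np.empty(0, np.int64)
    syms: list[np.ndarray] = []
    parents: list[np.ndarray] = []

    # Stage 1: single-nucleotide intervals straight from the first column.
    chunks = []
    for c in nucleotides:
        ri = ref_gbwt.symbol_interval(c)
        qi = read_gbwt.symbol_interval(c)
        if not ri.is_empty and not qi.is_empty:
            chunks.append((c, ri, qi))
    ref_b = np.array([ri.b for _, ri, _ in chunks], np.int64)
    ref_e = np.array([ri.e for _, ri, _ in chunks], np.int64)
    read_b = np.array([qi.b for _, _, qi in chunks], np.int64)
    read_e = np.array([qi.e for _, _, qi in chunks], np.int64)
    syms.append(np.array([c for c, _, _ in chunks], np.uint8))
    parents.append(np.full(len(chunks), -1, np.int64))

    for _stage in range(2, k + 1):
        cand = []
        for c in nucleotides:
            if ref_b.size == 0:
                break
            rb, re = ref_gbwt.extend_left_batch(ref_b, ref_e, c)
            qb, qe = read_gbwt.extend_left_batch(read_b, read_e, c)
            alive = (rb <= re) & (qb <= qe)
            if alive.any():
                rows = np.flatnonzero(alive)
                cand.append(
                    (
                        rb[rows],
                        re[rows],
                        qb[rows],
                        qe[rows],
                        np.full(rows.size, c, np.uint8),
                        rows.astype(np.int64),
                    )
                )
        if not cand:
            ref_b = ref_e = read_b = read_e = np.empty(0, np.int64)
            syms.append(np.empty(0, np.uint8))
            parents.append(np.empty(0, np.int64))
            continue
        ref_b = np.concatenate([c[0] for c in cand])
        ref_e = np.concatenate([c[1] for c in cand])
        read_b = np.concatenate([c[2] for c in cand])
        read_e = np.concatenate([c[3] for c in cand])
        syms.append(np.concatenate([c[4] for c in cand]))
        parents.append(np.concatenate([c[5] for c in cand]))

    return _Traversal(k, ref_b, ref_e, read_b, read_e, syms, parents)


def _check_k(read_gbwt: GeneralizedBWT, k: int) -> None:
    read_length = int(read_gbwt.member_lengths.min())
    if not 1 <= k <= read_length:
        raise ValueError(
            f"k = {k} out of range [1, {read_length}] for reads of length "
            f"{read_length}"
        )


def enumerate_shared_kmers(
    ref: ReferenceIndex, read_gbwt: GeneralizedBWT, k: int
) -> Iterator[SharedKmer]:
    """Yield every k-mer present in both indexes, once, lexicographically."""
    _check_k(read_gbwt, k)
    trav = _traverse_shared(ref.gbwt, read_gbwt, k)
    codes = trav.decode()
    for i in range(len(trav)):
        yield SharedKmer(
            decode_sequence(codes[i]),
            QInterval(int(trav.ref_b[i]), int(trav.ref_e[i])),
            QInterval(int(trav.read_b[i]), int(trav.read_e[i])),
        )


def _interval_genomes(ref: ReferenceIndex, interval: QInterval) -> np.ndarray:
    if interval.is_empty:
        raise ValueError("interval is empty")
    members = ref.gbwt.member_ids[interval.b : interval.e + 1]
    return ref.genome_of_member[members]


def classify_interval(
    ref: ReferenceIndex, interval: QInterval
) -> tuple[int, int]:
    """Deepest rank on which every genome in the interval agrees.

    Returns ``(taxon_id, level)``; ``(UNCLASSIFIED, UNCLASSIFIED)`` when the
    genomes disagree even at superkingdom.
    """
    genomes = _interval_genomes(ref, interval)
    lin = ref.genome_lineages[genomes]
    agree = (lin.min(axis=0) == lin.max(axis=0))
    level = -1
    for lvl in range(N_LEVELS):
        if not agree[lvl]:
            break
        level = lvl
    if level < 0:
        return UNCLASSIFIED, UNCLASSIFIED
    return int(lin[0, level]), level


def genome_occurrence_counts(
    ref: ReferenceIndex, interval: QInterval
) -> dict[int, int]:
    """Occurrences per genome within the interval, both strands pooled."""
    genomes = _interval_genomes(ref, interval)
    uniq, counts = np.unique(genomes, return_counts=True)
    return {int(g): int(c) for g, c in zip(uniq, counts)}


class ClassificationResult:
    """Ordered (lexicographic) classifications of all retained shared k-mers.

    Array attributes (aligned, one entry per retained k-mer): ``taxon``,
    ``level``, ``read_count``, ``ref_count``, ``rep_genome`` (one genome
    carrying the k-mer, used for fast lineage roll-ups).  K-mer strings are
    decoded lazily via :attr:`kmers`.
    """

    def __init__(
        self,
        ref: ReferenceIndex,
        trav: _Traversal,
        kept: np.ndarray,
        taxon: np.ndarray,
        level: np.ndarray,
        rep_genome: np.ndarray,
        summary: dict[str, int],
    ):
        self.ref = ref
        self.k = trav.k
        self._trav = trav
        self._kept = kept
        self.taxon = taxon
        self.level = level
        self.read_count = trav.read_e[kept] - trav.read_b[kept] + 1
        self.ref_count = trav.ref_e[kept] - trav.ref_b[kept] + 1
        self.rep_genome = rep_genome
        self.summary = summary
        self._kmers: list[str] | None = None

    def __len__(self) -> int:
        return int(self._kept.size)

    @property
    def kmers(self) -> list[str]:
        if self._kmers is None:
            codes = self._trav.decode(self._kept)
            self._kmers = [decode_sequence(row) for row in codes]
        return self._kmers

    def ref_interval(self, i: int) -> QInterval:
        j = self._kept[i]
        return QInterval(int(self._trav.ref_b[j]), int(self._trav.ref_e[j]))

    def read_interval(self, i: int) -> QInterval:
        j = self._kept[i]
        return QInterval(int(self._trav.read_b[j]), int(self._trav.read_e[j]))

    def __iter__(self) -> Iterator[KmerClassification]:
        kmers = self.kmers
        for i in range(len(self)):
            yield KmerClassification(
                kmer=kmers[i],
                taxon=int(self.taxon[i]),
                level=int(self.level[i]),
                read_count=int(self.read_count[i]),
                genome_counts=genome_occurrence_counts(
                    self.ref, self.ref_interval(i)
                ),
            )

    def to_frame(self) -> pd.DataFrame:
        names = self.ref.taxonomy.names
        return pd.DataFrame(
            {
                "kmer": self.kmers,
                "taxon_id": self.taxon,
                "taxon_name": [names[int(t)] for t in self.taxon],
                "level_name": [LEVELS[int(l)] for l in self.level],
                "read_count": self.read_count,
                "ref_count": self.ref_count,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify_dataset(
    ref: ReferenceIndex, read_gbwt: GeneralizedBWT, k: int
) -> ClassificationResult:
    """Classify every shared k-mer; drop copy-number violations and
    superkingdom-level disagreements; count read occurrences.

    Output order is lexicographic by k-mer.
    """
    _check_k(read_gbwt, k)
    trav = _traverse_shared(ref.gbwt, read_gbwt, k)
    nk = len(trav)
    if nk == 0:
        return ClassificationResult(
            ref,
            trav,
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            {
                "shared_kmers": 0,
                "copy_filtered": 0,
                "unclassified": 0,
                "classified": 0,
            },
        )

    sizes = trav.ref_e - trav.ref_b + 1
    starts = np.zeros(nk, np.int64)
    np.cumsum(sizes[:-1], out=starts[1:])
    total = int(sizes.sum())
    pos = np.arange(total, dtype=np.int64) - np.repeat(starts, sizes) + np.repeat(
        trav.ref_b, sizes
    )
    genomes = ref.genome_of_member[ref.gbwt.member_ids[pos]].astype(np.int64)
    seg = np.repeat(np.arange(nk, dtype=np.int64), sizes)

    # Copy-number filter: any genome seen twice within one segment.
    order = np.lexsort((genomes, seg))
    g_s = genomes[order]
    seg_s = seg[order]
    adj = (seg_s[1:] == seg_s[:-1]) & (g_s[1:] == g_s[:-1])
    dup = np.zeros(nk, dtype=bool)
    dup[seg_s[1:][adj]] = True

    # LCA classification: deepest rank where min == max across the segment.
    lin = ref.genome_lineages[genomes]
    mins = np.minimum.reduceat(lin, starts, axis=0)
    maxs = np.maximum.reduceat(lin, starts, axis=0)
    agree = np.logical_and.accumulate(mins == maxs, axis=1)
    level = agree.sum(axis=1).astype(np.int64) - 1

    unclassified = level < 0
    keep = ~dup & ~unclassified
    kept = np.flatnonzero(keep)
    lvl = level[kept]
    taxon = lin[starts[kept], lvl]
    rep_genome = genomes[starts[kept]]

    summary = {
        "shared_kmers": nk,
        "copy_filtered": int(dup.sum()),
        "unclassified": int((unclassified & ~dup).sum()),
        "classified": int(kept.size),
    }
    logger.info(
        "k=%d: %d shared k-mers, %d copy-number filtered, %d unclassified, "
        "%d classified",
        k,
        summary["shared_kmers"],
        summary["copy_filtered"],
        summary["unclassified"],
        summary["classified"],
    )
    return ClassificationResult(ref, trav, kept, taxon, lvl, rep_genome, summary)


def assign_reads(
    ref: ReferenceIndex,
    read_gbwt: GeneralizedBWT,
    result: ClassificationResult,
) -> tuple[np.ndarray, np.ndarray]:
    """Optional per-read assignment: each read gets the LCA of the taxa of
    its classified k-mers.

    This secondary output is a declared convention of this package (the
    per-k-mer classification above is the canonical product).  Returns
    ``(taxon, level)`` arrays over reads, ``UNCLASSIFIED`` where a read has
    no classified k-mer.
    """
    n_reads = read_gbwt.member_count
    n = len(result)
    if n == 0:
        full = np.full(n_reads, UNCLASSIFIED, np.int64)
        return full, full.copy()

    # Path matrix per classified k-mer: lineage prefix, -1 beyond its level.
    paths = ref.genome_lineages[result.rep_genome].copy()
    mask = np.arange(N_LEVELS)[None, :] > result.level[:, None]
    paths[mask] = -1

    sizes = np.empty(n, np.int64)
    starts_b = np.empty(n, np.int64)
    for i in range(n):
        iv = result.read_interval(i)
        starts_b[i] = iv.b
        sizes[i] = iv.size
    offs = np.zeros(n, np.int64)
    np.cumsum(sizes[:-1], out=offs[1:])
    total = int(sizes.sum())
    pos = np.arange(total, dtype=np.int64) - np.repeat(offs, sizes) + np.repeat(
        starts_b, sizes
    )
    read_of = read_gbwt.member_ids[pos].astype(np.int64)
    kmer_of = np.repeat(np.arange(n, dtype=np.int64), sizes)

    order = np.argsort(read_of, kind="stable")
    read_s = read_of[order]
    path_s = paths[kmer_of[order]]
    seg_starts = np.flatnonzero(
        np.concatenate([[True], read_s[1:] != read_s[:-1]])
    )
    mins = np.minimum.reduceat(path_s, seg_starts, axis=0)
    maxs = np.maximum.reduceat(path_s, seg_starts, axis=0)
    agree = np.logical_and.accumulate((mins == maxs) & (mins != -1), axis=1)
    lca_level = agree.sum(axis=1).astype(np.int64) - 1
    seg_reads = read_s[seg_starts]

    taxon = np.full(n_reads, UNCLASSIFIED, np.int64)
    level = np.full(n_reads, UNCLASSIFIED, np.int64)
    ok = lca_level >= 0
    taxon[seg_reads[ok]] = mins[np.flatnonzero(ok), lca_level[ok]]
    level[seg_reads[ok]] = lca_level[ok]
    return taxon, level
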