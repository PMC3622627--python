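"""Taxonomy-annotated reference index over genomes and their reverse complements.

The reference side of the classifier is a generalized BWT over every input
record *and* its reverse complement (so read k-mers from either strand match
without canonicalization), joined to an 8-level taxonomy
(superkingdom .. strain).  The taxonomic unit is the strain: FASTA records
sharing a full 8-level lineage are pooled into one "genome", whose length is
the sum of its record lengths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .bwt import (
    ALPHABET,
    GeneralizedBWT,
    SequenceCollection,
    build_gsa_bwt,
    gbwt_equal,
    load_gbwt,
    save_gbwt,
)

logger = logging.getLogger(__name__)

#: The eight taxonomic ranks, shallowest to deepest.
LEVELS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)
N_LEVELS = len(LEVELS)

REF_FORMAT = "bwtax-ref-v1"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TaxonomyError(ValueError):
    """Invalid or inconsistent taxonomy input."""


class TaxonomyTable:
    """Per-sequence 8-level lineages with interned integer taxon ids.

    Names are interned to integers in first-seen order, keyed by
    ``(level, name)`` so a name reused across ranks gets distinct ids.
    Lineages must form a tree: a taxon id always has the same ancestor path
    (the same species may not appear under two genera).
    """

    def __init__(
        self,
        sequence_ids: Sequence[str],
        lineages: np.ndarray,
        names: Mapping[int, str],
    ):
        self.sequence_ids = list(sequence_ids)
        self.lineages = np.asarray(lineages, dtype=np.int64)
        if self.lineages.shape != (len(self.sequence_ids), N_LEVELS):
            raise TaxonomyError(
                f"lineage matrix shape {self.lineages.shape} does not match "
                f"{len(self.sequence_ids)} sequences x {N_LEVELS} levels"
            )
        self.names = dict(names)
        self._row_of = {s: i for i, s in enumerate(self.sequence_ids)}
        if len(self._row_of) != len(self.sequence_ids):
            raise TaxonomyError("duplicate sequence_id in taxonomy")
        # taxon id -> (level, ancestor path up to and including it)
        self._path: dict[int, tuple[int, tuple[int, ...]]] = {}
        for row in self.lineages:
            for lvl in range(N_LEVELS):
                tid = int(row[lvl])
                path = tuple(int(x) for x in row[: lvl + 1])
                prev = self._path.setdefault(tid, (lvl, path))
                if prev != (lvl, path):
                    raise TaxonomyError(
                        f"taxon {self.names.get(tid, tid)!r} appears with "
                        "two different lineages; taxonomy is not a tree"
                    )

    # -- construction ---------------------------------------------------

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, Sequence[str]]]
    ) -> "TaxonomyTable":
        """Build from ``(sequence_id, 8 lineage names)`` rows, interning
        names deterministically in first-seen order."""
        intern: dict[tuple[int, str], int] = {}
        names: dict[int, str] = {}
        seq_ids: list[str] = []
        lineage_rows: list[list[int]] = []
        for row_no, (seq_id, lineage) in enumerate(rows, start=1):
            if len(lineage) != N_LEVELS:
                raise TaxonomyError(
                    f"row {row_no} ({seq_id!r}): expected {N_LEVELS} levels, "
                    f"got {len(lineage)}"
                )
            ids = []
            for lvl, name in enumerate(lineage):
                name = name.strip()
                if not name:
                    raise TaxonomyError(
                        f"row {row_no} ({seq_id!r}): empty {LEVELS[lvl]} name"
                    )
                key = (lvl, name)
                tid = intern.get(key)
                if tid is None:
                    tid = len(intern)
                    intern[key] = tid
                    names[tid] = name
                ids.append(tid)
            if seq_id in {s for s in seq_ids}:
                raise TaxonomyError(f"row {row_no}: duplicate sequence_id {seq_id!r}")
            seq_ids.append(seq_id)
            lineage_rows.append(ids)
        if not seq_ids:
            raise TaxonomyError("taxonomy holds no rows")
        return cls(seq_ids, np.array(lineage_rows, dtype=np.int64), names)

    # -- queries --------------------------------------------------------

    def lineage_of(self, sequence_id: str) -> np.ndarray:
        row = self._row_of.get(sequence_id)
        if row is None:
            raise TaxonomyError(f"unknown sequence_id {sequence_id!r}")
        return self.lineages[row]

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self._row_of

    def level_of(self, taxon_id: int) -> int:
        try:
            return self._path[taxon_id][0]
        except KeyError:
            raise TaxonomyError(f"unknown taxon id {taxon_id}") from None

    def ancestor(self, taxon_id: int, level: int) -> int:
        """Ancestor of ``taxon_id`` at rank index ``level`` (<= its own)."""
        own_level, path = self._path.get(taxon_id, (None, None))
        if path is None:
            raise TaxonomyError(f"unknown taxon id {taxon_id}")
        if level > own_level:
            raise TaxonomyError(
                f"taxon {taxon_id} is at {LEVELS[own_level]}; no descendant "
                f"ancestor at {LEVELS[level]}"
            )
        return path[level]

    def name(self, taxon_id: int) -> str:
        return self.names[taxon_id]

    def subset(self, sequence_ids: Sequence[str]) -> "TaxonomyTable":
        """Row subset that preserves the original taxon-id interning."""
        rows = [self._row_of[s] for s in sequence_ids]
        return TaxonomyTable(
            list(sequence_ids), self.lineages[rows], self.names
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TaxonomyTable)
            and self.sequence_ids == other.sequence_ids
            and np.array_equal(self.lineages, other.lineages)
            and self.names == other.names
        )

    def to_rows(self) -> list[tuple[str, list[str]]]:
        return [
            (sid, [self.names[int(t)] for t in self.lineages[i]])
            for i, sid in enumerate(self.sequence_ids)
        ]


def load_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV: ``sequence_id`` then 8 lineage-name columns
    (superkingdom..strain); a header row starting with ``sequence_id`` is
    accepted; extra columns (e.g. numeric ids) are ignored."""
    path = Path(path)
    rows: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if row_no == 1 and fields[0] == "sequence_id":
                continue
            if len(fields) < 1 + N_LEVELS:
                raise TaxonomyError(
                    f"{path.name} row {row_no}: expected {N_LEVELS} levels "
                    f"after sequence_id, got {len(fields) - 1}"
                )
            rows.append((fields[0], fields[1 : 1 + N_LEVELS]))
    return TaxonomyTable.from_rows(rows)


def save_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\t" + "\t".join(LEVELS) + "\n")
        for sid, names in table.to_rows():
            fh.write(sid + "\t" + "\t".join(names) + "\n")


# -- FASTA --------------------------------------------------------------

_IUPAC_EXTRA = set("RYSWKMBDHVU")


def read_fasta_collection(paths: Iterable[str | Path]) -> SequenceCollection:
    """Read one or more (multi-record, wrapped, case-insensitive) FASTA
    files; IUPAC degeneracy codes other than N are converted to N."""
    members: list[tuple[str, str]] = []
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if any(c in _IUPAC_EXTRA for c in set(seq)):
                n_sub = sum(seq.count(c) for c in _IUPAC_EXTRA)
                logger.warning(
                    "record %s: converted %d degenerate IUPAC symbols to N",
                    rec.id,
                    n_sub,
                )
                seq = "".join("N" if c in _IUPAC_EXTRA else c for c in seq)
            members.append((rec.id, seq))
    if not members:
        raise ValueError("no FASTA records found")
    return SequenceCollection(members)


# -- the reference index ------------------------------------------------


@dataclass
class ReferenceIndex:
    """Generalized BWT over records + reverse complements, with taxonomy.

    Members come in pairs: member ``2r`` is record r forward, ``2r + 1`` its
    reverse complement; ``genome_of_member`` maps members to the pooled
    genome (strain) they belong to.
    """

    gbwt: GeneralizedBWT
    record_ids: list[str]
    genome_of_member: np.ndarray
    taxonomy: TaxonomyTable
    genome_lineages: np.ndarray  # (n_genomes, 8) taxon ids
    genome_lengths: np.ndarray  # forward bp per genome (records summed)
    genome_names: list[str]  # strain name per genome

    @property
    def n_genomes(self) -> int:
        return int(self.genome_lengths.size)

    def mean_genome_length(self, taxon_id: int, level: int) -> float:
        """Mean forward length of ALL reference genomes under a taxon."""
        mask = self.genome_lineages[:, level] == taxon_id
        if not mask.any():
            raise TaxonomyError(
                f"taxon {taxon_id} has no genomes in the reference"
            )
        return float(self.genome_lengths[mask].mean())


def build_reference_index(
    genomes: SequenceCollection,
    taxonomy: TaxonomyTable,
    exclude: Iterable[str] = (),
) -> ReferenceIndex:
    """Index genomes and their reverse complements with taxonomy annotation.

    ``exclude`` drops records (e.g. plasmids) by identifier before indexing.
    Every retained record must have a lineage; records sharing a full
    lineage (same strain) pool into one genome.
    """
    exclude = set(exclude)
    kept = [(n, s) for n, s in genomes if n not in exclude]
    if not kept:
        raise ValueError("no genomes left after exclusion")
    for name, _ in kept:
        if name not in taxonomy:
            raise TaxonomyError(f"genome {name!r} has no lineage in the taxonomy")

    genome_key: dict[tuple[int, ...], int] = {}
    genome_of_record: list[int] = []
    genome_lengths: list[int] = []
    genome_lineages: list[np.ndarray] = []
    genome_names: list[str] = []
    for name, seq in kept:
        lineage = taxonomy.lineage_of(name)
        key = tuple(int(x) for x in lineage)
        g = genome_key.get(key)
        if g is None:
            g = len(genome_key)
            genome_key[key] = g
            genome_lengths.append(0)
            genome_lineages.append(lineage)
            genome_names.append(taxonomy.names[int(lineage[-1])])
        genome_of_record.append(g)
        genome_lengths[g] += len(seq)

    members: list[tuple[str, str]] = []
    genome_of_member: list[int] = []
    for (name, seq), g in zip(kept, genome_of_record):
        members.append((name, seq))
        members.append((name + "|rc", reverse_complement(seq)))
        genome_of_member.extend([g, g])

    gbwt = build_gsa_bwt(SequenceCollection(members))
    return ReferenceIndex(
        gbwt=gbwt,
        record_ids=[n for n, _ in kept],
        genome_of_member=np.array(genome_of_member, dtype=np.int32),
        taxonomy=taxonomy.subset([n for n, _ in kept]),
        genome_lineages=np.vstack(genome_lineages),
        genome_lengths=np.array(genome_lengths, dtype=np.int64),
        genome_names=genome_names,
    )


def save_index(index: ReferenceIndex, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    save_gbwt(index.gbwt, path / "gbwt")
    save_taxonomy(index.taxonomy, path / "taxonomy.tsv")
    meta = {
        "format": REF_FORMAT,
        "record_ids": index.record_ids,
        "genome_of_member": [int(x) for x in index.genome_of_member],
        "genome_lineages": [[int(t) for t in row] for row in index.genome_lineages],
        "genome_lengths": [int(x) for x in index.genome_lengths],
        "genome_names": index.genome_names,
    }
    (path / "reference.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n"
    )


def load_index(path: str | Path) -> ReferenceIndex:
    path = Path(path)
    try:
        meta = json.loads((path / "reference.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read reference metadata: {exc}") from exc
    if meta.get("format") != REF_FORMAT:
        raise ValueError(
            f"unsupported reference format {meta.get('format')!r}; "
            f"expected {REF_FORMAT!r}"
        )
    gbwt = load_gbwt(path / "gbwt")
    taxonomy = load_taxonomy(path / "taxonomy.tsv")
    index = ReferenceIndex(
        gbwt=gbwt,
        record_ids=list(meta["record_ids"]),
        genome_of_member=np.array(meta["genome_of_member"], dtype=np.int32),
        taxonomy=taxonomy,
        genome_lineages=np.array(meta["genome_lineages"], dtype=np.int64),
        genome_lengths=np.array(meta["genome_lengths"], dtype=np.int64),
        genome_names=list(meta["genome_names"]),
    )
    if gbwt.member_count != 2 * len(index.record_ids):
        raise ValueError("reference index is corrupt: member/record mismatch")
    if index.genome_of_member.size != gbwt.member_count:
        raise ValueError("reference index is corrupt: genome_of_member size")
    return index


def index_equal(a: ReferenceIndex, b: ReferenceIndex) -> bool:
    return (
        gbwt_equal(a.gbwt, b.gbwt)
        and a.record_ids == b.record_ids
        and np.array_equal(a.genome_of_member, b.genome_of_member)
        and a.taxonomy == b.taxonomy
        and np.array_equal(a.genome_lineages, b.genome_lineages)
        and np.array_equal(a.genome_lengths, b.genome_lengths)
        and a.genome_names == b.genome_names
    )
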