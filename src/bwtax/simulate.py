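"""Synthetic metagenome communities with known ground truth.

The generator emulates a shotgun-sequencing experiment on a community of
related microbes: reference genomes are evolved top-down along a synthetic
taxonomy (one random ancestor per taxon, children derived by point
substitutions at a per-rank divergence rate, so same-genus species share
detectable sequence while different superkingdoms share none beyond
chance), and reads are drawn from both strands with uniform substitution
errors, at per-organism read counts proportional to cell fraction times
genome length (cell-abundance semantics: a cell of a larger genome yields
proportionally more reads).

Everything is deterministic under the community seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .bwt import SequenceCollection
from .profile import ProfileEntry, TaxonomicProfile, UNCLASSIFIED_ID, UNCLASSIFIED_NAME
from .reads import ReadSet
from .reference import LEVELS, N_LEVELS, TaxonomyError, TaxonomyTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {c: i for i, c in enumerate("ACGT")}

#: Default substitution divergence applied when deriving a child taxon's
#: ancestral sequence from its parent's, per rank of the child.  Rates
#: shrink toward the tips so deeper ranks are harder to tell apart, as in
#: real lineages.
DEFAULT_DIVERGENCE: dict[str, float] = {
    "phylum": 0.35,
    "class": 0.25,
    "order": 0.18,
    "family": 0.12,
    "genus": 0.08,
    "species": 0.04,
    "strain": 0.01,
}


@dataclass(frozen=True)
class CommunityMember:
    """One organism: full 8-level lineage, genome size, cell fraction."""

    lineage: tuple[str, ...]
    genome_length: int
    cell_fraction: float

    def __post_init__(self) -> None:
        if len(self.lineage) != N_LEVELS:
            raise ValueError(
                f"lineage needs {N_LEVELS} levels, got {len(self.lineage)}"
            )
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must be in (0, 1]")


@dataclass
class CommunitySpec:
    """Study conditions for one simulated community."""

    seed: int
    taxa: list[CommunityMember]
    read_length: int = 80
    n_reads: int = 100_000
    error_rate: float = 0.01
    divergence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERGENCE)
    )

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("community holds no taxa")
        total = sum(t.cell_fraction for t in self.taxa)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"cell fractions sum to {total}, expected 1")
        for t in self.taxa:
            if t.genome_length < self.read_length:
                raise ValueError(
                    f"genome of {t.lineage[-1]!r} ({t.genome_length} bp) is "
                    f"shorter than the read length {self.read_length}"
                )
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        rates = [self.divergence[lvl] for lvl in LEVELS[1:]]
        if any(r <= 0 for r in rates):
            raise ValueError("divergence rates must be positive")
        if any(a < b for a, b in zip(rates, rates[1:])):
            raise ValueError(
                "divergence rates must be non-increasing from phylum to strain"
            )
        # Lineages must form a tree (validated by taxonomy interning).
        taxonomy_table(self)

    @classmethod
    def even(
        cls,
        n_species: int = 15,
        seed: int = 0,
        min_length: int = 20_000,
        max_length: int = 200_000,
        read_length: int = 80,
        n_reads: int = 100_000,
        error_rate: float = 0.01,
        species_per_genus: int = 2,
        strains_per_species: int = 1,
    ) -> "CommunitySpec":
        """Even community: one strain per organism, equal cell fractions,
        genome lengths geometrically spanning ``min_length``..``max_length``
        (a >=10x spread by default), species nested pairwise into genera,
        families, orders, classes and phyla under one superkingdom."""
        lengths = np.unique(
            np.geomspace(min_length, max_length, n_species).round().astype(int)
        )
        if lengths.size < n_species:  # collisions after rounding
            lengths = np.linspace(min_length, max_length, n_species).round().astype(int)
        taxa = []
        frac = 1.0 / (n_species * strains_per_species)
        for i in range(n_species):
            genus = i // species_per_genus
            family = genus // 2
            order = family // 2
            klass = order // 2
            phylum = klass // 2
            for s in range(strains_per_species):
                taxa.append(
                    CommunityMember(
                        lineage=(
                            "sk_0",
                            f"phylum_{phylum}",
                            f"class_{klass}",
                            f"order_{order}",
                            f"family_{family}",
                            f"genus_{genus}",
                            f"species_{i}",
                            f"species_{i}_strain_{s}",
                        ),
                        genome_length=int(lengths[i]),
                        cell_fraction=frac,
                    )
                )
        return cls(
            seed=seed,
            taxa=taxa,
            read_length=read_length,
            n_reads=n_reads,
            error_rate=error_rate,
        )


def _sequence_ids(spec: CommunitySpec) -> list[str]:
    width = max(2, len(str(len(spec.taxa) - 1)))
    return [f"genome_{i:0{width}d}" for i in range(len(spec.taxa))]


def taxonomy_table(spec: CommunitySpec) -> TaxonomyTable:
    """The taxonomy implied by the community spec (deterministic ids)."""
    return TaxonomyTable.from_rows(
        (sid, list(t.lineage))
        for sid, t in zip(_sequence_ids(spec), spec.taxa)
    )


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(out.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def simulate_reference_set(
    spec: CommunitySpec,
) -> tuple[SequenceCollection, TaxonomyTable]:
    """Generate the community's genomes and taxonomy.

    One ancestral sequence is drawn per distinct taxon at each rank
    (processed shallow to deep, in first-seen order); each child's ancestor
    is a point-substituted copy of its parent's at the child rank's
    divergence rate, truncated to the longest genome beneath it.  Strain
    ancestors, truncated to their genome length, are the genomes.
    """
    taxonomy = taxonomy_table(spec)
    rng = np.random.default_rng([0, spec.seed])

    # Longest genome under every lineage prefix (ancestor length budget).
    max_under: dict[tuple[str, ...], int] = {}
    for t in spec.taxa:
        for lvl in range(N_LEVELS):
            key = t.lineage[: lvl + 1]
            max_under[key] = max(max_under.get(key, 0), t.genome_length)

    ancestors: dict[tuple[str, ...], np.ndarray] = {}
    for lvl in range(N_LEVELS):
        seen: set[tuple[str, ...]] = set()
        for t in spec.taxa:
            key = t.lineage[: lvl + 1]
            if key in seen:
                continue
            seen.add(key)
            length = max_under[key]
            if lvl == 0:
                ancestors[key] = rng.integers(0, 4, size=length, dtype=np.uint8)
            else:
                parent = ancestors[key[:-1]]
                rate = spec.divergence[LEVELS[lvl]]
                ancestors[key] = _mutate(parent[:length], rate, rng)

    members = []
    for sid, t in zip(_sequence_ids(spec), spec.taxa):
        codes = ancestors[t.lineage][: t.genome_length]
        members.append((sid, _BASES[codes].tobytes().decode("ascii")))
    return SequenceCollection(members), taxonomy


@dataclass
class SimulatedReads(ReadSet):
    """Reads plus per-read provenance (true source genome, position, strand)."""

    source_genome: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    start: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    strand: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))


def simulate_reads(
    genomes: SequenceCollection, spec: CommunitySpec
) -> SimulatedReads:
    """Draw shotgun reads: source genome with probability proportional to
    cell fraction x genome length, uniform start, uniform strand, i.i.d.
    substitution errors at ``spec.error_rate``."""
    if len(genomes) != len(spec.taxa):
        raise ValueError("genome collection does not match the community spec")
    L = spec.read_length
    lengths = np.array([len(s) for _, s in genomes], dtype=np.int64)
    if (lengths < L).any():
        short = genomes.identifiers[int(np.argmin(lengths))]
        raise ValueError(f"genome {short!r} is shorter than the read length")
    fracs = np.array([t.cell_fraction for t in spec.taxa])
    weights = fracs * lengths
    weights = weights / weights.sum()

    rng = np.random.default_rng([1, spec.seed])
    n = spec.n_reads
    src = rng.choice(len(genomes), size=n, p=weights)
    starts = np.floor(rng.random(n) * (lengths[src] - L + 1)).astype(np.int64)
    strand = (rng.random(n) < 0.5).astype(np.int8)

    # Gather read windows from the concatenated genome codes.
    offsets = np.zeros(len(genomes), dtype=np.int64)
    np.cumsum(lengths[:-1], out=offsets[1:])
    concat = np.empty(int(lengths.sum()), dtype=np.uint8)
    for j, (_, seq) in enumerate(genomes):
        concat[offsets[j] : offsets[j] + lengths[j]] = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8
        )
    code_of = np.zeros(256, dtype=np.uint8)
    for b, c in _CODE_OF.items():
        code_of[ord(b)] = c
    concat = code_of[concat]

    mat = concat[(offsets[src] + starts)[:, None] + np.arange(L)[None, :]]
    rc = strand == 1
    mat[rc] = 3 - mat[rc][:, ::-1]
    err = rng.random((n, L)) < spec.error_rate
    n_err = int(err.sum())
    if n_err:
        mat[err] = (mat[err] + rng.integers(1, 4, size=n_err)) % 4

    data = _BASES[mat].tobytes()
    width = len(str(n - 1))
    reads = [
        (f"read_{i:0{width}d}", data[i * L : (i + 1) * L].decode("ascii"))
        for i in range(n)
    ]
    return SimulatedReads(
        reads=reads,
        read_length=L,
        source_genome=src.astype(np.int64),
        start=starts,
        strand=strand,
    )


def true_profile(
    spec: CommunitySpec,
    level: str,
    taxonomy: TaxonomyTable | None = None,
) -> TaxonomicProfile:
    """Ground-truth cell-fraction profile at one rank, percent scale."""
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    lvl = LEVELS.index(level)
    if taxonomy is None:
        taxonomy = taxonomy_table(spec)
    fractions: dict[int, float] = {}
    for sid, t in zip(_sequence_ids(spec), spec.taxa):
        taxon = int(taxonomy.lineage_of(sid)[lvl])
        fractions[taxon] = fractions.get(taxon, 0.0) + t.cell_fraction
    entries = {
        t: ProfileEntry(0.0, f, 100.0 * f) for t, f in fractions.items()
    }
    return TaxonomicProfile(level, entries, dict(taxonomy.names))


def mask_species(
    genomes: SequenceCollection,
    taxonomy: TaxonomyTable,
    species: Iterable[int | str],
) -> tuple[SequenceCollection, TaxonomyTable]:
    """Remove every genome whose lineage contains a masked species (reads
    are untouched); taxon ids of the survivors are preserved."""
    species_level = LEVELS.index("species")
    ids: set[int] = set()
    for s in species:
        if isinstance(s, str):
            matches = {
                int(row[species_level])
                for row in taxonomy.lineages
                if taxonomy.names[int(row[species_level])] == s
            }
            if not matches:
                raise TaxonomyError(f"no species named {s!r} in the taxonomy")
            ids |= matches
        else:
            if taxonomy.level_of(int(s)) != species_level:
                raise TaxonomyError(f"taxon {s} is not a species")
            ids.add(int(s))
    kept = [
        (name, seq)
        for name, seq in genomes
        if int(taxonomy.lineage_of(name)[species_level]) not in ids
    ]
    if not kept:
        raise ValueError("masking removed every genome")
    return (
        SequenceCollection(kept),
        taxonomy.subset([name for name, _ in kept]),
    )


# -- file emission ------------------------------------------------------


def write_fasta(collection: SequenceCollection, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in collection:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    qual = "I" * reads.read_length
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def spec_from_dict(config: dict) -> CommunitySpec:
    """Build a :class:`CommunitySpec` from a parsed YAML/JSON mapping.

    Either an explicit ``taxa`` list (entries with ``lineage``,
    ``genome_length``, ``cell_fraction``) or an ``even`` shortcut mapping
    passed to :meth:`CommunitySpec.even`.
    """
    config = dict(config)
    seed = int(config.pop("seed", 0))
    even = config.pop("even", None)
    taxa_cfg = config.pop("taxa", None)
    if (even is None) == (taxa_cfg is None):
        raise ValueError("config needs exactly one of 'taxa' or 'even'")
    if even is not None:
        return CommunitySpec.even(seed=seed, **even, **config)
    taxa = [
        CommunityMember(
            lineage=tuple(t["lineage"]),
            genome_length=int(t["genome_length"]),
            cell_fraction=float(t["cell_fraction"]),
        )
        for t in taxa_cfg
    ]
    return CommunitySpec(seed=seed, taxa=taxa, **config)
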