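"""Taxonomic profiles: aggregation, genome-length normalization, distances.

Read counts of classified k-mers are rolled up to a chosen rank, divided by
the mean length of the reference genomes under each taxon (so the profile
reflects cell abundance rather than sequenced-base abundance), and rescaled
to percent fractions.  Profiles are compared by Euclidean distance on the
percent scale; an explicit "unclassified" bucket — k-mers classified only
above the requested rank — can optionally be included, since whether such
mass should enter the distance is a reporting convention, not a property of
the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classify import ClassificationResult, KmerClassification
from .reference import LEVELS, ReferenceIndex, TaxonomyError, TaxonomyTable

#: Pseudo-taxon id for mass not classified at the requested rank.
UNCLASSIFIED_ID = -1
UNCLASSIFIED_NAME = "unclassified"


@dataclass(frozen=True)
class ProfileEntry:
    raw_count: float
    normalized: float
    fraction: float  # percent


@dataclass
class TaxonomicProfile:
    """Per-rank abundance table: taxon id -> (raw, normalized, percent)."""

    level: str
    entries: dict[int, ProfileEntry]
    names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def fractions(self) -> dict[int, float]:
        return {t: e.fraction for t, e in self.entries.items()}

    def fraction_of(self, taxon_id: int) -> float:
        e = self.entries.get(taxon_id)
        return e.fraction if e is not None else 0.0

    def name_of(self, taxon_id: int) -> str:
        if taxon_id == UNCLASSIFIED_ID:
            return UNCLASSIFIED_NAME
        if self.names and taxon_id in self.names:
            return self.names[taxon_id]
        return str(taxon_id)


def _level_index(level: str) -> int:
    try:
        return LEVELS.index(level)
    except ValueError:
        raise ValueError(
            f"unknown level {level!r}; expected one of {', '.join(LEVELS)}"
        ) from None


def aggregate_by_level(
    classifications: ClassificationResult | Iterable[KmerClassification],
    taxonomy: TaxonomyTable,
    level: str | int,
) -> dict[int, int]:
    """Roll read counts up to one rank.

    A k-mer classified at a rank at least as deep as ``level`` contributes
    its read count to its lineage's ancestor at ``level``; k-mers classified
    only at shallower ranks contribute nothing here.
    """
    lvl = _level_index(level) if isinstance(level, str) else level
    counts: dict[int, int] = {}
    if isinstance(classifications, ClassificationResult):
        mask = classifications.level >= lvl
        if mask.any():
            # rep_genome carries a full lineage containing the k-mer's taxon.
            lineages = classifications.ref.genome_lineages[
                classifications.rep_genome[mask], lvl
            ]
            read_counts = classifications.read_count[mask]
            for t in np.unique(lineages):
                counts[int(t)] = int(read_counts[lineages == t].sum())
        return counts
    for c in classifications:
        if c.level < lvl:
            continue
        ancestor = taxonomy.ancestor(c.taxon, lvl)
        counts[ancestor] = counts.get(ancestor, 0) + c.read_count
    return counts


def normalize_by_genome_length(
    counts: Mapping[int, float],
    taxonomy: TaxonomyTable,
    genome_lineages: np.ndarray,
    genome_lengths: np.ndarray,
) -> dict[int, float]:
    """Divide each taxon's count by the mean length of ALL reference genomes
    under that taxon (sample-independent divisor)."""
    out: dict[int, float] = {}
    for taxon, raw in counts.items():
        lvl = taxonomy.level_of(taxon)
        mask = genome_lineages[:, lvl] == taxon
        if not mask.any():
            raise TaxonomyError(f"taxon {taxon} has no genomes in the reference")
        out[taxon] = float(raw) / float(genome_lengths[mask].mean())
    return out


def to_fractions(normalized: Mapping[int, float]) -> dict[int, float]:
    """Rescale non-negative values to percent fractions summing to 100."""
    total = float(sum(normalized.values()))
    if total <= 0:
        raise ValueError("cannot form fractions: all values are zero")
    return {t: 100.0 * v / total for t, v in normalized.items()}


def build_profile(
    classifications: ClassificationResult | Iterable[KmerClassification],
    ref: ReferenceIndex,
    level: str,
    include_unclassified: bool = False,
) -> TaxonomicProfile:
    """Aggregate, length-normalize and rescale classifications to a profile.

    With ``include_unclassified``, read counts of k-mers classified only
    above ``level`` form an explicit bucket, normalized by the mean length
    of all reference genomes.
    """
    lvl = _level_index(level)
    counts = aggregate_by_level(classifications, ref.taxonomy, lvl)
    normalized = normalize_by_genome_length(
        counts, ref.taxonomy, ref.genome_lineages, ref.genome_lengths
    )
    raw: dict[int, float] = {t: float(c) for t, c in counts.items()}
    if include_unclassified:
        if isinstance(classifications, ClassificationResult):
            shallow = int(
                classifications.read_count[classifications.level < lvl].sum()
            )
        else:
            shallow = sum(
                c.read_count for c in classifications if c.level < lvl
            )
        if shallow:
            raw[UNCLASSIFIED_ID] = float(shallow)
            normalized[UNCLASSIFIED_ID] = shallow / float(
                ref.genome_lengths.mean()
            )
    fractions = to_fractions(normalized)
    entries = {
        t: ProfileEntry(raw.get(t, 0.0), normalized[t], fractions[t])
        for t in normalized
    }
    names = dict(ref.taxonomy.names)
    names[UNCLASSIFIED_ID] = UNCLASSIFIED_NAME
    return TaxonomicProfile(level, entries, names)


def euclidean_distance(p: TaxonomicProfile, q: TaxonomicProfile) -> float:
    """Euclidean distance between percent-fraction profiles of one rank,
    over the union of taxa (missing entries count as 0)."""
    if p.level != q.level:
        raise ValueError(
            f"profiles are at different levels ({p.level!r} vs {q.level!r})"
        )
    taxa = set(p.entries) | set(q.entries)
    return math.sqrt(
        sum((p.fraction_of(t) - q.fraction_of(t)) ** 2 for t in taxa)
    )


# -- TSV round trip -----------------------------------------------------


def write_profile_tsv(profile: TaxonomicProfile, path: str | Path) -> None:
    taxa = sorted(profile.entries, key=lambda t: (-profile.entries[t].fraction, t))
    pd.DataFrame(
        {
            "level": [profile.level] * len(taxa),
            "taxon_id": taxa,
            "taxon_name": [profile.name_of(t) for t in taxa],
            "raw_count": [profile.entries[t].raw_count for t in taxa],
            "normalized": [profile.entries[t].normalized for t in taxa],
            "fraction_percent": [profile.entries[t].fraction for t in taxa],
        }
    ).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> TaxonomicProfile:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"profile {path} holds no rows")
    levels = df["level"].unique()
    if len(levels) != 1:
        raise ValueError(f"profile {path} mixes levels {levels}")
    entries = {
        int(r.taxon_id): ProfileEntry(
            float(r.raw_count), float(r.normalized), float(r.fraction_percent)
        )
        for r in df.itertuples()
    }
    names = {int(r.taxon_id): str(r.taxon_name) for r in df.itertuples()}
    return TaxonomicProfile(str(levels[0]), entries, names)
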