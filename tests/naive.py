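"""Independent brute-force oracles used to check the BWT index and the
classifier.  Everything here works by explicit enumeration over Python
strings and dicts — no suffix arrays, no interval propagation — so it stays
independent of the code paths it verifies."""

from __future__ import annotations

from collections import Counter

# Sentinels sort below the nucleotide alphabet, ordered by member index;
# nucleotides sort A < C < G < N < T (ASCII order, which Python gives us).
_SYM_ORDER = {c: i for i, c in enumerate("ACGNT")}

LEVEL_COUNT = 8


def suffix_sort(members: list[tuple[str, str]]) -> list[tuple[int, int]]:
    """All (member, offset) suffixes, sorted with per-member sentinels."""
    m = len(members)
    entries = []
    for j, (_, seq) in enumerate(members):
        for off in range(len(seq) + 1):
            key = tuple(m + _SYM_ORDER[c] for c in seq[off:]) + (j,)
            entries.append((key, j, off))
    entries.sort()
    return [(j, off) for _, j, off in entries]


def gbwt_arrays(members: list[tuple[str, str]]):
    """(bwt string with '$' sentinels, A, C) via plain suffix enumeration."""
    order = suffix_sort(members)
    bwt = []
    for j, off in order:
        seq = members[j][1]
        bwt.append("$" if off == 0 else seq[off - 1])
    return "".join(bwt), [off for _, off in order], [j for j, _ in order]


def count_occurrences(members: list[tuple[str, str]], query: str) -> int:
    """Occurrences of query across all members, overlaps included."""
    total = 0
    for _, seq in members:
        total += sum(
            seq[i : i + len(query)] == query
            for i in range(len(seq) - len(query) + 1)
        )
    return total


def members_containing(
    members: list[tuple[str, str]], query: str
) -> Counter:
    """Multiset of member indices, one entry per occurrence of query."""
    out: Counter = Counter()
    for j, (_, seq) in enumerate(members):
        n = sum(
            seq[i : i + len(query)] == query
            for i in range(len(seq) - len(query) + 1)
        )
        if n:
            out[j] += n
    return out


def kmer_counts(seqs: list[str], k: int) -> Counter:
    out: Counter = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            out[seq[i : i + k]] += 1
    return out


_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def classify_kmers(
    genome_seqs: dict[int, list[str]],
    lineages: dict[int, tuple[int, ...]],
    read_seqs: list[str],
    k: int,
) -> list[dict]:
    """Hash-table + explicit-lineage-LCA reimplementation of the classifier.

    genome_seqs maps genome index -> its record sequences (forward only;
    both strands are counted here); lineages maps genome index -> 8 taxon
    ids.  Returns, lexicographically by k-mer, dicts with keys kmer, taxon,
    level, read_count, genome_counts — k-mers repeated within any single
    genome or disagreeing at superkingdom are dropped, as the classifier
    specifies.
    """
    per_genome: dict[int, Counter] = {
        g: kmer_counts(seqs + [revcomp(s) for s in seqs], k)
        for g, seqs in genome_seqs.items()
    }
    ref_kmers = set()
    for c in per_genome.values():
        ref_kmers |= set(c)
    read_kmer_counts = kmer_counts(read_seqs, k)

    out = []
    for kmer in sorted(set(read_kmer_counts) & ref_kmers):
        genome_counts = {
            g: c[kmer] for g, c in per_genome.items() if c[kmer] > 0
        }
        if max(genome_counts.values()) > 1:
            continue
        lins = [lineages[g] for g in genome_counts]
        level = -1
        for lvl in range(LEVEL_COUNT):
            if len({lin[lvl] for lin in lins}) != 1:
                break
            level = lvl
        if level < 0:
            continue
        out.append(
            {
                "kmer": kmer,
                "taxon": lins[0][level],
                "level": level,
                "read_count": read_kmer_counts[kmer],
                "genome_counts": genome_counts,
            }
        )
    return out
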