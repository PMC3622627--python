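"""The synchronized traversal and per-k-mer taxonomic classification."""

from collections import Counter

import numpy as np
import pytest

from bwtax.bwt import QInterval, SequenceCollection, backward_search
from bwtax.classify import (
    UNCLASSIFIED,
    assign_reads,
    classify_dataset,
    classify_interval,
    enumerate_shared_kmers,
    genome_occurrence_counts,
)
from bwtax.reads import from_sequences, build_read_index
from bwtax.reference import TaxonomyTable, build_reference_index
from naive import classify_kmers, kmer_counts, revcomp


def lineage(sk="B", phylum="p1", genus="g1", species="s1", strain="t1"):
    return [sk, phylum, "c1", "o1", "f1", genus, species, strain]


def make_ref(named_seqs, lineages):
    tab = TaxonomyTable.from_rows(list(zip([n for n, _ in named_seqs], lineages)))
    return build_reference_index(SequenceCollection(named_seqs), tab)


def ref_interval(ref, q):
    return backward_search(ref.gbwt, q)


# -- shared k-mer enumeration -------------------------------------------


def test_single_shared_kmer_worked_example():
    ref = make_ref([("g1", "ACGT")], [lineage()])
    rbwt = build_read_index(from_sequences(["CGT"]))
    shared = list(enumerate_shared_kmers(ref, rbwt, 3))
    assert [s.kmer for s in shared] == ["CGT"]
    assert shared[0].ref_interval.size == 2  # both strands of the palindrome
    assert shared[0].read_interval.size == 1


def test_no_shared_kmers_gives_empty_stream():
    ref = make_ref([("g1", "AAAA")], [lineage()])
    rbwt = build_read_index(from_sequences(["TTTG"]))
    assert list(enumerate_shared_kmers(ref, rbwt, 4)) == []


def test_k_out_of_range_rejected():
    ref = make_ref([("g1", "ACGTACG")], [lineage()])
    rbwt = build_read_index(from_sequences(["ACGT"]))
    for k in (0, 5):
        with pytest.raises(ValueError):
            list(enumerate_shared_kmers(ref, rbwt, k))


def test_shared_set_equals_naive_intersection(rng):
    """Emitted k-mers = (k-mers of reads) ∩ (k-mers of genomes ∪ RCs),
    lexicographically ordered, with exact interval sizes."""
    for trial in range(25):
        n_g = int(rng.integers(1, 4))
        genomes = [
            (f"g{j}", "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 120)))))
            for j in range(n_g)
        ]
        lineages = [
            lineage(genus=f"gen{j // 2}", species=f"sp{j}", strain=f"st{j}")
            for j in range(n_g)
        ]
        ref = make_ref(genomes, lineages)
        reads = [
            "".join(rng.choice(list("ACGT"), size=20)) for _ in range(10)
        ] + [genomes[0][1][:20]]
        rbwt = build_read_index(from_sequences(reads))
        k = int(rng.integers(3, 9))
        shared = list(enumerate_shared_kmers(ref, rbwt, k))
        got = [s.kmer for s in shared]
        ref_kmers = set()
        for _, seq in genomes:
            ref_kmers |= set(kmer_counts([seq, revcomp(seq)], k))
        expect = sorted(set(kmer_counts(reads, k)) & ref_kmers)
        assert got == expect
        for s in shared:
            assert s.read_interval.size == kmer_counts(reads, k)[s.kmer]


# -- interval classification --------------------------------------------


def test_single_genome_interval_is_strain_level():
    ref = make_ref([("g1", "ACGTTACG")], [lineage()])
    taxon, level = classify_interval(ref, ref_interval(ref, "ACG"))
    assert level == 7
    assert ref.taxonomy.names[taxon] == "t1"


def test_genus_shared_species_split():
    seq = "ACGTACGTTT"
    ref = make_ref(
        [("g1", seq), ("g2", seq)],
        [
            lineage(species="sA", strain="tA"),
            lineage(species="sB", strain="tB"),
        ],
    )
    taxon, level = classify_interval(ref, ref_interval(ref, "CGTAC"))
    assert level == 5
    assert ref.taxonomy.names[taxon] == "g1"


def test_superkingdom_disagreement_is_unclassified():
    seq = "ACGTACGT"
    ref = make_ref(
        [("g1", seq), ("g2", seq)],
        [
            lineage(sk="B", species="sA", strain="tA"),
            ["A", "p2", "c2", "o2", "f2", "g2", "sB", "tB"],
        ],
    )
    assert classify_interval(ref, ref_interval(ref, "ACGT")) == (
        UNCLASSIFIED,
        UNCLASSIFIED,
    )


def test_empty_interval_rejected():
    ref = make_ref([("g1", "ACGT")], [lineage()])
    with pytest.raises(ValueError):
        classify_interval(ref, QInterval.empty())
    with pytest.raises(ValueError):
        genome_occurrence_counts(ref, QInterval.empty())


# -- genome occurrence counts -------------------------------------------


def test_occurrence_counts_pool_strands():
    ref = make_ref([("g1", "AACAA")], [lineage()])
    iv = ref_interval(ref, "AA")
    # forward positions 0 and 3; RC strand "TTGTT" holds no AA
    assert genome_occurrence_counts(ref, iv) == {0: 2}
    # TT occurs only on the RC strand, twice
    assert genome_occurrence_counts(ref, ref_interval(ref, "TT")) == {0: 2}


def test_occurrence_counts_across_genomes_sum_to_interval_size(rng):
    genomes = [
        ("g1", "".join(rng.choice(list("ACGT"), size=60))),
        ("g2", "".join(rng.choice(list("ACGT"), size=60))),
    ]
    ref = make_ref(
        genomes,
        [lineage(species="sA", strain="tA"), lineage(species="sB", strain="tB")],
    )
    for _ in range(20):
        i = int(rng.integers(0, 58))
        q = genomes[0][1][i : i + 3]
        iv = ref_interval(ref, q)
        counts = genome_occurrence_counts(ref, iv)
        assert sum(counts.values()) == iv.size


# -- full dataset classification ----------------------------------------


def test_error_free_single_genome_reads_classify_at_strain(rng):
    genome = "".join(rng.choice(list("ACGT"), size=400))
    ref = make_ref([("g1", genome)], [lineage()])
    reads = [genome[i : i + 40] for i in range(0, 360, 13)]
    rbwt = build_read_index(from_sequences(reads))
    k = 38
    result = classify_dataset(ref, rbwt, k)
    assert len(result) > 0
    assert (result.level == 7).all()
    # Total read-weighted count equals the read k-mer occurrences that are
    # present in the genome (all of them here) and copy-unique.
    oracle = classify_kmers({0: [genome]}, {0: tuple(range(8))}, reads, k)
    assert int(result.read_count.sum()) == sum(o["read_count"] for o in oracle)


def test_copy_number_filter_drops_repeated_kmer():
    # "ACGT" occurs twice in g1 via the embedded tandem repeat.
    ref = make_ref([("g1", "TTACGTACGTTT")], [lineage()])
    rbwt = build_read_index(from_sequences(["TACGTA", "ACGTTT"]))
    result = classify_dataset(ref, rbwt, 4)
    assert "ACGT" not in result.kmers
    assert result.summary["copy_filtered"] >= 1
    # k-mers unique in the genome (strands pooled) still classify
    assert result.kmers == ["CGTT", "GTTT"]


def test_empty_intersection_gives_empty_result():
    ref = make_ref([("g1", "AAAAAA")], [lineage()])
    rbwt = build_read_index(from_sequences(["GGGGG"]))
    result = classify_dataset(ref, rbwt, 5)
    assert len(result) == 0
    assert result.summary["shared_kmers"] == 0


def _random_instance(rng, n_genomes=3, genome_len=300, n_reads=40, read_len=30):
    genomes = {}
    lineages = {}
    seqs = []
    for j in range(n_genomes):
        seq = "".join(rng.choice(list("ACGT"), size=genome_len))
        genomes[j] = [seq]
        seqs.append(seq)
        lineages[j] = (
            0, j // 4, j // 4, j // 4, j // 2, j // 2, j, 10 + j,
        )
    reads = []
    for _ in range(n_reads):
        j = int(rng.integers(0, n_genomes))
        i = int(rng.integers(0, genome_len - read_len + 1))
        r = seqs[j][i : i + read_len]
        if rng.random() < 0.5:
            r = revcomp(r)
        reads.append(r)
    return genomes, lineages, reads


def _run_both(genomes, lineages, reads, k):
    names = []
    rows = []
    for j, seqs in genomes.items():
        lin = [f"L{lvl}_{lineages[j][lvl]}" for lvl in range(8)]
        for i, seq in enumerate(seqs):
            names.append((f"g{j}_{i}", seq))
            rows.append((f"g{j}_{i}", lin))
    tab = TaxonomyTable.from_rows(rows)
    ref = build_reference_index(SequenceCollection(names), tab)
    rbwt = build_read_index(from_sequences(reads))
    result = classify_dataset(ref, rbwt, k)
    oracle = classify_kmers(genomes, lineages, [r for r in reads], k)
    return ref, result, oracle


def assert_matches_oracle(ref, result, oracle):
    assert result.kmers == [o["kmer"] for o in oracle]
    assert result.read_count.tolist() == [o["read_count"] for o in oracle]
    assert result.level.tolist() == [o["level"] for o in oracle]
    # taxon ids are interned differently; compare via names
    got_names = [ref.taxonomy.names[int(t)] for t in result.taxon]
    expect_names = [f"L{o['level']}_{o['taxon']}" for o in oracle]
    assert got_names == expect_names
    for i, o in enumerate(oracle):
        got_counts = genome_occurrence_counts(ref, result.ref_interval(i))
        # genome indices coincide (insertion order) on these fixtures
        assert got_counts == o["genome_counts"]


def test_oracle_equivalence_randomized(rng):
    for _ in range(10):
        genomes, lineages, reads = _random_instance(rng)
        k = int(rng.integers(4, 13))
        ref, result, oracle = _run_both(genomes, lineages, reads, k)
        assert_matches_oracle(ref, result, oracle)


def test_strand_invariance_of_taxon_totals(rng):
    genomes, lineages, reads = _random_instance(rng, n_genomes=4)
    k = 8
    _, fwd, _ = _run_both(genomes, lineages, reads, k)
    _, rev, _ = _run_both(genomes, lineages, [revcomp(r) for r in reads], k)

    def totals(res):
        agg = Counter()
        for t, l, c in zip(res.taxon, res.level, res.read_count):
            agg[(res.ref.taxonomy.names[int(t)], int(l))] += int(c)
        return agg

    assert totals(fwd) == totals(rev)


def test_specificity_monotone_in_k(rng):
    """Error-free reads from one strain: the strain-level fraction of
    classified k-mers never falls as k grows."""
    base = "".join(rng.choice(list("ACGT"), size=500))
    # sibling strain: 2% diverged copy
    sib = list(base)
    for i in rng.choice(500, size=10, replace=False):
        sib[i] = "ACGT"[(("ACGT".index(sib[i])) + 1) % 4]
    sib = "".join(sib)
    ref = make_ref(
        [("g1", base), ("g2", sib)],
        [lineage(strain="tA"), lineage(strain="tB")],
    )
    reads = [base[i : i + 40] for i in range(0, 460, 7)]
    rbwt = build_read_index(from_sequences(reads))
    fractions = []
    for k in (8, 16, 24, 32, 40):
        res = classify_dataset(ref, rbwt, k)
        if len(res) == 0:
            break
        fractions.append(float((res.level == 7).mean()))
    assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))


def test_tandem_duplication_never_raises_counts(rng):
    """Filter soundness: duplicating a region cannot inflate a genome's
    aggregated read-weighted counts."""
    genome = "".join(rng.choice(list("ACGT"), size=600))
    dup = genome[:300] + genome[200:300] + genome[300:]
    reads = [genome[i : i + 40] for i in range(0, 560, 9)]
    rbwt = build_read_index(from_sequences(reads))
    k = 20

    def total(seq):
        ref = make_ref([("g1", seq)], [lineage()])
        res = classify_dataset(ref, build_read_index(from_sequences(reads)), k)
        return int(res.read_count.sum())

    assert total(dup) <= total(genome)


def test_assign_reads_lca(rng):
    genomes, lineages, reads = _random_instance(rng, n_genomes=2, n_reads=25)
    ref, result, _ = _run_both(genomes, lineages, reads, 12)
    taxon, level = assign_reads(ref, build_read_index(from_sequences(reads)), result)
    assert taxon.shape == (len(reads),)
    assigned = taxon >= 0
    assert assigned.any()
    # every assigned taxon exists at the reported level
    for t, l in zip(taxon[assigned], level[assigned]):
        assert ref.taxonomy.level_of(int(t)) == int(l)
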