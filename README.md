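# bwtax

Taxonomic classification and abundance profiling of environmental shotgun
sequencing (ESS) reads, built on Burrows-Wheeler indexes of **both** the
reference genomes and the reads themselves.

Metagenomic samples mix DNA from many organisms at unknown abundances.
`bwtax` answers "who is there, and in what proportion?" for communities of
reasonably well-characterized microbes: it matches every k-mer of the read
set against a database of reference genomes and assigns each k-mer to the
most specific taxonomic rank it can support, then converts the matched
counts into genome-length-corrected relative abundances. It is aimed at
method developers and analysts who want a transparent, fully inspectable
exact-matching classifier with ground-truth simulation built in.

## Method

* **Reference index.** The genomes g_1..g_m *and* their reverse complements
  are concatenated, each terminated by a distinct sentinel
  `$_1 < ... < $_n` below the nucleotide alphabet `A < C < G < N < T`, and
  suffix-sorted into a generalized BWT plus generalized suffix array: arrays
  `A` (suffix offset) and `C` (member of origin) record, for every BWT
  position, which sequence the i-th smallest suffix comes from. Each genome
  carries an 8-level lineage `T[i] = (superkingdom, phylum, class, order,
  family, genus, species, strain)`.
* **Read index.** The reads are indexed the same way (one strand; the
  reference already carries both), so each distinct k-mer is handled once,
  with its multiplicity across reads equal to its Q-interval size.
* **Synchronized traversal.** All k-mers shared by the two indexes are
  enumerated in lexicographic order by staged backward-search interval
  propagation — at most k sequential passes over the two BWTs, never
  random access.
* **Classification.** A shared k-mer Q with reference interval
  [b_Q, e_Q] is classified at the deepest rank l for which
  `T[C[b_Q]][l] = ... = T[C[e_Q]][l]`; k-mers occurring more than once in
  any single genome (strands pooled) are discarded (copy-number filter).
* **Profiles.** Read counts of classified k-mers are aggregated per taxon,
  divided by the mean length of the genomes within that taxon (so profiles
  reflect cell abundance, not sequenced bases), and rescaled to percent.
  Profiles are compared by Euclidean distance on the percent scale.

The simulator generates phylogenetically structured communities (ancestral
sequences mutated along a synthetic taxonomy), shotgun reads with
substitution errors at user-set cell abundances, and matching ground-truth
profiles — including the species-masking experiment in which all reference
genomes of the read-source species are removed.

## Worked example

```python
from bwtax import (CommunitySpec, simulate_reference_set, simulate_reads,
                   build_reference_index, build_read_index, classify_dataset,
                   build_profile, true_profile, euclidean_distance)

spec = CommunitySpec.even(n_species=5, seed=3, min_length=5_000,
                          max_length=50_000, n_reads=3_000,
                          read_length=80, error_rate=0.01)
genomes, taxonomy = simulate_reference_set(spec)
ref = build_reference_index(genomes, taxonomy)
reads = simulate_reads(genomes, spec)
result = classify_dataset(ref, build_read_index(reads), k=30)
print(result.summary)
profile = build_profile(result, ref, "species")
print({profile.name_of(t): round(f, 2) for t, f in profile.fractions.items()})
print(round(euclidean_distance(profile, true_profile(spec, "species", taxonomy)), 3))
```

prints

```
{'shared_kmers': 88519, 'copy_filtered': 0, 'unclassified': 0, 'classified': 88519}
{'species_0': 20.38, 'species_1': 20.65, 'species_2': 19.54, 'species_3': 20.2, 'species_4': 19.23}
1.192
```

Five species at equal cell abundance with a 10x spread of genome lengths
are recovered at ~20% each after length normalization (raw read counts
would range from ~5% to ~45%, tracking genome size); the Euclidean distance
between the estimated and true percent profiles is 1.19.

The same pipeline is available from the shell:

```bash
bwtax simulate --spec community.yaml --out sim/
bwtax build-ref --fasta sim/genomes.fasta --taxonomy sim/taxonomy.tsv --out ref/
bwtax index-reads --reads sim/reads.fastq --out reads-index/
bwtax classify --ref ref/ --reads-index reads-index/ -k 50 --out classifications.tsv
bwtax profile --classifications classifications.tsv --ref ref/ --level species --out profile.tsv
bwtax profile-distance --a profile.tsv --b sim/truth_species.tsv
```

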