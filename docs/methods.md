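# Methods

## Model and assumptions

`bwtax` performs exact-substring taxonomic classification. A read k-mer is
evidence for a taxon only if it occurs verbatim (on either strand) in at
least one reference genome; there is no mismatch-tolerant matching, so
sequencing errors and true biological divergence both act by removing
k-mers from the shared set rather than by producing wrong matches. The
method assumes the sample is dominated by organisms related to something in
the reference database; reads from entirely novel clades simply remain
unclassified (or, when only relatives are present, are absorbed at the
deepest rank the relatives support).

### The index

The reference is a *generalized* BWT over the genome collection plus all
reverse complements. Conceptually every member is terminated by a distinct
sentinel `$_1 < ... < $_n`, all below `A < C < G < N < T`; internally a
single sentinel code is used, with ties broken by member index, which
reproduces the distinct-sentinel suffix order exactly. A genome's forward
member immediately precedes its reverse-complement member, so forward
copies sort before their reverse complements at equal rank. Sentinel order
between members, and the placement of `N` between `G` and `T`, are
declared conventions: suffix order within the nucleotide alphabet only has
to be fixed and documented, not any particular choice.

The generalized suffix array is stored as two columns: `A[i]` (offset of
the i-th smallest suffix within its member) and `C[i]` (the member). The
taxonomy is a per-genome table of 8-vector lineages with names interned to
dense integer ids keyed by `(rank, name)`; lineages must form a tree.
FASTA records sharing a full 8-level lineage (same strain) are pooled into
one genome whose length is the sum of its records — the taxonomic unit is
the strain, not the record.

Construction is in-memory prefix doubling (numpy `lexsort`) over the
sentinel-augmented concatenation. Because sentinels are unique,
comparisons never cross a member boundary, and ranks become unique after
O(log of the longest sentinel-free run) rounds. This comfortably builds
desk-scale inputs (tens of Mb) in well under a minute; RefSeq-scale
external-memory construction is explicitly out of scope.

### Traversal

Stage s of the synchronized traversal holds, in lexicographic order, the
Q-intervals of every s-mer present in *both* the reference and the read
index; extending each interval on the left by `A,C,G,N,T` in symbol order
(backward search) yields stage s+1, still sorted. Substring closure (any
substring of a shared k-mer is itself shared in both indexes) means that
pruning to both-alive intervals loses no shared k-mer; the contract — every
k-mer present in both indexes, exactly once, lexicographically — is
unchanged, while intervals alive in only one index are dropped as early as
possible. Sentinels are never extension candidates, so k-mers cannot span
sequence boundaries. The traversal makes at most k sequential passes over
each BWT; here the interval lists live in memory as numpy arrays (a
streaming file-backed variant would change I/O, not results).

### Classification and filtering

For each shared k-mer the member slice `C[b_Q..e_Q]` of the reference
interval gives the genomes carrying it. The k-mer is classified at the
deepest rank on which all those genomes agree along the whole lineage
prefix (with a tree-consistent taxonomy this equals per-rank agreement);
disagreement already at superkingdom leaves it unclassified. The
copy-number filter then discards any k-mer occurring more than once in a
single genome, pooling that genome's forward and reverse-complement
members. Pooling has one documented edge case: an even-length
self-reverse-complementary k-mer present at a single site contributes one
count per strand and is therefore filtered; such palindromic k-mers are a
vanishing fraction at practical k (probability 4^-k/2 per k-mer) and
removing them is conservative. A k-mer occurring forward at one site and
as the reverse complement of a different site is likewise counted twice
and filtered, which is the desired repeat behavior.

The read-occurrence count of a k-mer is its read-index interval size. A
secondary, optional per-read output assigns each read the LCA of the taxa
of its classified k-mers; this is a convention of this package (the
canonical product is the per-k-mer table).

### Profiles

Counts are aggregated to a requested rank (a k-mer contributes at its
classified rank and every shallower rank, never deeper), divided by the
mean length of **all** database genomes under the taxon — a deterministic,
sample-independent divisor — and rescaled to percent. Distances between
profiles are Euclidean on the percent scale. Whether mass classified only
above the requested rank should enter the comparison is a reporting
convention, so it is exposed as an explicit `unclassified` bucket behind a
flag (default off; the bucket is normalized by the mean length of all
database genomes, the only available scale for mixed-origin mass).

## The simulator

The generator emulates a shotgun experiment on a community of related
microbes. Genomes are evolved top-down: one random ancestral sequence per
taxon at each rank, children derived by i.i.d. point substitutions at a
per-rank divergence rate (defaults 0.35, 0.25, 0.18, 0.12, 0.08, 0.04,
0.01 from phylum down to strain — non-increasing toward the tips, so
same-genus species share detectable sequence while different superkingdoms
share nothing beyond chance). Reads are sampled with per-genome probability
proportional to cell fraction x genome length (cell-abundance semantics:
the even-community read counts scale with genome size), uniform start and
strand, and i.i.d. substitution errors; indels are deliberately absent
because the classifier's exact-match semantics makes substitution-only the
informative error model for Illumina-like short reads. All randomness
derives from the community seed (separate streams for genomes and reads).

What the simulator does *not* reproduce: position- and motif-dependent
Illumina error profiles, quality scores, GC/coverage bias, repeats and
mobile elements, horizontal transfer, chimeras, contamination. Passing
end-to-end tests therefore demonstrates correctness of the indexing,
traversal, filtering and normalization machinery under the stated
statistical model — not robustness to every artifact of real libraries.

## Study conditions and problem sizes

The headline condition mirrors an even community of 15 organisms: equal
cell fractions, one strain per species, genome lengths spanning 10x
(20-200 kb, geometric spacing), 100,000 reads of 80 bp at 1% substitution
error, classified at k = 50 (the package default for 80 bp reads; k trades
specificity against error-driven dropout and is chosen empirically per
experiment). Genome sizes are scaled down from Mb-scale bacteria to keep
the whole pipeline fast on one CPU; the quantities being checked — fraction
recovery after length normalization — depend on the *spread* of lengths,
which is preserved. Smaller communities (5-6 species, 10-40 kb genomes,
shorter k) back the copy-number and species-masking checks.

## Numerical and design choices

* Intervals are closed, 0-based `[b, e]`, empty encoded as `e = b - 1`.
* `N` is a literal fifth symbol: searchable, matching only literal `N`;
  padding-derived k-mers containing `N` simply never match a reference
  without `N`. Degenerate IUPAC codes in input FASTA become `N` with a
  logged warning.
* The copy-number filter applies to reference genomes (the only collection
  with meaningful per-genome copy number).
* Serialization is plain text with a version header (BWT string with `$`
  sentinels plus a member table, GSA as TSV); saves are byte-deterministic
  and loads reject version mismatches and truncation.
* Plasmid-style exclusions are an explicit user-supplied identifier list,
  not hard-coded database logic.
* Empty intervals, empty classifications and all-zero profiles raise
  rather than silently propagating; ties in suffix order cannot occur by
  construction (distinct sentinels).

## Limitations

Exact matching only; single fixed k per run (no multi-k aggregation); no
quality-aware read processing; in-memory construction targets desk-scale
references, not the full RefSeq; per-read assignment is a convenience
built on the per-k-mer classifications, with no claim of optimality.
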