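# Methods

## The sGBS model

A spiked-GBS run multiplexes two read populations. Targeted amplicons are
built in two PCR rounds: a locus-specific primer pair whose forward primer
carries an M13 linker amplifies the polymorphic target, and a universal
barcoded primer (platform forward site + 10-base sample barcode + the same
M13 linker) extends it into the final construct. Because the barcode oligo
set is locus-independent, its synthesis cost amortizes over all assays. The
pooled amplicons are added to a GBS library at a small fraction of molar
input, so the sequencer output is dominated by GBS reads with a thin stream
of amplicons distinguishable by the M13 tail.

Genotypes follow from allele read counts. For a sample s and locus l with
counts n_A and n_B of the two allele targets, the relative read frequency
f = n_A / (n_A + n_B) concentrates near the allele-A dosage of the
genotype: 1, 0.5, 0 for homozygous-A, heterozygous, homozygous-B at a
single-copy locus, or the dosage fractions k/p for k copies in a ploidy-p
genome (a hexaploid AAAABB expects f = 2/3). Clustering samples on f and
labeling clusters by their nearest expected fraction turns counts into
genotype classes without a per-locus statistical model.

## Parsing and counting

Routing is sequence-exact, mirroring how such pipelines are actually run:

* A read is an **amplicon candidate** iff the M13 tail occurs in it
  (first occurrence wins — the construct places the barcode immediately
  before the tail, so the preceding 10 bases are the barcode). An exact
  barcode hit demultiplexes the read; a miss leaves it *unassigned*.
* The post-tail payload is assigned to the unique marker whose allele
  target occurs in it; reads matching no marker, several markers, or both
  alleles of one marker are counted as unmatched (never guessed).
* Reads without the tail are GBS background; their QC is the fraction
  with an exact GBS-barcode prefix, and with barcode followed by the
  restriction-site remnant (PstI `TGCAG` by default).

Exact matching admits no mismatch tolerance (an optional 1-mismatch
barcode mode exists but is off by default): a substitution anywhere in the
tail, barcode, or target simply drops the read. Two consequences are worth
stating. First, counting is conservative — errors thin depth but almost
never flip an allele (a flip requires hitting exactly the SNP base with
exactly the other allele's base, probability e/3 per read). Second, the
M13-count estimator of the spiked fraction undercounts by a factor
(1−e)^18 at base-error rate e (~16% relative at e = 0.01); the estimator
is unbiased only as e → 0, and the package's estimator tests are therefore
run error-free. Real Ion Torrent data additionally has indel errors the
default simulator does not model; exact matching treats those identically
(dropped reads), so the count tables degrade the same way, but observed
spiked fractions in real runs should be read as lower bounds.

The M13 tail ships as the canonical M13 forward (−21) sequence
`TGTAAAACGACGGCCAGT` and is configurable; platform sites default to the
Ion Torrent A and P1 adapters. Barcode sets must be unique and
single-length; generated sets additionally guarantee pairwise Hamming
distance ≥ 3 (seeded rejection sampling; the standard set is 384 × 10 bp).
User-supplied sets are checked for uniqueness only, since exact-match
parsing gains nothing from a distance guarantee. Degenerate IUPAC bases
are rejected everywhere.

## Genotype calling

* **Depth filter**: cells with n_A + n_B < 10 are excluded from
  clustering and reported as missing; the boundary is inclusive at 10.
  Unmatched reads do not count toward depth.
* **k-means**: scikit-learn, k-means++ with 10 restarts and a fixed seed
  (best inertia wins), k defaulting to the number of classes in the
  marker's model. Every sample is assigned, so k-means is forced to place
  outliers.
* **DBSCAN**: scikit-learn, Euclidean on the 1-D frequency axis,
  eps = 0.1 by default with per-locus overrides (tight multi-copy loci may
  need ~0.06), min_pts = 5. Noise points stay unclassified — preferable in
  polyploids where an off-cluster sample may be a heterozygote at one of
  several homoeologous copies.
* **Labeling**: clusters are renumbered by ascending centroid and each
  centroid maps to the nearest expected class fraction. The map must be
  injective; a collision (e.g. centroids 0.45 and 0.55 both nearest 0.5)
  raises a labeling error, or in pipeline mode flags the locus for manual
  curation and reports it all-missing.
* **Concordance** between the two callers is reported two ways: over
  cells called by at least one method, and restricted to cells called by
  both. The restricted figure isolates clustering disagreement from
  DBSCAN's refusal to classify outliers, which otherwise dominates.
* **Summaries**: per-locus call rate (non-missing / samples assayed, so
  low-depth loss counts against it) and average depth over filter-passing
  samples.

Clustering is deliberately 1-D: plotting tools often show (n_A, n_B) or
(f, 1−f) scatter, but the second coordinate is determined by the first, so
eps is interpreted on the frequency axis and 2-D views are export-only
(`scatter_*.tsv`).

## The simulator

The generator emulates the study conditions of a spiked Ion Proton run:

| parameter | default | rationale |
|---|---|---|
| spike fraction | 0.01 | ~1% molar spike; observed run fractions of 1.8–3.1% are within a configurable factor |
| per-cell depth | negative binomial, mean 300, dispersion 5 | overdispersed counts spanning observed per-marker average depths (~114–1573) |
| base error rate | 0.01 (substitutions only) | Ion-class error magnitude; substitution-only keeps the exact-match loss model analyzable |
| GBS read length | normal(145, 30), truncated ≥ 30 bp | observed library means of 145/183 bp |
| GBS barcode / +cut-site integrity | 0.836 / 0.813 | observed QC rates of unspiked GBS libraries |
| amplicon barcodes | 384 × 10 bp, Hamming ≥ 3 | the standard barcoded-primer set |

Truth tables draw a genotype class per (sample, locus) from configurable
class frequencies; amplicon reads then draw depth per cell, allele
Bernoulli(expected fraction), and iid substitutions. Background reads
draw a barcode, corrupt it (one base) with probability 1 − 0.836, corrupt
the remnant given an intact barcode with the conditional probability that
yields the 0.813 joint rate, and append random insert; any background
read containing the M13 tail is rejected and redrawn, so the background
can never masquerade as an amplicon. When a total read count is given,
the amplicon count is binomial(n, spike fraction) and is allocated across
cells proportionally to depth-model draws; otherwise cell depths are
taken directly and background is added to hit the spike fraction in
expectation. All randomness flows from one integer seed; identical seeds
give byte-identical FASTQ.

A counts-level shortcut (`simulate_allele_counts`) draws the count table
directly — depth from the same model, reads surviving exact matching with
probability (1−e)^L for an effective matched length L = 40 bp
(tail + barcode + target), survivors split binomially. It is
distributionally equivalent to read-level simulation followed by counting
(the read-level path is verified exactly on noise-free runs) and is used
where only counts matter, e.g. clustering studies at hundreds of samples
× many seeds.

What the simulator does **not** emulate: flow-space/homopolymer error
structure, indels, PCR duplicates and amplification bias, restriction-site
biology of the GBS fraction, or cross-sample index hopping. Passing tests
therefore demonstrate the correctness of parsing, counting, and calling
under a clean substitution-error model — not robustness to
platform-specific artifacts.

## Numerical and design choices

* Cluster ids are renumbered by ascending centroid before labeling, so
  results are invariant to backend label permutations and point order.
* k-means determinism comes from the fixed seed + 10 restarts; DBSCAN is
  deterministic up to border-point ties (a non-core point within eps of
  two clusters may join either; the test oracle accepts any permissible
  assignment, and such ties are measure-zero on continuous frequencies).
* The depth-filter boundary, frequency normalization (f_B ≡ 1 − f_A
  exactly), and the inclusive ≥ comparison are asserted by tests.
* Dosage labels derive from fractions at a declared ploidy (default 6,
  bread wheat): fraction k/p → "A"×k + "B"×(p−k). Fractions must be
  strictly decreasing and near multiples of 1/p.
* Marker TSVs store the reverse flank on the construct (forward) strand;
  reverse-complement rescan of reads is not performed (single-end reads
  sequence from the forward adapter).
* Empty inputs are defined, not errors: an empty FASTQ yields empty
  tables, a spiked fraction of 0, and exit 0 with a warning.

## Known limitations

* Exact matching discards every errored read; at high error rates or long
  targets, depth (and the spiked-fraction estimate) drops geometrically.
* Near the 10-read floor a heterozygote's frequency can drift past the
  midpoint between class centers (binomial sd at depth 10 is 0.16);
  k-means, which must classify everything, occasionally miscalls such
  cells (~0.3% of called cells at depth mean 50 under the overdispersed
  depth model), while DBSCAN tends to leave them unclassified. Pooled
  recovery across seeds stays ≥ 99% for both callers under those
  conditions, but individual replicates can graze the threshold.
* k (for k-means) and eps (for DBSCAN) are per-locus curation inputs;
  automatic model selection is out of scope. A locus whose true classes
  are fewer than k will usually trip the injective-labeling guard rather
  than produce silent miscalls.
* VCF export represents dosage-model genotypes in a `CL` FORMAT field
  (diploid GT cannot express them); downstream VCF consumers see missing
  GT for those loci.
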