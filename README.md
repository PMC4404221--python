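# spikegbs

Tools for **spiked genotyping-by-sequencing (sGBS)** — a dual-purpose
genotyping design in which a small pool of targeted, barcoded amplicons
(~1–3% of reads) is co-sequenced with a reduced-representation GBS library,
so a single sequencing run yields both a whole-genome profile and
single-marker genotype calls for marker-assisted selection.

The package is aimed at breeders and genotyping-lab bioinformaticians. It
implements the computational half of the design:

* **Construct modeling** — the spiked amplicon read, in sequencing order, is

  ```
  platform_fwd_site | barcode(10 bp) | M13 tail | fwd flank | allele target | rev flank | platform_rev_site
  ```

  One universal set of barcoded primers (platform site + barcode + M13
  tail) serves every locus, because locus-specific primers carry the same
  M13 linker. KASP allele-specific primer pairs convert to this design by
  dropping the 3′ selective base, yielding a single common forward primer.
* **Simulation** — synthetic runs mixing GBS-like background reads
  (in-line barcode + restriction-site remnant + random insert, truncated-
  normal lengths) with spiked amplicons under per-sample genotype truth,
  including hexaploid allele-dosage classes. Fully seeded and audited.
* **Demultiplexing and allele counting** — reads containing the M13 tail
  are parsed by the 10-base barcode immediately preceding it and counted
  by **exact matching** to each locus's two allele target sequences; the
  fraction of M13-containing reads estimates the spiked fraction, and GBS
  barcode / cut-site integrity is reported as run QC.
* **Genotype calling** — per locus, samples with ≥ 10 allele reads are
  clustered on the 1-D relative read frequency
  `freq_A = n_A / (n_A + n_B)` with either k-means (k = number of expected
  classes) or DBSCAN (reachability distance ε, default 0.1; outliers stay
  unclassified). Cluster centroids map to the nearest expected class
  fraction — 1 / 0.5 / 0 for A / Heterozygous / B, or declared dosage
  fractions such as 1, 2/3, 1/3 → AAAAAA / AAAABB / AABBBB in a hexaploid —
  with an injectivity check that flags unresolvable loci for manual
  curation. Call rates, average depths, method concordance, TSV/VCF
  exports.

## Worked example

Simulate a 24-sample, 3-locus run with a 2% spike and 1% base error, then
count and call:

```bash
sgbs simulate --markers markers.tsv --out-fastq run.fastq \
    --truth-out truth.tsv --barcodes-out barcodes.tsv \
    --n-samples 24 --spike-fraction 0.02 --depth-mean 120 \
    --error-rate 0.01 --seed 7
# wrote 413000 reads (8260 amplicon) to run.fastq

sgbs count --fastq run.fastq --markers markers.tsv \
    --barcodes barcodes.tsv --out counts.tsv --qc-out qc.json
# 413000 reads: 6283 amplicon (spiked fraction 0.0168), 406065 gbs, 652 unassigned

sgbs call --counts counts.tsv --markers markers.tsv --out-prefix demo --seed 1
# concordance: overall 0.9028, co-classified 1.0000 (n=65)
```

Reading the numbers: 8,260 amplicon reads were emitted, but the M13-count
estimator sees a spiked fraction of 0.0168 rather than 0.020 — at a 1% base
error, ~16% of amplicon reads acquire a substitution inside the 18-bp M13
tail and are no longer recognized by exact matching (error-free runs recover
the configured fraction to within binomial noise). The two callers agree on
**100%** of the samples they both classify; the lower overall concordance
(0.90) counts the cells DBSCAN leaves unclassified but k-means is forced to
call. Per-marker summaries match the familiar report format:

```
locus_id    call_rate   avg_depth
locus_001   100.0%      70
locus_002   100.0%      82
locus_003   100.0%      81
```

and `demo.genotypes_kmeans.tsv` holds the samples × loci call matrix
(`NA` = filtered or unclassified), with a VCF 4.2 export alongside.

The same pipeline is available as a library (`spikegbs.simulate_run`,
`count_alleles`, `call_genotypes`, `concordance`, …) and as a single
`sgbs run --config run.yaml` orchestration with a JSON run manifest.

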