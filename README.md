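# seaati

Discovery, curation and genomic characterization of active cis-regulatory
element (CRE) motifs from TF-enriched randomized-ligand selection libraries,
plus a selection-round simulator so the whole pipeline can be exercised at
desk scale with known ground truth.

The package covers:

* **ligand_io** — FASTA/FASTQ reading (gzip-transparent), extraction of the
  randomized core (default 30 bp inside a 76-bp ligand), PCR-duplicate
  removal, per-read mononucleotide shuffling for control libraries.
* **kmer_stats** — continuous and gapped k-mer counting, enrichment against
  shuffled controls, and the gapped-10-mer rank matrix / PCA used to compare
  libraries.
* **mutual_information** — joint 3-mer distributions at position pairs and
  the E-MI (top-10 pointwise contributions), D-MI (identical/revcomp pairs)
  and full-MI statistics over the triangular position grid.
* **motif_discovery** — local-max k-mer seeds (lengths 8–10, count cutoff
  40, substitution + shift neighborhood, both strands) and multinomial-1
  PFM construction with information-content summaries.
* **motif_curation** — IC filters (consensus IC < 1.8, total IC 2–30,
  per-base IC > 0.2), aligned-Pearson dedup (r > 0.90 merges, highest total
  IC survives), distinct/similar/reported classification against a
  JASPAR-style reference library, per-library activity and tissue
  specificity contrast.
* **dimer_landscape** — orientation (DR/IR/ER) × spacing landscapes of a
  core pair (default TTGAC), enrichment vs shuffled controls and the
  dimeric gapped-10-mer scatter.
* **genome_scan** — log-odds PWMs with *exact* p-value score thresholds
  (integer-scaled dynamic programming), two-strand scanning, accessibility
  (THS) enrichment, metagene profiles and TSS-window expression enrichment.
* **cistrome_context** — TPM, aggregated cut-count profiles, footprint
  depth with control subtraction, positive/negative model classification
  (|r| > 0.5), bound/unbound splitting and the CRE dose–response summary.
* **simulator** — full selection experiments (uniform 30-bp cores, logistic
  PWM occupancy and/or dimeric affinities, proportional capture, PCR
  duplication over 3–5 rounds) and a toy genome with planted CREs, peaks,
  Tn5-style cut tracks and CRE-coupled expression.

## CLI

```bash
seaati simulate --preset monomer --seed 1 --outdir sim/     # synthetic data
seaati extract sim/round4.fastq --out cores.fa              # core extraction + dedup
seaati kmers cores.fa --k 8 --out scatter.tsv               # 8-mer enrichment
seaati mi cores.fa --stat emi --out emi.tsv                 # E-MI triangle
seaati discover cores.fa --out motifs.jaspar                # seeds + PFMs
seaati curate motifs.jaspar --out curated.jaspar            # IC filters + dedup
seaati classify curated.jaspar --reference ref.jaspar --out classes.tsv
seaati dimers cores.fa --core TTGAC --out landscape.tsv     # DR/IR/ER x spacing
seaati scan genome.fa --motifs curated.jaspar --out hits.bed
```

## Notes on conventions

* Bases are encoded A=0, C=1, G=2, T=3; k-mer integer codes sort
  lexicographically. Coordinates are 0-based half-open (BED); GFF3 input is
  converted on read.
* Dimer spacing counts the bases strictly between two core matches
  (adjacent cores = spacing 0). IR is head-to-head (core…revcomp), ER is
  tail-to-tail (revcomp…core); minus-strand direct repeats are folded into
  DR, so each physical pair is counted exactly once.
* MI statistics use the plug-in estimator with no pseudocounts; zero-count
  pairs contribute 0.
* PWM thresholds are reported on the achievable integer-score grid: the
  smallest achievable score t with P(score ≥ t) ≤ p under the background.
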