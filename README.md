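# regsnap

From GWAS index SNPs to candidate regulatory mechanisms: a tested pipeline
for LD expansion, motif discovery from ChIP-seq peaks, allele-specific
TF-binding disruption statistics, brain-eQTL evidence integration, and
multi-evidence variant prioritization — exercised end-to-end on synthetic
data with planted ground truth.

## Pipeline stages

1. **LD expansion** (`regsnap ld-expand`) — expand index SNPs into sets of
   variants with r² ≥ 0.3 (inclusive, configurable) within ±500 kb, from a
   phased or unphased VCF panel (EM haplotype-frequency estimation for
   unphased genotypes).
2. **Motif discovery** (`regsnap discover`) — seed-and-refine discovery
   from the top 500 peaks (±20 bp, ranked by height) against per-sequence
   dinucleotide shuffles, with held-out enrichment p-values and a 5%
   Benjamini–Hochberg FDR filter. A simplified, fully self-contained
   stand-in for external discovery tools.
3. **Database matching** (`regsnap match-motifs`) — Pearson-correlation
   alignment of discovered PWMs against a MEME-format motif database
   (similarity ≥ 0.75 by default).
4. **Disruption scoring** (`regsnap score`) — per allele, the best
   log-odds window score over both strands within ±20 bp of the variant;
   affinity p-values per allele (occupancy gate, p < 0.001 for at least one
   allele) and a rank p-value for the allelic score difference
   (p < 0.05 after Bonferroni), exact by enumeration for short scans and
   seeded Monte Carlo otherwise.
5. **eQTL integration** (`regsnap eqtl`) — per-dataset BH q-values
   (q < 0.001), cross-dataset replication flags (≥ 2 datasets).
6. **Prioritization** (`regsnap prioritize`) — eQTL + RegulomeDB
   category-1 gates, 0–4 additive evidence score (promoter marks, enhancer
   marks, DNase protein binding, motif change), genomic-context
   classification, per-TF and co-disruption summaries.

`regsnap run --config cfg.yaml --outdir out` runs everything;
`regsnap simulate --outdir sim --seed 1` generates a complete synthetic
scenario (reference, haplotype panel, peaks with planted motif instances,
disrupting variants with known score differences, eQTL tables with planted
effects, annotations, gene model) plus a JSON manifest of the ground truth.

## Library use

```python
from regsnap.motif_core import from_consensus, best_match_score
from regsnap.binding_disruption import evaluate_variants, call_disrupting

pwm = from_consensus("YGCGCAYGCGCR")
score, start, strand = best_match_score(pwm, "GGCGCAGCCGCAGC", 9, "G")
```

File formats: FASTA (pyfaidx), VCF 4.2 (cyvcf2), BED6(+summit) peaks with
the score column as peak height, minimal MEME motif format, TSV for eQTL
summaries/annotations/outputs, BED12 or GFF3 gene models. All internal
coordinates are 0-based half-open; VCF and GFF3 I/O convert at the
boundary.
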