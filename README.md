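# indelchip

Toolkit for genotyping large insertions/deletions (including presence/absence
variants) with a SNP-style fluorescence array, end to end and at desk scale:

- **breakpoints** — base-pair-resolved InDel representation, classification of
  junctions into four breakpoint types by microhomology/inserted-fragment
  content (events with microhomology > 5 bp are excluded from design), and
  construction of 35 bp breakpoint (BP) probes with the iterative one-base
  junction shift (≤ 5 bp) to reach a discriminative position.
- **kmers** — canonical 17-mer indexes over assemblies/read subsets and
  detection of presence/absence regions (PARs): runs ≥ 35 bp of an InDel
  sequence not covered by any comparison line's k-mers, minus annotated
  repeats.
- **design** — internal OTV/MONO probe candidates, a transparent surrogate
  conversion score with the recommended/neutral/not-recommended thresholds
  (0.6/0.4), 16-mer hit counting, genome-hit filters (≤ 1 for deletion
  probes, 0 for insertion probes, < 3 for BP probes), strict > 70% PAR
  overlap, windowed best-probe selection over 75/50/25 bp tiles with the
  fewer-than-4-probes retry rule, rescue of untargeted InDels, and duplicate
  removal.
- **calling** — Gaussian-mixture cluster callers on (contrast, intensity)
  fluorescence summaries: a codominant BP caller with off-target relabelling
  and hemizygous (OA/OB) clusters, an OTV caller that relabels
  low-intensity "AB" clusters as absence, and the Hom2OTV caller for
  monomorphic internal probes (two homozygous-looking clusters separated
  primarily in intensity → lower = absent). Includes the inbred-penalty
  prior down-weighting, probeset quality categories and sample call-rate QC.
- **consensus** — presence-alphabet conversion, per-InDel average presence
  frequency, majority-allele consensus (exact ties → missing), FreqDiff01,
  the binomial probe-error simulation (362 lines × 10,000 InDels) with exact
  closed-form oracles, array-vs-sequencing concordance (≤ 5% mismatch
  alignment rule) and Mendelian F1 checks.
- **diversity** — marker filters (missing < 20%, het < 15%, MAF > 5%),
  best-probe-per-InDel selection, genomic IBD kinship and principal
  coordinate analysis on 1 − IBD.
- **simulate** — synthetic genomes with planted InDels of all four breakpoint
  types, repeats, array signals with configurable cluster geometry/error/
  dropout, and multi-probe call panels — every generator is a pure function
  of (config, seed) and ships ground truth for testing.

## CLI

```sh
indelchip simulate-data --seed 1 --n-indels 10 -o fixtures/
indelchip design --genome fixtures/reference.fa --alt fixtures/alternative.fa \
    --variants fixtures/indels.vcf -o manifest.tsv
indelchip call --signals signals.tsv --manifest manifest.tsv -o calls.tsv
indelchip consensus --calls calls.tsv --manifest manifest.tsv -o consensus.tsv
indelchip simulate-errors --lines 362 --indels 10000 --probes 2..50 \
    --error 0.01,0.03,0.05,0.10 --seed 1 -o simulation.csv
indelchip diversity --genotypes geno.tsv --kinship-out k.csv --pcoa-out p.csv
indelchip pipeline --config pipeline.yaml
```

`pipeline` runs simulate-data → design → call → consensus → diversity from a
YAML config (`outdir`, `seed`, optional `synthetic`/`design`/`calling`/
`markers` sections), supports stage subsets via `--stages`, and writes a
provenance record with the config hash and seed.

## Notes

- The vendor's random-forest conversion score is proprietary; `design`
  substitutes a documented monotone surrogate (GC deviation, homopolymer and
  dinucleotide-repeat penalties, 16-mer hit normalisation) with identical
  thresholds and classification semantics.
- Hemizygous genotypes are called for BP probes only; OTV/MONO callers emit
  presence/absence states.
- Coordinates are 0-based half-open everywhere except VCF output.
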