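# top1tam

Analysis toolkit for the indel signature of topoisomerase-1 (TOP1)
transcription-associated mutagenesis: short deletions (typically 2–5 bp) of
one repeat unit at short tandem repeats (SSTRs) and single-nucleotide
microhomology (SNMH) sites, the pattern catalogued as COSMIC signature
ID4/ID-TOP1. TOP1 cleaves preferentially 3′ of thymidine; sequential cleavage
around a genome-embedded ribonucleotide followed by strand realignment
deletes the bases between two thymidines, leaving the motif

```
T · N^(d−1) · T        (a d-bp deletion bracketed by thymidines, "TNT")
```

The package is aimed at researchers analysing indel calls from mutation
accumulation experiments, cancer genomes or de novo germline variants who
want to quantify this mutational process. It provides:

- `genome_context` — SSTR and microhomology annotation, genome-background
  TNT fractions, composition-adjusted dinucleotide context rates;
- `indel_classify` — VCF-style indel normalization (left alignment), deletion
  context classification (STR / SNMH / other, repeat copies, microhomology
  length), strand-collapsed TNT scoring over all equivalent placement
  registers, six canonical dinucleotide classes, ID-83 spectra and wild-type
  background subtraction;
- `null_enrichment` — the uniform genomic null (100,000 random deletions in
  the mappable genome), the matched-repeat bootstrap null (1,000 replicates
  matched on repeat type, unit length and total length), exact enrichment
  tests and multiple-testing correction;
- `spectra_stats` — cosine similarity with a Dirichlet-multinomial null,
  complete-linkage clustering with bootstrap clade support, and two-bit
  sequence logos of canonicalized deletion contexts;
- `fluctuation` — Lea–Coulson method-of-the-median mutation rates
  (r₀/m − ln m = 1.24) with rank-based 95% CIs (ranks 4 and 13 for 16
  cultures) and per-bp / per-reporter-copy normalization;
- `transcription_strata` — deletion rates per expression stratum,
  rate = c/(g·n) with gene-bootstrap CIs, housekeeping-like and highly
  expressed tissue-restricted (HETR) gene rules, TOP1-activity signal decile
  relative rates, per-individual outlier filtering;
- `reporter_design` — synonymous recoding of a CDS to maximize 2 bp tandem
  repeats (5-codon sliding window, exhaustive synonymous permutations) and
  removal of stop codons from the +2 reading frame;
- `synthetic_data` — deterministic generators for every input above, with
  machine-readable truth labels (planted repeats, TNT placement bias,
  Luria–Delbrück colony counts, HETR genes, signal–deletion coupling).

## Worked example

Simulate a genome, plant deletions with a known TNT bias, and test enrichment
against the genomic null:

```python
import numpy as np
from top1tam import (
    generate_genome, plant_deletions, classify_deletion,
    genomic_null, enrichment_test,
)

genome = generate_genome(20_000, seed=7)
planted = plant_deletions(genome, 228, tnt_bias=1.0,
                          length_distribution={2: 1.0}, seed=11)
flags = [classify_deletion(c, genome.sequences).tnt_compliant
         for c in planted.deletions]
expected = genomic_null(genome.sequences, genome.mappability_mask,
                        d=2, n_samples=100_000, seed=13)
res = enrichment_test(len(flags), int(np.sum(flags)), expected)
print(f"observed TNT fraction: {np.mean(flags):.3f}")
print(f"background fraction:   {expected:.3f}")
print(f"p = {res.p_value:.2e}")
```

prints

```
observed TNT fraction: 1.000
background fraction:   0.359
p = 4.08e-102
```

every one of the 228 biased deletions scores TNT-compliant, against a
genome background of ~36% — decisive enrichment. A fluctuation assay run the
same way:

```python
from top1tam import simulate_fluctuation, lea_coulson_estimate

exp = simulate_fluctuation(6.1e-9 * 1032, n_final=1e7, n_cultures=16,
                           seed=1, target_bp=1032)
est = lea_coulson_estimate(exp)
print(f"rate = {est.rate:.2e} per bp per generation "
      f"(95% CI {est.ci_low:.2e}–{est.ci_high:.2e}, ranks "
      f"{est.rank_low}/{est.rank_high})")
```

```
rate = 4.81e-09 per bp per generation (95% CI 3.98e-09–7.86e-09, ranks 4/13)
```

the estimator recovers the simulated per-bp rate (6.1e-9) within the spread
expected of a single 16-culture assay, with the CI built from the 4th- and
13th-ranked cultures.

A command-line interface mirrors the library
(`top1tam simulate genome|deletions|fluctuation|expression|signal`,
`top1tam enrich|compare|logo|fluctuation|strata|hetr|deciles|design`).

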