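# Methods

## The mutational process and its classification

TOP1 nicks DNA with a strong preference for a thymidine 5′ of the cleavage
site. At a genome-embedded ribonucleotide, sequential cleavage and religation
after strand slippage deletes the bases between two thymidines. For a d-bp
deletion the footprint is the motif `T · N^(d−1) · T`: the deleted bases read
`N^(d−1),T` with a further T immediately 5′. Because slippage requires
pre-existing sequence redundancy, these deletions concentrate at short tandem
repeats (STRs) and at single-base microhomology (SNMH) sites — a base matched
d positions away, `B · N^(d−1) · B`.

### Placement registers

A deletion inside repetitive sequence has many equivalent representations:
the set of start positions producing the same post-deletion sequence is a
contiguous range between the left-aligned (VCF-normalized) and right-aligned
registers. All classification and motif scoring enumerate this range, so the
result does not depend on how a caller happened to write the variant, and a
dedicated test asserts identical classification for every rewriting of an
event.

### Context assignment

- `repeat_copies`: tandem copies of the deleted unit spanning the site,
  counted from the left-aligned register and including the deleted copy
  (so deleting one unit of a doublet gives 2), matching ID-83 repeat-size
  semantics.
- `mh_length`: the longer of the 5′-anchored and 3′-anchored flanking
  homologies of the deleted sequence, evaluated at the right-aligned
  register; ties report the 3′-anchored value, consistent with the
  right-alignment convention used for logos.
- Context precedence: `repeat_copies >= 2` → STR; else `mh_length >= 1` →
  MH/SNMH; else "other". The same precedence governs the region annotation:
  an MH anchor pair whose supported deletion lies in a tandem array is
  reported as STR, not MH.

### Strand handling

A deletion is an event on duplex DNA. The TNT rule is therefore evaluated on
the forward presentation and on the reverse complement at the mirrored
position, and compliance is their disjunction. This is equivalent to scoring
the canonical orientation (A-containing deleted pairs read on the other
strand) and is what makes classification invariant under reverse
complementing the genome. On the forward string the complementary-strand
condition appears mirrored: `T,T` spaced d becomes `A,A` spaced d. One
consequence worth stating plainly: deletions in AC-class repeats (AC/CA on
one strand, GT/TG on the other) can be TNT-compliant via the T-bearing
strand; only pairs with no T on either strand (CC/GG, CG/GC) are structurally
non-compliant.

The six canonical dinucleotide classes group strand-complementary deleted
pairs: {AT}, {TA}, {CC,GG}, {CG,GC}, {CT,TC,AG,GA}, {AC,CA,GT,TG}. AA/TT
pairs sit inside homopolymer runs, are not dinucleotide-repeat deletions, and
deliberately fall outside the scheme (the classifier records no class for
them).

### ID-83 spectra

Spectra follow the COSMIC ID-83 layout (type × length 1,2,3,4,5+ × repeat
copies or microhomology length). Insertions are carried for completeness but
receive no TNT or class annotation. Background subtraction is per-category
`max(0, ko − mean(wt))`. Arbitrary fixed subsets of the 83 labels are
supported as schemes; a built-in subset collects the categories whose length
change shifts the downstream frame by +2 (deletions of 3k+2 bp, insertions
of 3k+1 bp), the events a +2-frameshift reporter selects.

## Null models and enrichment

Two nulls quantify "how often would deletions look TNT-compliant anyway":

- Genomic null: the compliant fraction of `n_samples` (default 100,000)
  uniformly placed d-bp deletions within the mappability mask, with a Wilson
  binomial CI. On the small genomes used in tests this is validated against
  exhaustive enumeration of every position.
- Matched-repeat bootstrap: each observed STR/MH deletion is matched on
  (repeat type, primitive unit length, total repeat length) and replaced, per
  replicate (default B = 1,000), by a uniformly drawn matching repeat from
  the genome catalog; the replicate statistic is the motif-containing
  fraction. The empirical p uses (k+1)/(B+1), never zero.

The observed-versus-expected test defaults to a two-sided exact binomial test
of the observed motif count against the expected fraction. The expected
fraction is a genome-wide constant, so the binomial test is exactly
calibrated; we verified that the alternative 2×2 pseudo-cohort Fisher
construction (also provided, `method="fisher"`) is structurally conservative
because it treats the constant expected arm as a random sample, and it fails
a uniformity check of null p-values that the binomial test passes. Both
report the same odds ratio. Bonferroni and Benjamini–Hochberg corrections are
applied through statsmodels.

## Spectrum statistics

Cosine similarity is Σaᵢbᵢ/(‖a‖‖b‖) on counts or proportions. Its
significance uses a Dirichlet-multinomial null: 10,000 (configurable) pairs
drawn with flat concentration (vector of ones) and trial counts m₁, m₂
matching the observed totals; p is the smoothed exceedance fraction. Under
the null the p-value is uniform, which the suite checks by KS test over 500
repetitions.

Hierarchical clustering uses complete linkage on cosine distance
(1 − cosine). Bootstrap support resamples each spectrum's mutations with
replacement (multinomial redraw at observed proportions), reclusters, and
scores a join as supported when its exact leaf set reappears as a clade;
support is the percentage over replicates, annotated on the Newick output.

Sequence logos use the uncorrected two-bit representation: per column,
information = 2 + Σ f·log₂f over non-N bases, cell height = f × information.
Small-sample correction is deliberately omitted; window width is a parameter
(default 10 bp flanks).

### Canonicalization of 2 bp deletion windows

Windows are reverse-complemented when the deleted dinucleotide contains an A,
except AT and TA (their base content is register-invariant because adjacent
registers swap the two bases). On the working strand the deletion is
right-aligned to the register whose deleted pair reaches the most 3′ T of the
ambiguity range — preferring a T as the second deleted base, then as the
first — otherwise to the limit of the range. Windows at sequence ends are
N-padded and flagged.

## Fluctuation analysis

The Lea–Coulson method of the median solves `r₀/m − ln m = 1.24` for the
expected mutations per culture m, with r₀ the median mutant count; the
constant is exposed in configuration. Rates divide by the final population
size (total generations approximated by N_final, the standard convention),
the mutational target (default 1,032 bp) and the reporter copy number (1 or
2). A zero median reports rate 0 flagged below detection rather than the
positive root of the relation.

The 95% CI uses order statistics: the tightest symmetric rank pair
(j, n+1−j) whose coverage under Binomial(n, ½) reaches the level — (4, 13)
for 16 cultures — each rank's count converted to a rate through the same
median relation. Simulated assays at mu = 10⁻⁷ per division and N_final =
10⁷ recover mu within 25% relative error in the median over 100 assays, with
rank-CI coverage ≥ 93%; both are asserted in the suite.

The simulator uses synchronized doublings with binomial mutation per
generation (mutants breed true, no back mutation, no fitness cost), matching
the per-generation rate definition of the estimator; continuous-time birth
processes are out of scope.

## Expression and activity stratification

Per-stratum deletion rates are `c/(g·n)`: deletions whose leftmost deleted
base falls in the stratum's union gene span, divided by that span and the
number of genomes. CIs bootstrap gene selection (resample genes with
replacement to the same number, recompute c, g; 2.5/97.5 percentiles;
default 100 replicates). Overlapping genes are resolved hierarchically,
keeping the higher median (then mean) expression. Decile schemes bin genes by
median TPM; the housekeeping-like rule keeps genes with max expression below
ten times the median; the germline scheme collapses precomputed groups 1–9
into unexpressed/low/mid/high.

HETR (highly expressed, tissue-restricted) genes satisfy within-tissue median
≥ q90 (the 90th percentile of within-tissue per-gene medians — the
within-median reading of "high expression"; the any-sample alternative is a
one-line change flagged in the code) and other-tissue median < 0.1·q90.
Enrichment per cancer–tissue pair uses a 2×2 Fisher test of HETR vs non-HETR
deletion counts against all other cancers, Bonferroni-corrected over all
pairs; depletion odds ratios are displayed as reciprocals.

Signal-decile curves rank 1 kb bins (partial terminal bins keep their true
mappable width) by mean replicate signal per mappable bp, count deletions per
bin, and report per-decile rates relative to decile 1 with bin-resampling
bootstrap CIs.

Individual filtering removes totals strictly below the 10th or above the 90th
percentile (linear interpolation). Note this operation is one-shot: re-running
it on the filtered cohort would tighten the thresholds, so stability holds
with respect to the originally computed bounds, not per repeated call.

## Reporter redesign

A 5-codon (15-base) window slides one codon at a time. Within a window every
synonymous codon combination is enumerated and keyed by (longest tandem
dinucleotide run in bp, total dinucleotide-repeat bp, longest homopolymer
run), lexicographically smaller sequences breaking exact ties. An edit is
applied only when the dinucleotide components strictly improve —
homopolymer runs alone never justify a substitution, which keeps
dinucleotide repeats prioritized and leaves a single codon untouched. Edited
codons are censored from later windows. Stop purging then removes TAA/TAG/TGA
from the +2 frame (the frame exposed by a 2 bp deletion; +1 screening is
available) by synonymous substitution of the two overlapping codons,
preferring fixes that preserve local repeat content, iterating to a fixpoint
and reporting unresolvable positions. Protein identity under the standard
code is asserted on every path. On random 200-codon CDSs the pass typically
triples the dinucleotide-repeat fraction (e.g. ~18% → ~57%).

## Synthetic data: what it emulates and what it does not

Backgrounds are i.i.d. per-base at a stated GC fraction (default 0.4) — no
higher-order Markov structure, no chromatin or replication-timing
covariates. Planted repeats are guarded by fix-up bases so each planted run
is exactly the maximal run a scanner recovers, making truth labels exact.
Deletion planting draws, with probability `tnt_bias`, from the
classifier-compliant site list, else uniformly from mappable sites; truth
flags record the branch, so the observed compliant fraction converges to
`bias + (1 − bias) · background`. Expression datasets give non-HETR genes a
shared lognormal gene-level mean (σ = 1.5) with tight cross-sample noise and
HETR genes high home-tissue/zero elsewhere expression, so the q90 rule
recovers truth exactly; deletions are placed per gene with expectation
∝ TPM^coupling. Signal tracks add gamma noise to a term proportional to
local planted-deletion density, two replicates differing only in noise.

Passing tests on these data demonstrate correctness of the statistical
machinery and recoverability of planted effects at realistic effect sizes;
they do not demonstrate robustness to alignment artefacts, caller-specific
error modes, mappability biases or covariate confounding in real genomes.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep the suite fast
while leaving clear statistical margins: 2–20 kb genomes for exhaustive
oracle comparisons, 100–200 simulated assays or datasets for calibration
checks, 2,000 null pairs per DM p-value in repeated-calibration settings
(10,000 for single analyses), B = 100–1,000 bootstrap replicates. Root
finding uses Brent's method on (10⁻¹², 10⁹); empirical p-values are smoothed
by (k+1)/(B+1); rates are exact ratios of integer counts. Repeat regions are
reported once per primitive unit, left-anchored and trimmed to whole copies
(span = r·n); consequently mirror-image annotations can differ by less than
one unit length at 2.5-copy-style runs, and the strand-symmetry test checks
equality up to that register.
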