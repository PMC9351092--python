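# Methods

## The problem

DNase digestion never removes genomic DNA (gDNA) from a total-RNA preparation
completely.  The residue survives library preparation — almost entirely so
under ribosomal depletion (Ribo-Zero, RZ), barely under poly(A) selection
(PA), because gDNA fragments rarely carry an oligo-dT-captureable poly-A
tract — and its fragments are sequenced and mapped like any cDNA.  Because
gDNA is spread uniformly over the genome while cDNA concentrates in gene
bodies, the fraction of mapped fragments landing in *intergenic* space (the
intergenic mapping ratio) is an observable proxy for the contamination level,
and contamination inflates every gene's FPKM by the *same* additive amount,
which perturbs low-abundance genes disproportionately and manufactures false
differential-expression calls.

## The model

For a library with spiked gDNA mass fraction `DNA_a` and residual fraction
`DNA_r`, the intergenic mapping ratio is modelled as linear in the gDNA
content:

    mapping_ratio_IR = (α·c·p_IR)·DNA_a + (α·c·p_IR)·DNA_r + α·cDNA_IR + ε

* `c` — DNA capture coefficient of the library-prep method (how efficiently
  gDNA survives target-RNA capture), dimensionless in (0, 1];
* `p_IR` — intergenic fraction of the genome (length of the complement of
  annotated genes plus assembled novel transcripts, over genome length);
* `cDNA_IR` — mass fraction of reverse-transcribed *unannotated* transcripts
  that map to the nominally intergenic region;
* `α` — scale relating mapped-fragment share to mass share.  Only the
  products `α·c·p_IR` and `α·cDNA_IR` are identifiable, so the package (and
  its simulator) fixes `α = 1`.

Estimation is sequential.  (1) The PA dilution series is fit by ordinary
least squares; since `c_PA ≈ 0`, its intercept estimates `α·cDNA_IR_PA`, the
polyadenylated unannotated-transcript background (the PA slope's F test is
recorded but does not enter the computation).  (2) Ribosomal depletion
additionally retains non-polyadenylated transcripts; assuming unannotated
transcripts mirror the annotated coding/noncoding composition, the RZ
background is `(1 + n_noncoding/n_coding) · cDNA_IR_PA`.  (3) The RZ fit's
intercept is `slope·DNA_r + cDNA_IR_RZ`, so

    DNA_r = (intercept_RZ − cDNA_term_RZ) / slope_RZ ,

and any single RZ library's total contamination is predicted by inversion,
`gDNA = (mapping_ratio_IR − cDNA_term_RZ) / slope_RZ`.  Negative estimates
are reported with a below-detection flag, not clamped (the one exception is a
negative PA intercept, clamped to zero with a flag, since a negative mass
fraction has no physical reading).

## Expression correction

Uniform contamination gives every gene of a library the same contamination
FPKM, equal to the FPKM of the intergenic region computed from
DNA-attributable intergenic fragments:

    FPKM_DNA = fragments_DNA_IR / (total_reads_M · intergenic_len_kb)

The corrected value is `max(FPKM_total − FPKM_DNA, 0)`; clipped cells are
counted and logged.  Correction precedes the DEG stage's +0.01 pseudocount —
subtracting a physical estimate from a pseudocounted value would bias short,
weak genes.  When fragments cannot be re-counted against a novel-transcript-
free intergenic region, the pipeline obtains `fragments_DNA_IR` by removing
the fitted cDNA background from the raw intergenic count,
`(mapping_ratio_IR − cDNA_term_method)·N`, which is algebraically the same
subtraction performed in ratio space.

## DEG screening

Fixed constants, all surfaced in configuration: pseudocount 0.01 added to
every FPKM; genes with pre-offset FPKM < 0.02 in ≥ 30% of a method's
libraries removed (the inclusive reading avoids boundary flicker at exactly
30%); two-sided pooled-variance Student t test on log2 values with unadjusted
p < 0.05; |log2 fold-change| > 1 on the linear offset values, both thresholds
strict; Pearson correlation of log2 expression against the nominal gDNA
fraction on the linear concentration scale across all replicate libraries,
two-sided p from the t transform of r, Bonferroni-corrected over all filtered
genes at 0.05.  A DEG whose gene passes the correlation screen is labelled
"Correlated" (gDNA-driven false discovery), otherwise "Not Correlated".
Welch's test and linear/log alternatives are available behind flags;
libraries with unknown gDNA content (no DNase treatment) are excluded from
fitting and correlation and are only scored by prediction.

## The synthetic experiment

The generator emulates the calibration design: gDNA spiked at {0, 0.01%,
0.1%, 1%, 10%} of total RNA mass on top of `DNA_r_true`, three replicates per
condition, both library-prep methods, fixed depth N per library.  Each
library is one multinomial draw of N fragments over (genes ∪ one aggregate
intergenic bin) with probabilities assembled from three mass components:
gDNA `c_method·(DNA_a + DNA_r_true)` spread uniformly (intergenic share
`p_IR`, genic share proportional to gene length), an intergenic
unannotated-transcript background (`cDNA_IR_PA_true`, scaled by
`1 + n_noncoding/n_coding` for RZ), and annotated cDNA taking the remainder,
distributed over captured genes (PA: coding only) proportionally to
abundance × length with per-gene abundances θ drawn log-normally.  By
construction the expected mapping ratio is *exactly* the linear model above,
so `noise="none"` (exact expected counts, kept as floats rather than rounded
precisely so these identities hold to ≈1e-9) recovers every parameter to
floating-point accuracy, and multinomial mode adds pure counting noise.

Defaults (the study conditions, scaled to desk size):

| parameter | default | rationale |
|---|---|---|
| genome / chromosomes | 50 Mb / 5 | scaled-down genome; keeps per-gene counts realistic at N = 2e6 |
| genes | 200 coding + 100 noncoding, 20–70 kb | gene-count ratio 0.5 ⇒ RZ background scale 1.5 |
| target p_IR | 0.73 | with c_RZ = 0.9 gives slope ≈ 0.657, the magnitude of the study fit |
| DNA_r_true | 0.018 | the residual fraction the decomposition should recover |
| c_RZ / c_PA | 0.9 / 1e-6 | rRNA depletion retains gDNA; oligo-dT capture of gDNA is negligible (the PA slope is statistically flat, as observed) |
| cDNA_IR_PA_true | 0.035/1.5 | so the scaled RZ cDNA term is 0.035 |
| θ ~ lognormal(0, 2) | — | FPKM dynamic range spanning ~4 orders of magnitude |
| N | 2e6 fragments | depth at which the mapping-ratio SE ≈ 1.5e-4, small against the spike signal |

Seeding: one experiment seed feeds per-library `SeedSequence` substreams
keyed by (method, fraction, replicate), so extending the design never
perturbs existing libraries and identical configurations are byte-identical
on disk.

### What the generator does and does not emulate

It reproduces the *compositional* structure the model rests on — uniform
gDNA placement, method-specific capture, an intergenic transcript background,
fixed sequencing depth — with multinomial counting noise only.  It does not
model read-level error, GC or positional coverage bias, fragment-length
effects, rRNA carryover, overdispersed biological replicate variability, or
misalignment.  Passing tests therefore demonstrate correctness of the
estimation and correction procedures under the model's own assumptions, not
robustness to real-data violations of them.  Two consequences are worth
stating plainly.  First, because fragments of all sources share a fixed
depth, contamination *dilutes* RNA fragments: true RNA-only FPKM falls
slightly as DNA_a grows, and the truth record stores that per-library value
(corrected values match it exactly in noise-free runs).  Second, with a 1.8%
residual floor in both arms of a comparison, a 1% spike cannot move any gene
past the two-fold threshold (bound 1 + 0.01/0.018 ≈ 1.55), so
contamination-driven DEGs appear only at the 10% spike; the large 1% DEG
excess seen in real data reflects noise structure this generator deliberately
omits.  Relatedly, the correction can slightly *increase* noise-driven DEG
counts in nearly-clean comparisons, because clipping near-zero corrected
values against the pseudocount inflates relative variance in weak genes —
the same effect observed for poly(A) libraries in practice.

## Numerical choices

* OLS, the slope F test (= squared t), the pooled t statistic and the
  Pearson t transform are closed-form; scipy supplies only distribution
  functions.  Perfect fits (zero residual variance) get F = ∞, p = 0.
* Genes with zero variance in both DEG groups: p = 1 when means are equal,
  0 otherwise.  Constant-expression genes get undefined r, flagged and never
  called correlated.
* Interval arithmetic is 0-based half-open internally (GTF converted at the
  boundary); fragment counting uses the ≥ 1-base-overlap rule by default
  with full containment behind a flag; strand is ignored throughout, since
  gDNA is double-stranded and the intergenic definition is strandless.
* Degenerate designs (all DNA_a equal, fewer than 3 points), non-positive RZ
  slope, zero denominators and double offset/adjustment all raise typed
  errors rather than returning NaN.

## Problem sizes used in the checks

Parameter-recovery runs use the full default design (30 libraries × 2e6
fragments) over 200 seeds; correction-direction runs use 100 seeds; oracle
comparisons use ≥ 100 random small instances per statistic.  These sizes give
Monte-Carlo standard errors well below the decision margins they support.

## Known limitations

The sequential procedure inherits the study's approximation that the PA
intercept is pure transcript background; the `c_PA·p_IR·DNA_r` it actually
contains biases `DNA_r` down by a factor ~`1.5·c_PA·p_IR/slope_RZ`
(negligible for realistic `c_PA`).  The coding/noncoding scaling assumes
unannotated transcripts mirror annotated composition.  The correction assumes
strictly uniform contamination; CNVs, mitochondrial excess or mapping bias
would break per-gene uniformity.  Totals are not recomputed after removing
intergenic fragments.
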