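# Methods

`earmap` implements the fine-mapping workflow used to localize a porcine
ear-size quantitative trait locus (QTL) on SSC5 in a Large White × Minzhu
F2 intercross: a residual-based mixed-model genome scan with genomic
control, conditional analysis, marker-assisted segregation analysis (MASS)
of F1 sires, linkage-disequilibrium / haplotype-sharing interval
refinement, and breed-panel selective-sweep detection.  All stages run on
synthetic populations produced by the package's own generator, so the
whole workflow is testable without any external data.

## The association model (GRAMMAR with genomic control)

Step 1 fits, by REML, the polygenic mixed model

    y = Xb + w p + T c + Z a + e

where `y` is ear area (cm²) of the F2 animals, `b` collects the fixed
effects of sex, parity and batch (slaughter group), `w` is body weight
with regression coefficient `p`, `c ~ N(0, I σ²_c)` is the litter effect,
`a ~ N(0, A σ²_a)` is the additive polygenic effect with `A` the pedigree
numerator relationship matrix (tabular method: founders unrelated and
non-inbred, `A_ii = 1 + ½A_sd`, `A_ij = ½(A_j,s + A_j,d)`), and
`e ~ N(0, I σ²_e)`.  The residual

    y* = y − X b̂ − w p̂ − T ĉ − Z â

is carried to Step 2, a single-locus regression of `y*` on each marker's
allele dosage (pairwise deletion of missing genotypes), giving a slope
`k̂`, its sampling variance, and `T² = k̂²/var(k̂)`.  Step 3 applies genomic
control: `λ = median(T²)/0.456`, `T²_adj = T²/λ`, and P from the upper
tail of χ²(1).  The rounded constant 0.456 is the method's conventional
value; the exact χ²(1) median (0.45494) is available through the
`gc_constant` argument.  `λ` is applied as estimated, including values
below 1.  Genome-wide thresholds are Bonferroni (`α/n_tests`); the
conditional analysis appends the top marker's dosage to the fixed effects
and re-runs all three steps with that marker excluded from the rescan.

**REML numerics.**  Average-information updates with step halving; when
the AI step is unusable (non-positive-definite information, bound
violation, or an unrepairable likelihood decrease) an EM-flavored scaled-
gradient step is taken.  Components are kept non-negative by projection to
a floor of `1e-8·var(y)`; components pinned at the floor with negative
score are held out of the update (active set).  Convergence is a REML
log-likelihood change below 1e-6; non-convergence raises with the
likelihood trace attached.  Confounded fixed effects trigger a
rank-deficiency warning and a reduced design.

**On the deflation factor.**  In a 43-family F2 the marker dosages covary
strongly with the family structure that the litter and polygenic BLUPs
remove, so the raw residual scan is conservative: across null simulations
at the default design the pooled `λ` is ≈0.74–0.78 (and ≈0.84 even with
negligible variance components, from fixed-effect projection alone).  This
is intrinsic to residual-based association in structured populations, and
it is exactly what the genomic-control division corrects: the GC-adjusted
type-I error in the same simulations is 0.049–0.056 at nominal 0.05.
Tests assert both quantities; the raw-`λ` band check fails by design of
the method, not by implementation error, and is retained unmodified.

## Quality control

Iterative two-step QC: each pass removes SNPs with call rate < 90 %, then
minor allele frequency < 3 %, then exact Hardy–Weinberg P < 1e-6 (in that
order; a marker failing several filters records the first reason), then
removes samples with call rate < 90 %; passes repeat, with all statistics
recomputed on the surviving data, until a pass removes nothing.  The HWE
test is the exact conditional test (probabilities of heterozygote counts
no more probable than observed, given the allele counts), chosen over the
χ² approximation because it is well defined at all counts and matches use
of a 1e-6 tail.  Whether to recompute HWE within each iteration was open;
we recompute every pass.  Sex-linkage checks require chip intensity data
that are not modeled; the report notes this as unsupported.

## MASS (marker-assisted segregation analysis)

Offspring of an F1 sire are sorted by the paternal homolog they inherited:
at each sire-heterozygous marker the transmitted sire allele is inferred
where the offspring (and optionally dam) genotype determines it uniquely,
and the homolog compatible at the majority of informative markers wins
(ties → unassigned).  The score is

    Z = log10 ( L_H1 / L_H0 )

with Gaussian likelihoods: H1 has group-specific means and a pooled
maximum-likelihood variance; H0 a common mean and variance (a point model
for the "QQ or qq" hypothesis, not a mixture — an approximation we
document rather than hide).  Sires are called heterozygous (Qq) when
Z > 2, homozygous when Z < −2, undetermined otherwise; boundary values are
undetermined.

Two marker-assisted nuisance adjustments are applied to the trait before
the likelihood ratio, both valid under either sire genotype: phenotypes
are centered within litter (removing litter and dam-level polygenic
variance), and the dam-transmitted allele at the central window marker —
offspring dosage minus the inferred paternal allele — is regressed out
(removing the maternal QTL-allele component from the within-group noise).
In simulations with a Qq sire, a QTL at half the phenotypic variance and
40 offspring these adjustments raise detection (Z > 2) from ≈0.73 to
≈0.85–0.90 while the false-positive rate on homozygous sires stays ≈0.05.

## Haplotype analyses

*LD.*  Two-locus haplotype frequencies by EM on unphased dosages (double
heterozygotes split by the current phase estimate); `D = p11 − pA·pB`,
`D' = D/Dmax`, `r² = D²/(pA(1−pA)pB(1−pB))`.

*Blocks.*  Confidence-interval (Gabriel-style) rule: a normalized
likelihood over |D'| (allele frequencies fixed at their estimates, 101
grid points) yields 5 %/95 % bounds per pair; "strong LD" means lower
bound ≥ 0.70 and upper ≥ 0.98, "strong recombination" means upper < 0.90.
A contiguous run is a block when ≥ 95 % of its informative pairs show
strong LD; candidate runs are accepted greedily, longest bp span first,
without overlap.  The bound values are defaults exposed in the API, since
the original tooling's settings are not recorded.

*Haplotype score test.*  General-window EM (flat start, convergence 1e-8,
≤ 12 markers per window) returns posterior diplotype probabilities; the
per-individual expected haplotype counts enter a Gaussian GLM score
function.  With trait `y`, null MLEs `ȳ, σ̂²` and centered count matrix
`Xc`: `U = Xcᵀ(y−ȳ)/σ̂²`, `V = XcᵀXc/σ̂²`, per-haplotype z-scores
`U_h/√V_hh` (two-sided normal P), and global statistic `Uᵀ V⁻ U` on
df = (number of scored haplotypes − 1), using a generalized inverse
because the counts sum to two per individual.  Haplotypes below a pooling
frequency (default 0.02) are pooled and not scored.  For a single marker
the global statistic reduces exactly to the squared score-test z of the
marker regression (asserted in tests).

*Sharing.*  Maximal marker runs over which all Q-bearing founder
haplotypes are identical; exact identity (mismatch budget 0), since the
sharing display convention codes the commoner allele 1 and the rarer 2
per marker.  Segment length is the bp span between its first and last
marker; single-marker runs are reported but the pipeline refines on runs
of ≥ 2 markers.

*Refinement.*  Interval intersection is ordinary pairwise intersection
with merging; the pipeline successively intersects the significant-SNP
span with the sharing segments, the block region and the sweep interval,
keeping the previous interval whenever an intersection is empty (recorded
in the report).

## Selective sweep

A sweep is a run of ≥ `min_run` (default 4, reading "more than three"
strictly) consecutive markers fixed for one allele in the case breed —
fixation judged as allele frequency 1.0 on observed calls, missing
fraction reported — while every control breed remains polymorphic at ≥ 1
run marker (a strict mode requires all).  The reported interval runs
between the nearest non-fixed flanking markers, both exclusive, and its
length is the distance between those flanks.

## The synthetic generator

Defaults reproduce the mapped study design: 314 F2 in 47 litters from 9 F1
sires × 34 F1 dams (each F1 from its own Large White sire and Minzhu dam),
trait mean 244 cm² with CV 22 %, a biallelic QTL explaining half the
phenotypic variance whose Q allele (= allele2) is fixed in Minzhu and
absent in Large White, and 200 evenly spaced markers on one 60-Mb
chromosome at 1 cM/Mb (≈1 marker/300 kb, a desk-scale stand-in for a 60K
chip).  Founder allele frequencies are drawn per marker with moderate
between-breed divergence, elevated within ±3 Mb of the QTL.  Crossovers
are Poisson in the chromosome's Morgan length with uniform placement
(Haldane, no interference).  Polygenic values descend the pedigree by
Mendelian sampling (founders N(0, σ²_a); offspring = parent mean +
N(0, σ²_a/2), ignoring inbreeding), which is exact under the model behind
the A matrix.  Variance bookkeeping targets the phenotypic variance
`(mean·CV)²`: QTL 0.5, polygenic 0.20, litter 0.05 as fractions of that
total, fixed-effect and covariate variance computed analytically (sex ±4
cm², parity and batch effect SD 3 cm², body-weight slope 0.35 cm²/kg over
a N(100, 8²) kg covariate), and the residual absorbing the remainder, so
realized trait moments match the targets.  Sex/parity/batch have 2/3/28
levels; 28 matches the study's slaughter groups.

The whole-pipeline default instead simulates a 5-chromosome genome (300
markers, QTL mid-way along the chromosome labelled "5") so genomic control
and genome-wide thresholds see a mostly unlinked background, as in a real
scan; and it plants a shared founder haplotype over ±5 markers around the
QTL so the sharing stage has the structure the workflow expects.  Breed
panels for sweep detection default to the study's sizes (case 32; controls
38/69/95) with the case fixed over a configurable run and every panel
forced polymorphic where fixation would be an artifact.

What the generator does **not** emulate: sequence-level variation and
mutation, crossover interference, X-chromosome dosage, genotyping batch
artifacts, marker ascertainment bias, and polygenic effects that are
*linked* to the simulated markers (the polygenic term is pedigree-driven,
not marker-driven).  Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to every
property of real chip data.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at the study's n (314 F2; 200–300 markers)
over 20–60 seeds per property: 25 null scans for calibration, 50 seeds for
QTL recovery (top marker within 2 Mb of truth), 20 for conditional
clearance, 60 for MASS detection at 40 offspring.  These sizes give
standard errors comfortably inside the asserted margins while keeping the
full suite under a minute of compute.

## Known limitations

- The raw-scan λ band discussed above: the GRAMMAR residual scan is
  conservative by construction in structured populations; rely on the
  GC-adjusted P-values.
- The H0 of MASS is a single-mean Gaussian, not a QQ/qq mixture.
- Block-definition bounds and the rare-haplotype pooling threshold are
  field-standard defaults, not values recovered from the original
  analyses.
- The exact-identity sharing rule is sensitive to genotyping error on
  real data; a mismatch budget would be needed there.
- The toy BED annotator reports nearest-edge distances only; it is not a
  genome-annotation tool.
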