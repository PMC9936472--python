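# Methods

This note documents the statistical models implemented in memoryflow,
the assumptions behind the synthetic-data generators, and the numerical
and design choices that were genuinely open.

## Screen statistic

**Model.**  For one strain and GFP gate, barcode counts against the
pooled wildtype controls across a timepoint transition follow a binomial
GLM with logit link: response = (strain count, pooled control count) per
(timepoint, replicate) cell, linear predictor = intercept + replicate
factor + timepoint factor.  The timepoint coefficient β is the log
odds-ratio of the strain/control composition across the transition.
Quasibinomial overdispersion is estimated as Pearson X²/df_resid and the
standard error is scaled by √max(φ, 1).  A single-replicate design is
saturated and solved in closed form (β = ln odds-ratio), with a
Haldane–Anscombe 0.5 correction only when a cell is zero; the GLM path
never applies the correction.  Complete separation returns a capped
estimate (|β| ≤ 15) flagged `converged=False`.

**Dispersion pooling.**  A per-fit dispersion at one or two residual df
is far too noisy to calibrate a z-score: flooring it at 1 deflates the
null z variance well below 1, while using it raw produces heavy tails
(the reciprocal of a χ²₁ has no mean).  Overdispersion in a pooled
screen is a property of the assay, not of one strain×gate fit, so the
default pools Pearson X²/df over every fit of the screen and applies the
single pooled φ to all standard errors (`dispersion_pooling="global"`);
`"per_fit"` reproduces the per-model behaviour of a stock quasibinomial
fit for comparison.

**Memory z and combination.**  Per gate,
z = (β₁ − β₂)/√(se₁ + se₂) compares the naive transition (TP3→TP4) with
the primed one (TP5→TP6).  The denominator is implemented exactly as
written — the *sum of standard errors* under the root — with
`se_combine="quadrature"` (√(se₁² + se₂²), the conventional unit-variance
form) available as an option.  The as-printed form deflates |z| whenever
the SEs are below 1, so calibration checks (null variance of z) use the
quadrature option, while default pipeline calls use the as-printed form.
Gates are combined as Z = Σ wᵢ|zᵢ| / √(Σ wᵢ²) with FACS sorted-cell
counts (summed over the four transition timepoints) as weights; |z| is
used because a real memory strain redistributes cells between gates, so
per-gate z legitimately changes sign once across the gate order.  The
sign-change filter admits at most one change, zeros skipped, in gate
order R5→R8 (the ordering is a package choice; no other ordering is
biologically meaningful).  Direction: if all nonzero z share a sign, a
positive common sign (weaker primed response) is *decreased* memory;
with one sign flip the call follows the gate-score trend — z > 0 in high
gates means the strain lags the controls' primed gate shift, hence
decreased memory.

**Significance threshold.**  No universal cutoff exists for the
as-printed Z.  The default is 4 (conservative); the recommended practice,
used by the acceptance checks, is `null_calibrated_threshold`: simulate a
null screen at matched depth and take the (1 − fpr) quantile of null Z.

**GFP score.**  Per sample, strain reads are divided by the sample
total; the relative abundance is multiplied by the gate's share of FACS
events at that timepoint; the score is the mass-weighted mean of the gate
scores (R5=1 … R8=4), hence always in [1, 4] and monotone under mass
shifts toward higher gates.

**Screen generator.**  Gate occupancy of strain k at timepoint t is
softmax((τ_t + θ_k(t))·s) over gate scores s = (−1.5, −0.5, 0.5, 1.5).
τ_t is the shared wildtype tilt along the experiment; its magnitudes on
the analyzed transitions are moderate (|τ| ≤ 0.6) so every gate keeps
roughly ≥15 expected reads at the reference depth of 50
reads/strain/gate — small-count Wald errors would otherwise decalibrate
the z-score.  θ_k jumps by the strain's memory effect δ at the primed
re-induction, which makes the per-gate log-odds change across the primed
transition graded in the gate score (monotone, at most one sign change)
— a uniform shift would cancel inside the within-strain normalization
and is not observable in this design.  Totals per strain×sample are
Poisson around depth × a log-normal (σ = 0.2) library factor, split
across gates multinomially; `dispersion_inflation` > 1 switches to a
Dirichlet-multinomial whose concentration is chosen to match the target
Pearson dispersion (beta-binomial gate margins).  `noiseless=True`
writes expected counts, under which every null strain's z is exactly 0.
Eight wildtype-barcoded control strains (δ = 0 by construction) form the
pooled reference; a flag selects a single control instead.

Because all strains in one screen share one realization of the control
noise, the per-gate z across strains *within* a screen has variance
n_c/(n_c + 1) ≈ 8/9 of nominal and a screen-specific offset.  Null
calibration is therefore measured across independent simulated screens
(25 screens × 20 strains), where the variance of z is within Monte-Carlo
error of 1.

## Expression classification

**Normalization.**  Size factor = per-sample coding-transcriptome sum /
geometric mean of those sums; counts are divided by it.  This measures
*relative* abundance: a gene's lfc is only meaningful jointly with the
rest of the transcriptome.

**Differential test.**  lfc = log₂((mean_t + 0.5)/(mean_t0 + 0.5))
against naive t0 of the same strain.  p-values come from a
negative-binomial Wald test on the log2 means.  The default shares one
method-of-moments dispersion across all genes of a contrast (untruncated
per-gene moment estimates averaged, then floored at 1e-8) with a normal
reference — the information sharing that lets 3-replicate designs reach
small p, in the spirit of DESeq2's dispersion shrinkage; `per_gene` mode
keeps gene-wise estimates with a t reference on n₁+n₂−2 df and is
markedly conservative.  On a 2000-gene NB null at 3 vs 3 the pooled test
holds the nominal 0.05 level within [0.03, 0.08].  padj is
Benjamini–Hochberg within each contrast.  The classifier equally accepts
an externally produced lfc table (`ExpressionMemoryModel.from_lfc_table`)
so a DESeq2 export can replace the internal engine.

**Rules.**  All inequalities strict; boundary ties are never called.
Induced: lfc(t180) > 0, lfc(t60′) > 0, lfc(t180) > lfc(t60),
lfc(t180) > lfc(t30), padj < 0.001 at both the t180 and t60′ contrasts
(the two endpoints named for naive and primed induction).  Repressed is
the mirror.  Induction memory: lfc(t30′) − lfc(t30) > log₂ 1.5 or
lfc(t60′) − lfc(t60) > log₂ 1.5; repression memory mirrored with
< −log₂ 1.5.  TM_score = lfc(t15′) − lfc(t180) for both induced and
repressed genes (one formula).  Mutant effect from ΔTM = TM_mut − TM_wt:
induced genes are *enhanced* above +0.58 and *attenuated* below −0.58;
repressed genes the reverse.  Effect categories are only reported for
genes carrying the memory flag in at least one strain
(`require_memory_flag=False` relaxes this).  The base class comes from
the wildtype strain; the memory flag from either strain.

**Expression generator.**  Each of the nine categories gets a planted
wildtype and mutant lfc trajectory sitting `margin` (default 0.5) beyond
every threshold it must clear.  Counts are NB (gamma-Poisson,
α = 0.05 by default) around baseline 200 × 2^lfc × a log-normal size
factor; α = 0 writes expected counts (the noiseless limit in which
classification recovers every planted label exactly).  Because coding-sum
normalization measures relative abundance, the planted lfc are only
recoverable if the summed transcriptome 2^lfc is constant over
timepoints; a *ballast* class (4× the signal genes, per strain) absorbs
the composition shift, and its truth label is whatever the classification
rules assign to its own exact trajectory.  The generator emulates
trajectory shapes and NB noise, not gene-length effects, batch structure,
or DESeq2's exact shrinkage — passing recovery tests shows the rule
logic and normalization are correct, not that real data would classify
identically.

## Turnover

θ = converted/total reads per gene×condition, genes under 20 total reads
dropped per condition independently (a gene can be measured in naive but
not primed).  The mapping to rates assumes synthesis/decay steady state
during the 10-min pulse: θ = 1 − e^(−k·t_label), so k = −ln(1−θ)/t_label,
t½ = ln2/k, degradation rate = 60·ln2/t½ per hour.  This first-order
mapping is the package's explicit model choice; raw θ is always reported
alongside, and no rate conversion is attempted for timepoints inside the
galactose response where steady state does not hold.  Pulse-chase decay
is fitted by OLS of log(labeled fraction) on time (points ≤ 0 dropped,
k floored at 0 and flagged on a positive slope); on noiseless
first-order data it agrees with the steady-state mapping to 1e-9.
Group shifts in Δθ use a two-sided rank-sum test: exact enumeration
(tie-safe, deviation-from-mean two-siding) when either group has ≤ 8
members, normal approximation with tie correction otherwise.

The SLAM generator draws totals ~ Poisson(reads/gene) and conversions ~
Binomial(total, θ·detection_efficiency); it does not model per-read
conversion-count mixtures, SNP contamination, or uridine content, so
recovery tests validate the estimator arithmetic, not read-level calling.

## Occupancy and CRAC

Coordinates are 0-based half-open throughout; the closed literature
ranges map to half-open offset windows of identical width
([−150, −50) etc.).  Offsets o map to TSS+o on the + strand and TSS−o on
the − strand; antisense regions read the opposite strand's track;
nucleosome/NDR regions are unstranded (both strands summed).  Region
means are arithmetic per-base means; condition ratios use a 0.01 cpm
pseudocount (both-zero regions ratio to 1).  Metagene profiles align
per-gene windows on the TSS in transcription direction, exclude genes
whose window exits the chromosome (counted), average across genes, and
smooth with a centered 5-bp moving mean whose window truncates at the
edges (interior values are exact local means).

CRAC association: score_g = (factor_g/Σfactor)/(polII_g/ΣpolII) over
genes with ≥ 20 counts in *both* libraries (the conservative reading of
a "less than 20 counts" filter that does not name the library; a flag
relaxes to factor-only).  Totals are taken over the retained genes; the
score is invariant to rescaling either library.

The coverage generator places genes ≥ 2 kb apart on one linear
chromosome, alternating strands, with Gaussian dyad peaks (split equally
between strand tracks) and rectangular promoter signals; truth records
analytic region means.  The CRAC generator draws Poisson counts around
planted association ratios.

## Pipeline

One global seed; each stage derives an independent substream via seed
sequences.  All outputs are plain-text TSV/bedGraph/BED6/JSON with fixed
float formatting, so identical configs give byte-identical files (the
JSON report echoes the output directory path and is excluded from that
guarantee).  Stage reports obey in = kept + filtered for every filter.
CLI defaults are the published thresholds: ratio 1.5, ΔTM band 0.58,
padj 0.001, 20-read and 20-count filters, 10-min label pulse.

## Problem sizes

The test suite and acceptance script use desk-scale simulations chosen
to keep Monte-Carlo error well inside the asserted bands: 500 null
strains across 25 screens and 40 planted strains for the screen, 4500
genes (900 signal) for classification, 1400 gene×condition measurements
for the turnover grid, 300 genes for the CRAC comparison, and 1000
random genes for the coordinate geometry checks.

## Known limitations

- The as-printed z denominator is not unit-variance; all calibration
  statements refer to the quadrature option.  Both are exposed.
- The internal NB Wald test is a stand-in for DESeq2; lfc values agree
  by construction of the formula but p-values will differ in detail.
- Half-open region endpoints may be off by one base relative to
  analyses using closed intervals.
- The screen generator's graded gate effect is one plausible
  data-generating dual of the fitted GLM; real mutants may move through
  gates in more complex ways.
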