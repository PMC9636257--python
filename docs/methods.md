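# Methods

This note documents the models and procedures implemented in `sedapipe`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real data.

## The analytical problem

Lake-sediment ancient DNA (sedaDNA) metabarcoding produces, per sediment
sample, read counts of amplicon sequence variants ("barcodes") across
several independent PCR replicates, together with negative extraction and
PCR controls. The counts are noisy in characteristic ways: sporadic
replicate dropout of rare templates, laboratory contaminants, polymerase
slippage artifacts (homopolymer length variants), and imperfect reference
matches for degraded templates. `sedapipe` turns such tables into
quality-gated community matrices, ecological-indicator series,
stratigraphic zones, a temperature reconstruction, and a multivariate
driver analysis.

## Retention cascade (`filtering`)

A barcode is retained when all of the following hold: sequence length
>= 10 bp, not a dataset-wide singleton, a perfect (100%) match to at
least one reference database (the maximum across databases is used,
because identifications from several libraries are consolidated with
priority to the best local one), raw total reads >= 10, and detections in
>= 3 replicates. A cell counts as a *detection* only with >= 3 reads;
retained tables have sub-threshold cells zeroed so that 1–2-read noise
cannot leak into downstream indices. The "three replicates" rule is read
dataset-wide (its literal phrasing); a per-sample mode is available via
`FilterParams(replicate_scope="sample")`.

Cascade order: length/singleton → identity → homopolymer merge →
detection/total thresholds → contaminant removal. Merging precedes the
thresholds deliberately: a true variant's reads then rescue its source's
totals rather than being discarded.

**Homopolymer merging.** Two sequences are artifact-related when they
differ only in the length of a single homopolymer run. Each such variant
is summed into the *most abundant* strictly-more-abundant related barcode
(abundance ties never merge; candidate ties break lexicographically by
sequence); chains resolve transitively toward the final unmerged source.
Targets are decided on the input table's totals, so the outcome is
independent of merge order.

**Contaminant rule.** A barcode whose mean per-unit read count in
negative controls exceeds its mean in sediment samples is removed, unless
its taxon is whitelisted (ecologically plausible taxa independently
confirmed by another proxy, e.g. conifers confirmed by pollen). All
control-detected taxa are logged regardless.

**Mammal curation.** For the 16S marker, off-target taxa (human — a
ubiquitous contaminant — and pig, indistinguishable from wild boar at the
locus) are discarded, barcodes are collapsed by assigned taxon, and a
(taxon, sample) occurrence is flagged *sporadic* (likely contamination)
when it rests on exactly one replicate detection with no detection in the
stratigraphically adjacent retained sample on either side (window
configurable).

## Sample quality (`sample_quality`)

Two bounded scores gate samples:

- `MTQ(s)` — fraction of the sample's raw reads on perfect-match
  barcodes (technical quality);
- `MAQ(s)` — fraction of raw reads on barcodes surviving the full
  cascade (analytical quality).

These read-fraction definitions are a reconstruction — the source
convention is not printed in full — so both formulas live in one function
(`compute_quality`) for easy replacement; `MAQ <= MTQ` is asserted, since
retained barcodes are a subset of perfect matches. Gates: *relaxed*
requires MTQ >= 0.45 and MAQ >= 0.175 (thresholds set at the maximum
scores observed in negative controls); *strict* requires both >= 0.9.
Strict membership is a subset of relaxed by construction. Diagnostics
correlate each metric (plus raw read count, read-weighted mean barcode
length, mean wtRep, proportion terrestrial) with sample age and richness,
Pearson and Spearman, two-sided at alpha = 0.05 with no multiplicity
correction — these are diagnostics, not inference.

## Relative Abundance Index (`abundance`)

For sample *s* and taxon *t*:

    RAI(s, t) = prop_reads(s, t) * wtRep(s, t)

`prop_reads` is the taxon's share of the sample's retained reads.
`wtRep` weights each replicate's detection by the taxon's read count
relative to the *maximum* count among retained taxa in that replicate,
averaged over all replicates the sample ran. The per-replicate-maximum
normalizer is the default because it bounds a replicate-dominating taxon
at weight 1; the per-replicate-sum alternative is available
(`norm="sum"`) since the source convention is not printed. Replicates
that yielded zero retained reads stay in the denominator — a failed PCR
is evidence of low detectability — but replicate columns that were never
run do not. Both factors are scale-free, so RAI is invariant to uniform
scaling of a sample's counts, and per sample the values sum to <= 1.

## Indicator grading (`indicators`)

A barcode maps to its haplotype-sharing species (all species whose
reference sequences are identical at the marker). Per ecological
dimension — elevational belt, pastoral flag, arable flag — the barcode is
an *optimal* indicator only if every haplotype-sharing species carries
the same value (unanimity); any conflict, missing species, or missing
value makes it unsuitable *for that dimension only*. Intermediate
agreement levels (e.g. 3-of-4 majority) are logged but never used: the
published gradient from optimal to not-suitable is collapsed to a binary
because only unanimous sequences feed the series. Species names match
after whitespace/case normalization; no fuzzy matching.

Derived series: belt profiles (RAI summed per belt and renormalized over
belt indicators; a count-based variant — share of detected indicator taxa
— is available, covering the two plotting conventions), pastoral/arable
RAI sums, per-sample richness (count of recorded taxa; loess span 0.1 for
display), and growth-form proportions.

## Zonation (`zonation`)

CONISS: agglomerative clustering in which only stratigraphically adjacent
clusters may merge, choosing at each step the merge with the smallest
increase in within-cluster sum of squares about centroids (squared
Euclidean distance on the transformed matrix; default transform is the
fourth root, matching the ordination transform, with chord distance
available). Increment ties break toward the stratigraphically older
merge. The increments sum exactly to the data's total dispersion, which
the tests assert to 1e-10.

The number of significant zones uses the broken-stick convention: the
k-th split's proportional dispersion reduction (the corresponding merge
increment over total dispersion) is compared with
`E_k = (1/n) * sum_{j=k..n} 1/j`, and zones count 1 + the leading splits
that exceed expectation. `optimal_partition` is the exact
dynamic-programming minimization of total within-zone sum of squares over
contiguous partitions, used as the cross-check for cut positions.

## Temperature transfer function (`transfer_function`)

WA-PLS with 2 components on square-root-transformed assemblage
proportions, the standard configuration for chironomid–July-temperature
calibration. Component extraction is iterative weighted averaging with
orthogonalization (site-total weighted inner products) and inverse
deshrinking by weighted regression; with one component the procedure is
algebraically identical to classical weighted averaging with weighted
inverse deshrinking, which the tests verify to 1e-8. If the assemblages
carry no compositional signal (all sites identical) the model degrades
gracefully to predicting the weighted mean temperature.

Uncertainty: bootstrap cross-validation (default 9999 cycles; the test
suite and acceptance script use 199–999 cycles, a scaled-down cycle count
that leaves the estimators unchanged). RMSEP pools out-of-bag residuals
across cycles (an out-of-bag reading of "cross-validation by
bootstrapping"); the sample-specific error follows the standard
palaeolimnological combination `eSEP(s) = sqrt(s1(s)^2 + s2^2)` with `s1`
the SD of the bootstrap predictions for *s* and `s2` = RMSEP.

Low-count fossil samples are amalgamated greedily: the topmost deficient
sample merges with its nearer-in-depth neighbour until every unit reaches
the minimum count (default 40), with a per-sample exception list for
deliberate departures.

## Driver analysis (`drivers`)

Community matrices enter RDA fourth-root transformed. RDA is the
eigen-decomposition of the fitted values of the multivariate least-squares
regression of the centered community on standardized covariates; inertia
is variance (SS/(n−1)), and constrained plus unconstrained inertia equals
the total to 1e-10. The gradient-length (DCA) diagnostic is *not*
implemented: the linear-method choice is accepted as given, and the
function documents this.

Significance uses Pillai's trace with permutations: whole-model tests
permute rows of the centered community (the total SSCP is
permutation-invariant, which the implementation exploits); single terms
are tested partially via Freedman–Lane (permute reduced-model residuals,
add the reduced fit back). `p = (1 + #{perm >= obs}) / (1 + n_perm)`;
unrestricted permutations, since no temporal blocking is specified.
Forward selection: a candidate enters when it minimizes
`AIC = n ln(RSS/n) + 2(k+1)` (RSS = total residual SS of the multivariate
fit), improves on the current AIC *and* is significant marginally
(permutation p < 0.05); a drop phase follows each addition; candidates
collinear with the selection are skipped.

The richness GAM is Poisson with log link: one cubic regression spline
per covariate (basis dimension 10, uniform interior knots, second-order
difference penalty), fitted by penalized IRLS. Each smooth is
reparameterized into its penalty null space (absorbed by the intercept
and a linear column) plus an identity-penalized range part, so as the
smoothing parameter grows the fit collapses *exactly* onto the linear
Poisson GLM — the tests verify the limit at 1e-6 against an independent
GLM fit. Smoothing parameters come from GCV over a log grid (coordinate
descent, two passes) with the customary gamma = 1.4 inflation that guards
against undersmoothing. A companion linear GLM screens outliers
(|Pearson residual| > 3), which are removed before the final fit.
Residual autocorrelation is summarized by the Durbin–Watson statistic
(`sum (e_t − e_{t−1})^2 / sum e_t^2`) on age-ordered deviance residuals.
Predictions are reported on 500-point per-covariate grids (others at
their means) with ±1.96 SE bands formed on the link scale and
exponentiated.

Piecewise SEM: each endogenous variable is fitted by OLS on its parents
(the generalized-least-squares original with no stated correlation
structure reduces to OLS; an AR(1) variant is a natural extension but not
wired in). Standardized coefficients are raw × SD(x)/SD(y). Model fit is
Shipley's d-separation test: for every non-adjacent pair with at least
one endogenous member (pairs of two exogenous variables are excluded —
their covariance is unmodelled), the conditional independence given the
union of both parents is tested by a partial regression p-value, and
`C = −2 sum ln p_i` is compared to chi-square with `df = 2k`. A saturated
DAG yields C = 0, df = 0, p = 1.

Loess: local polynomial regression of degree 2 with tricube weights; the
span is the fraction of points per window (at least degree + 1).

## Synthetic data (`synthetic_data`)

The generator defines the study conditions the tests run under:
80 sediment samples at 10-cm spacing (16 yr/cm), 8 extraction and 8 PCR
negative controls, 8 PCR replicates (4 would be the mammal setting),
40 plant taxa with lognormal base abundances (sigma = 1), per-replicate
read totals negative-binomial around 1000 reads (shape 5), and
per-replicate inclusion logistic in log10 true abundance (slope 1.5 per
decade, midpoint at 0.5% abundance) — the abundance–replicability
coupling that RAI exploits. Contaminants (2 taxa) receive ~400
reads/replicate in controls versus ~5 in samples, so the removal rule has
unambiguous truth; negative controls carry only contaminant reads unless
cross-talk is switched on. Homopolymer artifacts copy the most abundant
templates with one run length ±1 and 5% of the source's reads. Three
taxa carry an imperfect (0.97) best match with an age-increasing
abundance share (decay 3.0 on the log scale), emulating the declining
assignability of degraded DNA down-core; this is what makes the strict
gate bite on old samples while everything passes the relaxed gate.
Haplotype-sharing species sets (1–4 species) are unanimous except for 4
planted conflict taxa. The chironomid calibration uses Gaussian
unimodal responses (274 sites, 30 taxa, optima spread over 4–18 °C,
tolerance 2 °C, multinomial counts of size 120) and a sigmoid deglacial
fossil trajectory (73 samples, 6–12 °C). Driver series are smooth
Holocene-shaped trajectories (deglacial temperature ramp, mid-Holocene
organic-matter optimum, late-Holocene fire/grazing rise) with 5% relative
noise; composition responds through a per-taxon linear effect matrix on
log abundance, off by default and switched on where recovery is tested.

What the generator does *not* emulate: sequence-level substitution and
chimera errors, amplification bias beyond the detection model, taxonomic
mis-assignment, age-model uncertainty, and the spatial taphonomy of real
catchments. Passing tests therefore demonstrate that the algorithms
implement their stated contracts and recover known structure under
realistic replicate/contamination/dropout noise — not that any particular
real-world record is analysed correctly.

## Numerical conventions and degenerate inputs

- Nearest-age alignment ties go to the younger point (deterministic).
- Empty samples yield all-zero RAI rows and are flagged, never imputed.
- Samples lacking any belt indicator get NaN belt rows (flagged empty).
- CONISS increment ties break toward the older merge; equal-abundance
  sequences never merge as artifacts.
- Permutation p-values are never zero (the +1 convention).
- Zero-variance inputs error loudly (Durbin–Watson on zero residuals,
  constant covariates in RDA, constant covariate in a GAM smooth).
- All randomness flows from one integer seed; per-stage child streams are
  spawned deterministically, so reruns are byte-identical.

## Problem sizes used by the test and acceptance runs

Unit tests run the generator at 10–24 samples and the calibration at
50–200 sites; the acceptance checks run 200 random tables for the
filtering oracle, 500 for the RAI contract, 100 matrices (n <= 8) for the
CONISS oracle, 1000 null data sets x 199 permutations for the Pillai
size, 500 data sets (n = 500) for the Fisher's C size, and 199–999
bootstrap cycles for WA-PLS — sizes chosen so the full suite completes in
well under a minute per criterion on one CPU while keeping Monte Carlo
error far below the asserted bands.

## Known limitations

- MTQ/MAQ are reconstructions of an unprinted convention (bounded read
  fractions); swapping in the original definitions is a one-function
  change.
- The wtRep normalizer (max vs sum) is likewise a documented choice.
- The GAM's basis/penalty configuration is a standard reconstruction of
  "a GAM" (k = 10 cubic splines, second-order difference penalty, GCV);
  REML selection is not implemented.
- The SEM assumes Gaussian OLS sub-models and independent observations;
  temporal autocorrelation is summarized (Durbin–Watson) but not
  modelled.
- RMSEP is bootstrap out-of-bag; leave-one-out would differ slightly.
- The mammal sporadic-occurrence rule uses a one-sample adjacency window
  by default; wider windows are configurable but untested against real
  records.
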