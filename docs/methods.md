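# Methods

This note records the models implemented in `lipidims`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer from the code.

## Mass scale

All m/z values derive from elemental formulas and NIST monoisotopic masses
(¹H 1.00782503207, ²H 2.01410177785, ¹²C 12 exactly, ¹⁴N 14.0030740048,
¹⁶O 15.9949146196, ³¹P 30.97376163 Da). Protonation and deprotonation use
the proton mass 1.00727647 Da — the hydrogen atom minus one electron — so
electron bookkeeping is exact; this is the convention that reproduces the
deuterated internal-standard masses (butyryl-d7-carnitine [M+H]⁺
239.19827, hexadecanoyl-d3-carnitine [M+H]⁺ 403.36097) to five decimals,
which an H-atom convention does not. [M+Na]⁺ and [M+NH4]⁺ subtract the
electron mass likewise.

Species formulas come from per-class composition rules written as functions
of total acyl carbons c and double bonds d (e.g. diacyl-PC:
C(c+8)H(2c−2d+16)NO8P; ceramide on a d18:1 backbone: C(c)H(2c−2d+1)NO3;
cholesteryl ester counting only fatty-acyl carbons: C(c+27)H(2c−2d+44)O2;
sterols with the four rings outside the double-bond count). A hydroxyl
substitutes H → OH, i.e. adds exactly one oxygen. The rule table is
versioned (`COMPOSITION_RULES_VERSION`); a custom library can be supplied
as CSV instead.

## Libraries and isobars

The CID fatty-acid library is the exhaustive enumeration C14–36 × 0–6
double bonds × 0–1 hydroxyl as [M−H]⁻ within 50–1000 Da (322 ions). The
built-in intact-lipid library is a reconstruction of a typical shotgun
target list (the original instrument list is not public); its class/carbon/
double-bond ranges live in `default_intact_specs` and users should expect
library sizes, not masses, to differ from any particular lab's list.

Direct infusion cannot separate isobars, so ions within the matching
tolerance are clustered by single linkage (default 9 ppm, mirroring the
match tolerance) into isobar groups. Since no algorithm can decide
biological likelihood from m/z alone, each group carries a ranked
annotation list from a static, configurable class-priority table (default
PC > PE > TG > SM > CE > Cer > others; remaining ties by m/z then label)
and the top-ranked annotation represents the group in class aggregation.
This is a documented convention, not an inference.

## Matching and QC

Each observed peak is assigned to the ion minimising |ppm| deviation,
accepting matches within 9 ppm (intact) or 12.5 ppm (CID fatty-acid mode).
Ties — including ions with identical elemental composition and therefore
identical m/z — resolve deterministically to the lower-m/z ion and, within
an equal-m/z run, to the first ion in library order, so repeated runs and
jittered masses can never split one signal across two feature columns.
Replicate peaks from one sample matching the same ion are summed. In CID
mode unmatched signals above noise are carried forward as unannotated
features keyed by their cross-sample mean m/z; in intact mode they are
dropped.

Filter thresholds are strict as worded: median S/N < 3 discards (the median
over detected entries), presence < 20% of all retained samples discards
(per-group presence is available by configuration), dilution-linearity
keeps Pearson r > 0.75 against the QC-pool dilution factors on the raw
intensity scale (a log-scale switch exists; zero-variance pools are
"degenerate" and discarded), and samples detecting < 66.7% of features are
excluded — a sample at exactly the boundary is kept. Multivariate outlier
flags (|PC1/PC2 score| > 3 SD) are advisory only and never auto-exclude,
because a reproducible pipeline cannot encode a judgement call. Every
filter reports feature-in = feature-out + per-rule discards; nothing drops
silently.

## Preprocessing

Order is fixed and logged in provenance: per-mille scaling → zeros become
missing → NIPALS imputation → normalization; statistics run on the final
log₂ values, while fold changes are computed on the pre-log per-mille
scale to match the reporting convention of relative-abundance figures.

**Imputation.** The model is x_ij ≈ μ_j + t_i p_j: column means plus one
NIPALS component fitted using only observed entries. Column means taken
over observed entries alone are biased whenever missingness is uneven
across rows, and a single centre-fit-impute pass then fails the defining
property of the method (exact reconstruction of a rank-one matrix). The
imputer therefore iterates the cycle — recompute column means from the
completed matrix, refit, re-impute — to a fixed point (tolerance 1e-8
relative to the data spread, cap 2000 cycles; inner NIPALS converges on
the relative change of the score vector, cap 500, deterministic
initialisation from the highest-variance column, no RNG anywhere).
At the fixed point a rank-one matrix is recovered exactly (the test
asserts 1e-6). Observed entries are never modified; imputed abundances are
floored at 0 because per-mille values cannot be negative. Zero-floored
entries are subsequently raised to half the feature's smallest positive
value — the conventional detection-limit floor — because the log step of
normalization requires strictly positive values.

**Normalization.** "Cyclic loess" sweeps all unordered sample pairs
(3 iterations): per pair, the log₂-ratio M is regressed on the log₂-average
A by locally weighted regression (tri-cube weights, span 0.7, 2 robustness
iterations; the smoother is statsmodels' lowess) and half the fitted trend
moves each sample toward the other. Plain quantile normalization (each
sample mapped onto the mean order-statistic distribution) and the chained
loess-then-quantile variant are selectable; the choice is recorded in
provenance. Default is cyclic loess on log₂ values: it is the named
algorithm of the two readings of "quantile cyclic loess", and log₂ is the
scale on which MS intensity bias is approximately additive.

## Statistics

The per-feature gate runs Shapiro–Wilk on each group; both p ≥ 0.05 routes
to the pooled-variance two-sided t-test, otherwise the two-sided
Mann–Whitney U (exact when both groups have n ≤ 8 and no ties, normal
approximation with tie correction otherwise; two identical constant groups
return p = 1 by convention, and zero-variance groups — for which
Shapiro–Wilk is undefined — take the rank route).

A calibration fact worth knowing: each branch test holds its nominal level
unconditionally (our simulations: t 0.0498, exact Mann–Whitney 0.0499 at
n = 8 vs 8), but *conditioning on a Shapiro–Wilk rejection selects samples
with extreme observations*, which inflates the Mann–Whitney branch to
≈ 0.067–0.071 and the overall gated procedure to ≈ 0.052–0.053 at α = 0.05.
This anti-conservatism is intrinsic to normality-gated testing, not an
implementation artifact; the unit suite asserts the unconditional levels,
and the acceptance suite documents the gated rate. Users wanting exact
calibration should fix the test rather than gate it.

PLS-DA is NIPALS PLS1 on autoscaled features with the class coded −1/+1,
two components by default (capped at the effective rank), deterministic
throughout. VIP_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = c_a² t_a't_a, giving Σ_j VIP²_j = p exactly; zero-variance
features get VIP 0 with a warning. The regulation call is the conjunction
p < 0.05 ∧ VIP > 1; no multiple-testing correction is applied to the call
(the conjunction with VIP plays that role in this design), but a
Benjamini–Hochberg column is emitted for transparency.

Class sums attribute each feature once, to its top-ranked isobar
annotation; MG/DG/TG pool as "TG"; the TG/PL ratio uses
PL = PC+PE+PG+PS+PA+PI. Factorial diet × sex ANOVA uses Type-II sums of
squares (statsmodels) so unbalanced cells are handled sensibly.
Maternal–fetal correlations average fetal values per dam before pairing to
avoid pseudo-replication of littermates. PCA is column-centred SVD with
the largest-|loading| sign convention.

## Acyl-carnitine quantification

The rule chain is RT window → blank rule → quantification, all closed-form:
a peak is accepted iff |RT drift| ≤ 0.1 min (a drift of exactly 0.1 min is
kept — only *greater* drift excludes — with a 1 ns-scale epsilon so binary
float representation of minutes cannot flip the boundary); areas below 3×
the blank are zeroed ("Not Found"); accepted area / IS area × 5 µM, divided
by tissue mg. Because the blank rule compares a ratio of areas, it commutes
with the scaling steps — property-tested. Internal standards map by chain
length (≤ C12 → butyryl-d7, ≥ C14 → hexadecanoyl-d3) since the published
protocol lists two standards without an explicit mapping; the mapping, the
blank aggregation (one mean blank area per target per batch) and the class
boundaries (small C2–C5, medium C6–C12, long ≥ C14) are configuration, not
constants. Class pools are made disjoint by precedence dicarboxylic >
hydroxylated > odd-chain > chain-length, so the pool totals partition the
panel total. The shipped target panel is an editable default whose RTs
follow reversed-phase elution order anchored at the two standards; real
deployments should replace it with their measured panel.

## Stereology

V = ΣP × a_p × d with a_p = 9000 µm² by default and d the distance between
analysed sections — an input, because the sampling interval is
specimen-specific. No shrinkage or overprojection correction is applied.
Volume is exactly linear in counts, grid area and spacing
(property-tested), and a grid-counting simulation over a cylinder of known
volume converges to truth as the grid densifies.

## The synthetic-data generator

The generator emulates the study design end to end: a 2 × 2 diet × sex
layout (default n = 7 per cell, matching the 6–12 range of such cohorts),
log-normal feature intensities (feature baselines spread 3 log₂-units,
within-group spread 0.5 log₂ ≈ 40% CV — typical biological variation for
tissue lipidomics), a shared per-sample loading factor (0.25 log₂),
±2 ppm mass jitter truncated at 3σ (well inside the 9 ppm tolerance),
detection-limit-driven missingness (probability decaying with intensity
rank, matrix-wide mean = the nominal 5% rate; an MCAR switch exists),
log-normal S/N, and a QC-pool dilution series (0.25/0.5/1.0× of the pooled
mean with 0.05 log₂ noise). Diet effects multiply OB-group means of flagged
features by 2^magnitude; an optional per-sex variant injects disjoint
affected sets of different sizes to emulate a sexually dimorphic response.
Simulated true features are chosen among isobar-group representatives
isolated by > 30 ppm from every other library ion, so the matcher can
always identify them — this makes the generator the measurable inverse of
the matching stage. All randomness flows through one seeded
`numpy.random.Generator`.

What the generator does *not* emulate: correlated lipid modules (features
are independent given the sample loading), adduct-intensity relationships,
isotope envelopes, chromatographic peak shapes, acquisition-order drift,
and batch structure. Passing tests therefore demonstrate the pipeline's
arithmetic, calibration and recovery behaviour — not robustness to every
artifact of real spectra.

One emergent and realistic consequence of per-mille closure is worth
flagging: when the features carrying an injected effect happen to hold a
large share of total signal, scaling to a constant sum attenuates their
apparent log-fold change (to ≈ 0.7–0.85 of the injected 1.0 in our default
design) and induces small opposite shifts in unaffected features, which
the robust loess normalization only partly undoes. Detection sensitivity
of the p < 0.05 ∧ VIP > 1 rule at 8 vs 8 and 2-fold effects consequently
averages ≈ 0.86 across generator seeds rather than the ≈ 0.95 a
non-compositional power calculation would suggest. Interpreting fold
changes from relative-abundance data requires the same caution in real
studies.

## Problem sizes used in the shipped checks

The statistical property checks run at the design sizes stated above:
500 replicates × 200 features for null calibration, one 8 vs 8 study with
20 two-fold features for sensitivity, 1000 seeded section sets for
stereology, and the built-in positive-mode library (~3.7 k ions) for
matching — sizes chosen so the full suite runs comfortably on a laptop
while keeping binomial standard errors small enough for the stated bands.
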