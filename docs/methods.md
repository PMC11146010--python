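# Methods

## Localization scores and enrichment calls

The unit of analysis is the gene-level RPKM table of fractionated cytoplasm:
TIS-granule (TG) particle sorting, rough-ER particle sorting, and
digitonin-extracted cytosol (CY), with biological replicates per
compartment.  Localization scores are computed from replicate-mean RPKM:
`LS_c = mean_c / Σ_c' mean_c'`.  We use the replicate-mean form (rather than
averaging per-replicate scores) as the default; both give identical results
for balanced replicates and the difference is second-order otherwise.  Genes
whose three compartment means sum to zero are dropped with a warning.

Expression gating keeps genes whose mean RPKM across the three compartment
means is ≥ 3 (configurable; a whole-cell-sample mode is also provided, since
either reading of "the RPKM value" is defensible).  The knockout analysis
gates on mean ER/CY RPKM > 3 in both conditions, matching its two-compartment
design.

Non-membrane calls: per compartment the threshold is `fold × median(LS_c)`
over the profile collection (default fold 1.25, roughly one SD of the score
distribution), comparison is `≥`.  One passing compartment gives its label;
two give the compartment with the higher score; zero — or all three, which
can occur with strongly skewed medians — give `unbiased`.  With two passing
compartments at exactly equal scores the tie resolves in the fixed column
order TG, ER, CY; exact ties are measure-zero for real data.  The medians
default to the supplied profiles but can be fixed externally (e.g. to the
published 0.32/0.30/0.34) for reproduction purposes.

Membrane/secretory calls use a precedence of rules: cytosolic score > 0.36 →
CY; ER/TG ratio > 1.25 → ER; ratio < 0.8 → TG; ratio "similar" (within
[0.8, 1.25]) with cytosolic score < 0.18 → ER; otherwise not localized.
A zero TG score makes the ratio +∞.  The source description of the
"similar" case assigns both the ER and the not-localized outcomes to a
cytosolic score below 0.18; the precedence implemented here (ER when the
score is low, not-localized when it is ≥ 0.18) is one consistent reading
and is stated as such, not asserted as the only one.

Membrane classification itself: a transmembrane domain ⇒ membrane; a signal
sequence without one ⇒ secretory; all else non-membrane.  Missing flags are
conservatively treated as absent.  Canonical transcripts are the longest
mRNA per gene (ties broken by smallest transcript id), except the 3′ UTR
length, which is the longest annotated isoform; protein length is CDS/3.

## CLIP target sets and the RBP short-list

Per-RBP targets use two rules.  *Median rule*: peak count strictly greater
than the RBP's median over the expressed non-membrane universe (for sparse
RBPs the median is 0, so any peak qualifies).  *Stringent rule*: among genes
with ≥ 1 peak, the top third by count, ties broken by (count desc, gene id
asc), taking ⌈n/3⌉.  TIA1 and TIAL1 peaks are experimentally
indistinguishable and are summed into a single TIA1/L1 column at load time.

Short-listing compares observed versus expected targets per compartment
class, with expected = |targets| × class fraction computed from the supplied
call table (never hard-coded); any class ratio > 1.5 short-lists the RBP.
Expected counts below 1 are flagged low-power.

Predominant-binding partitions over the seven code RBPs: LARP4B/METAP2-only
targets (stringent targets of either, bound by none of the other five);
TIS11B-predominant (stringent TIS11B targets bound by no other, or co-bound
only by TIA1/L1 with peak-count ratio ≥ 2; ratio is +∞ at zero TIA1/L1
count); TIA1/L1-predominant symmetrically with ratio < 2.  Disjointness is
asserted on every call.

## The combinatorial code

Covariates (seven RBP peak counts, optionally mRNA length and mean CDS exon
length) are sqrt-transformed then z-scored; missing raw values are zero
before the transform; zero-variance columns are dropped with a warning.  The
transform state (sqrt flag, centering mean, scaling SD per column) is stored
so held-out genes can be mapped onto the fitted scale exactly.

The model is a maximum-likelihood multinomial logit with `unbiased` as the
base class, fitted by Newton iterations with log-likelihood convergence
(|Δℓ| < 1e-8, ≤ 200 iterations) via `statsmodels.MNLogit`, falling back to
L-BFGS when the observed information is ill-conditioned.  Standard errors
are Wald (observed information); t-statistics use the normal approximation,
appropriate at these sample sizes.  No regularization and no train/test
split: coefficients are reported in-sample.  The "top seven covariates" step
is implemented as ranking by the maximum |t| across classes, a documented
choice where the original reduction criterion is unstated.  Propensities are
the per-class linear predictors (log-odds versus unbiased); softmax over
classes recovers probabilities summing to one.

## Knockout shifts

With the TG scaffold removed only ER and cytosol are scored:
`ls_er = ER/(ER+CY)`, so a shift toward the ER of +x is identically a shift
away from the cytosol of −x.  The per-gene shift is `ls_er(KO) −
ls_er(control)` over genes passing the two-compartment gate in both
conditions.  "Top 20%" sets are the ⌊0.2·N⌋ most positive / most negative
shifts over all gated genes (a TG+-only ranking universe is available via
flag), intersected with the TG+ set; boundary ties break by gene id.

## smFISH quantification

Compartment masks come from Otsu-thresholded marker max-projections
(threshold overridable; externally drawn masks accepted); where the TG and
ER masks overlap, the region is defined as TG and subtracted from the ER, so
the masks are mutually exclusive.  Foci are prominence-filtered local
maxima: the image is lightly Gaussian-smoothed (σ = 1 px, a matched filter
for diffraction-limited spots), h-maxima suppression at the prominence value
is applied via grayscale reconstruction, and each surviving maximum is
reported at the brightest pixel of its plateau.  The default prominence is
3 × a MAD-based noise SD of the raw image, raised per probe when nuclear
background is high.  A focus belongs to a compartment iff its integer pixel
coordinate lies in the mask (no dilation).

The colocalization test compares per-cell observed foci fractions with the
compartment-size expectation by a two-sided Mann-Whitney test — by default
against the per-cell area-fraction distribution, optionally against a fixed
expected value (bundled medians: TG 0.11, ER 0.29).  Because observed and
expected values come from the same cells, the two samples are positively
dependent and the test is conservative under the spatially uniform null;
this mirrors the design it reproduces.  The enrichment ratio is median
observed / median expected.  Digitonin retention is mean cytoplasmic foci
per treated cell over mean per untreated cell, with nuclear-mask foci
excluded.  Line-profile colocalization is plain Pearson r (constant
profiles are rejected).

## Decay scores

Pro-seq counts proxy transcription; RNA-seq counts proxy abundance; at
steady state their ratio tracks decay.  Both tables are normalized to
log2(1 + CPM) (pseudocount 1), the score is the Pro-seq value over the
RNA-seq value, and genes with zero normalized RNA-seq signal are dropped.
The score is invariant to library size by construction.

## Synthetic data

The generators provide the minimal statistical structure each downstream
rule assumes; their distributional forms (Dirichlet proportions, log-normal
abundances, negative-binomial peak counts, Gaussian spots) are modelling
choices, not measurements.

*Expression*: compartment proportions are symmetric Dirichlet(α = 20)
(cell-to-cell-like spread of ±0.06 around 1/3); enriched genes multiply
their compartment's proportion by `enrichment_strength` (default 3, giving a
planted share of ≈ 0.6) and renormalize.  The class composition defaults to
the study's observed fractions (TG+ 17.8%, ER+ 13.1%, CY+ 21.1%, unbiased
48.0%), materialized as exact rounded counts and permuted.  Replicate RPKM =
log-normal base abundance (median 30, σ = 1) × proportion × multiplicative
noise (CV default 0.2).  Architecture features are drawn at human-plausible
scales (CDS as a multiple of three, 3′ UTR log-normal around 800 nt) and are
independent of the label except where a stage plants coupling itself.

*CLIP*: counts are negative-binomial with log-mean = baseline + class effect
+ 0.5·log(3′ UTR length / 1 kb); the default effect matrix mirrors the
qualitative code (TIS11B→TG, TIA1/L1 and HuR→ER, LARP4B/METAP2→CY).
Dispersion → ∞ recovers Poisson.

*Code dataset*: covariates are generated as above, prepared with the exact
production transform, and labels are sampled from the softmax of a known
coefficient matrix whose intercepts reproduce the study composition — so
coefficient recovery is measured on the estimation scale.

*Knockout*: every gene's TG share is redistributed; non-planted genes split
it proportionally to their ER/CY shares (leaving the two-compartment score
unchanged in expectation), while planted TG+ genes send a `shift_magnitude`
fraction of it to one side, ER-ward with probability
sigmoid(coupling × standardized log mRNA length).

*FISH fields*: cell mask is an ellipse; TG/ER masks are smoothed-noise blobs
thresholded at the quantile that hits the requested area fractions to within
a pixel; foci compartments are multinomial at the requested colocalization
fractions (defaulting to the area fractions, the spatially uniform null) and
spots are Gaussians (amplitude 10 × noise SD) over Gaussian noise.  Spots
keep a minimum separation (6 px ≈ 4.5 PSF σ) so that each planted molecule
resolves to its own detected maximum; overlapping diffraction spots — a real
phenomenon at high transcript density — are deliberately not modelled, so
detection-side counting error is excluded from colocalization validation.
The record-level cell generator additionally varies compartment sizes across
cells (Beta around the requested fraction, concentration 60, i.e. SD ≈ 0.04
at a mean of 0.11), matching the broad cell-to-cell spread of real
compartment areas; without that spread a rank test of noisy observed
fractions against near-constant expectations is anti-conservative.

What passing synthetic tests does *not* show: robustness to alignment or
RPKM-estimation artifacts, to compartment cross-contamination in the
fractionation, to CLIP library-specific biases, or to segmentation error on
real micrographs — none of which the generators emulate.

## Problem sizes and numerical choices

Validation runs use 2,000-gene universes for classification/KO recovery,
5,000 genes × 50 seeded fits for code sign recovery, 1,000 label
permutations for short-list calibration, 200 simulated experiments × 20
cells for colocalization calibration, and 50 rendered 256×256 fields for
imaging recovery — sizes at which every recovery statistic is stable to the
tolerances tested while the whole suite stays light.  Scores and thresholds
compare with `≥`; simplex sums are checked at 1e-9; degenerate inputs
(constant features, all-identical profiles, empty masks, zero-expression
genes) warn or raise as documented on each function rather than propagating
NaNs.

## Known limitations

- The membrane-rule "similar" branch encodes one reading of an ambiguous
  description (see above).
- The 24→7 RBP reduction criterion is a documented stand-in (max |t|
  ranking).
- Compartment medians, and hence non-membrane calls, depend on the gene
  universe supplied; the default universe is the non-membrane expressed set.
- Foci detection reports integer pixel coordinates; sub-pixel localization
  and 3D spot fitting are out of scope.
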