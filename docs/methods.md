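# Methods

`transmeta` analyses pairs of GWAS summary-statistic tables for genetic
signals that two diseases share (or that push the two diseases in opposite
directions), fine-maps and colocalizes those signals, scores candidate
genes, and estimates causal effects between the traits by two-sample
Mendelian randomization.  Everything operates at the summary level: no
individual-level genotypes are required anywhere, including in the
simulator.

## Harmonization

Two tables are joined on marker id (or on chromosome:position with sorted
alleles).  Trait 2's effect is re-expressed on trait 1's effect allele:
a swapped allele pair negates the effect and complements the allele
frequency, and strand flips are resolved through base complements.
Strand-ambiguous (A/T, C/G) markers cannot be resolved from alleles alone;
the default policy rescues them when both traits' allele frequencies fall
outside [0.42, 0.58] — concordant minor alleles imply the same strand,
discordant ones imply opposite strands and force a flip — and drops them
otherwise.  The 0.42–0.58 exclusion zone is conventional; near 0.5 the
frequency comparison carries no strand information.  Duplicate marker ids
keep the smallest-p copy (deterministic and conservative).  Every dropped
marker is recorded with a reason (`palindromic`, `allele_mismatch`,
`duplicate`), and drop counts reconcile exactly with the difference between
the intersection and the output.

A validation pass rejects rows with nonpositive SE, p outside (0, 1], EAF
outside (0, 1), or a |beta/se| that disagrees with the |z| implied by the
two-sided p by more than 10% relative (published p-values are rounded, so
the tolerance is deliberately loose; p below 1e-250 is not checked because
the normal quantile is unreliable there).

## The cross-trait meta-analysis statistic

For harmonized effects (beta1, se1) and (beta2, se2), the combined statistic
is a fixed, equally weighted combination:

    shared:    beta = (beta1 + beta2) / 2
    opposing:  beta = (beta2 - beta1) / 2
    variance:  V    = (se1^2 + se2^2) / 4

with z = beta/sqrt(V) and a two-sided normal p.  Equal weights (rather than
inverse-variance weights) preserve the interpretation of the combined beta
as an average log-odds ratio, and make the opposing scan a simple sign
reflection of trait 1.  Trait 2 carries the positive sign in the opposing
mode; swapping the inputs negates the opposing statistic and leaves the
shared statistic unchanged.  When the two SEs are within a factor sqrt(3)
of each other the combined variance is strictly smaller than either
single-trait variance, which is the power gain from combining.

A region is reported as a locus only when three criteria hold at its lead
marker: combined p < 5e-8 (genome-wide), both single-trait p < 1e-4
(suggestive), and the combined p smaller than both single-trait p-values.
Lead selection is greedy by ascending combined p (ties broken by chromosome
then position), suppressing candidates within 500 kb of an accepted lead on
the same chromosome; the reported window is lead ± 250 kb, 1-based
inclusive (BED export converts to 0-based half-open).  The extended MHC
(chr6:25–34 Mb) can be excluded by flag, since its LD structure defeats
single-lead clumping.  Shared and opposing scans run independently and
overlapping windows between the two modes are not merged.

## Credible sets and colocalization

Fine-mapping assumes one causal variant per locus and a N(0, W) prior on
its effect.  Per-marker evidence is Wakefield's approximate Bayes factor,
ABF = sqrt(se²/(se²+W)) · exp(z²W/(2(se²+W))); with a flat prior over which
marker is causal, posterior inclusion probabilities are normalized ABFs and
the 95% credible set is the smallest descending-PIP prefix reaching 0.95.
W defaults to 0.04 (prior SD 0.2 on the log-odds scale), a common choice
for binary traits; it is configurable everywhere.  Credible sets for the
combined statistic use (beta, sqrt(V)) from the meta-analysis stage as the
input pair.  All ABF accumulation is done in log space; on small z the
log-space and direct-space computations agree to 1e-9.

Colocalization enumerates the five standard hypotheses (no association /
trait 1 only / trait 2 only / two distinct causal variants / one shared
causal variant) with per-marker priors p1 = p2 = 1e-4 and p12 = 1e-5.  The
H3 sum over ordered pairs of distinct markers is computed as the difference
between the full product term and the diagonal, in log space with a
`log1p(-exp(.))` correction.  Loci are the markers within ±100 kb of the
lead.  Only the single-causal-variant model is implemented; multi-signal
loci should be interpreted through the credible sets with that caveat.

## Gene prioritization

A gene becomes a candidate at a locus when a credible-set marker is a
significant eQTL or mQTL for it (p < 1e-6, strict) or carries a
protein-modifying annotation.  Evidence is a boolean gene × source matrix
in which each source belongs to exactly one category: `eqtl`, `mqtl` or
`other`.  The aggregate score counts the presence of *any* eQTL evidence
once and *any* mQTL evidence once — expression and methylation panels are
highly correlated, and counting each panel would bias the ranking toward
well-assayed genes — plus each distinct `other` source.  With the default
five non-QTL sources (protein-modifying variant; differential expression in
either disease; enriched mouse phenotype; drug target; nearest gene or
promoter-capture Hi-C contact) the score ranges from 1 to 7.  The
source-to-category partition is data (a table column), not code, so other
partitions can be configured.  Evidence ingestion is file-based: this
package does not query QTL or annotation services.

## Mendelian randomization

Instruments are markers with exposure p ≤ 1e-4, LD-clumped greedily by
ascending p with an r² ceiling of 0.001 inside 10 Mb windows (a missing LD
entry counts as r² = 0 with a warning; strict mode errors).  Estimators:

- **IVW** — weighted regression of outcome on exposure effects through the
  origin, weights 1/se_out²; the SE is inflated by sqrt(Q/(n−1)) when the
  heterogeneity ratio exceeds 1 (multiplicative random effects, never
  deflated).  One instrument degrades to the Wald ratio, flagged.
- **Egger** — the same regression with an intercept, after flipping rows to
  non-negative exposure effects; t-based p-values with n−2 df.  The
  intercept estimates directional pleiotropy.
- **Weighted median** — interpolated weighted median of Wald ratios with
  first-order inverse-variance weights; SE by seeded parametric bootstrap
  (default 1000 draws, seed recorded in the output).
- **Mode** — maximum of the weighted normal-kernel density of Wald ratios;
  bandwidth is the modified Silverman rule (0.9 · min(sd, scaled MAD) ·
  n^(−1/5)) times a configurable factor.  The density search is confined to
  the weighted 1–99% quantile range of the ratios so that a near-zero
  exposure effect in a bootstrap draw (whose wild ratio carries almost no
  weight) cannot stretch the grid; SE by seeded bootstrap.
- **Multivariable IVW** — weighted multiple regression without intercept of
  outcome effects on all exposures' effects over the pooled instrument set.
  Exposures with no instrument signal (an all-zero column) are dropped from
  the design and flagged, so the remaining fit reduces correctly (with one
  exposure left, exactly to univariable IVW); genuinely collinear designs
  (condition number > 1e8) are rejected.

**SMR** combines the top-QTL and GWAS z-scores at a marker into
T = z_gwas² z_qtl² / (z_gwas² + z_qtl²), referred to chi-square(1); the
mediated-effect estimate is b_xy = beta_gwas/beta_qtl.  **HEIDI** tests
whether the per-SNP b_xy estimates across the LD neighbourhood (r² to the
top SNP in [0.05, 0.9], at most 20 SNPs) are homogeneous: deviations from
the top-SNP estimate have a delta-method covariance assembled from the LD
matrix and both studies' SEs, and the sum of squared standardized
deviations is referred to a Satterthwaite-scaled chi-square.  The scaled
approximation is used rather than the original software's exact
distribution of a correlated quadratic form; simulations show near-nominal
rejection at the conventional 1.57e-3 threshold under a shared causal
variant and substantially elevated rejection under linkage.  Fewer than
three eligible neighbours yields a missing result with a reason, not an
error.

## The simulator

The generator emulates the statistical structure the pipeline consumes and
nothing more.  Markers lie on a chromosome in AR(1) LD blocks (default 50
markers per block, rho = 0.9, 500 bp spacing); per-marker SEs follow
se = 1/sqrt(2·N·maf(1−maf)) with effective sample sizes defaulting to
26,000 and 160,000 — the scale of an ~11k/16k case-control study paired
with a ~61k/124k one.  Z-scores are drawn from z ~ N(RΛ, R) per block,
where Λ carries the planted effects, so LD spreads both signal and noise.
Planted locus types are shared, opposing, trait1-only, trait2-only and
null, at positions at least 500 kb apart (enforced at config time).  The
default planted strength is |z| ≈ 6.5 per affected trait: the reported loci
of the motivating analysis have per-trait z between 3.9 and 8.1, and a
power calculation shows that recovery experiments need the upper end of
that range — at z = 4 the probability of passing the suggestive threshold
is only ~0.54, so a locus planted there is undetectable by design, not by
defect.  The locus-level generator additionally allows two causal variants
inside one window (for colocalization and HEIDI scenarios) and asymmetric
strengths; the credible-set shrinkage experiment plants z = 8 in one trait
and 4.5 in the other, the asymmetric regime the reported loci actually
display.

What the simulator does **not** reproduce: realistic human LD (block AR(1)
only), allele-frequency/effect-size coupling, imputation error, sample
overlap between the two GWAS, and population stratification.  Passing
recovery tests therefore demonstrates correctness of the statistics and
decision rules under the assumed model, not robustness to those real-data
complications.

MR scenarios draw true exposure effects from N(0, 0.05²) with exposure and
outcome measurement SEs of 0.01 and 0.025; winner's-curse selection is
reproduced by rejection sampling on the observed exposure p-value and can
be disabled.  With selection off, the residual regression-dilution
attenuation at these settings is σx²/(σx²+se_exp²) ≈ 0.96, small relative
to sampling noise at 448 instruments.  Pleiotropy is zero, balanced
(mean-zero) or directional (nonzero mean) per config.

## Numerical and reproducibility choices

All stochastic stages take explicit integer seeds, which appear in outputs
and in the run manifest; the same seed gives byte-identical output files.
Posterior vectors are renormalized after log-space accumulation.  Ties in
PIP are broken by input order (stable sort), ties in locus calling by
(chromosome, position).  Bootstrap SEs default to 1000 draws; simulation
tests use 100–200 draws to keep the suite fast.  Problem sizes in the test
and acceptance experiments (6,000-marker chromosomes, 150-marker loci,
20–50 replicates, 250 null replicates for calibration) were chosen so the
binomial/Monte-Carlo error of each checked rate is well inside the margin
being asserted.

## Known limitations

Single-causal-variant fine-mapping and colocalization only; no LD-aware
joint models or conditional analysis.  No liftover or imputation-quality
filtering (inputs are assumed well-imputed and on a common build).  The MR
suite does not implement random-effects profile-likelihood estimators
(e.g. RAPS-style weighting); multivariable IVW is the adjustment tool, and
no sample-overlap correction is applied.  HEIDI's p-value is a scaled
chi-square approximation, adequate at conventional thresholds but not in
the extreme tail.
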