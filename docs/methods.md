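# Methods

`canopygrowth` reconstructs the aboveground woody biomass growth of
individual tropical canopy trees from destructive field measurements and
asks which stem and crown traits explain the variation in that growth among
trees.  The design follows a four-species, 43-tree destructive study of
emergent canopy trees in a Bolivian moist forest (15 *Hura crepitans*, 11
*Schizolobium parahyba*, 9 *Cariniana ianeirensis*, 8 *Sweetia fruticosa*),
whose raw data were never publicly deposited.  A calibrated synthetic
generator therefore stands in for the field data; everything else in the
package operates on measurement tables that real field data could populate
identically.

## Trait derivation

**Disc geometry.** Each tree contributes two stem discs, one at ~1 m and
one just below the first major branch.  Discs are never circular, so three
radii (longest, shortest, one intermediate) are measured inside bark; a disc
is modelled as a circle on the arithmetic mean radius r̄.  This convention
(rather than averaging per-radius areas) keeps the sapwood/heartwood/pith
partition an exact identity: with pith radius q and mean heartwood and
sapwood radial lengths h̄, s̄,

    pith = πq²,  heartwood = π[(q+h̄)² − q²],  sapwood = π[(q+h̄+s̄)² − (q+h̄)²],

and the three areas sum to the disc basal area exactly.  The alternative
mean-of-areas convention is available via `convention="mean_area"` for
sensitivity analysis.

**Growth.** Ring widths of the last five years on the three radii are
averaged to one width w̄ (five years damps climatic year-to-year
variability), and annual basal-area growth is the outermost annulus
ΔBA = πr̄² − π(r̄−w̄)².  Wood density (dry mass / fresh volume) of the
youngest sapwood sample converts this to a biomass growth rate per metre of
stem, rate = WD·ΔBA·0.1 (kg m⁻¹ yr⁻¹).  Taper is assumed confined to the
stem below the first branch, so

    AGR = mean(rate_lower, rate_upper)·H_stem + rate_upper·(H_total − H_stem),

with leaf mass deliberately excluded (it covaries with total leaf area, one
of the predictors).

**Total leaf area.** Per branch, leaf area = shoot count × mean leaves per
shoot × tree-level mean leaf area (from the pooled 20–25-leaf sample); the
branch basal-area : leaf-area ratio is averaged over the 4–5 branches, and
TLA = (stem BA just below the first branch) / ratio, assuming the ratio is
conserved between that point and the branches.

**Other traits.** SLA = pooled leaf area / pooled dry mass.  Sapwood
lifespan = sapwood width / 15-year mean ring width.  Tree-level sapwood
area, lifespan and sapwood growth average the two discs (a `lower | upper |
mean` switch exists because the original protocol is explicit only for SA);
stem basal area is the lower disc, the basal sample.  Trees of a species
without a visible sapwood–heartwood colour boundary carry explicit nulls
for SA and lifespan, never zeros.

## Statistical analysis

Growth, SA and stem BA are log-transformed, TLA square-root-transformed;
all numeric columns are centred and SD-scaled so coefficients are
standardized; species enters as a reference-coded fixed factor (reference
*Sweetia*).  Species × trait interactions are screened by partial F-tests
(α = 0.05) and enter later stages only if significant.  Cook's distance is
reported per observation with a 4/n flag threshold, flag-only — no
automatic removals.

The growth model is reduced by all-subsets regression: every admissible
subset of the predictor terms (species as one block; interactions only with
their main effects) is fitted by OLS.  AIC = 2k − 2 log L with the Gaussian
ML likelihood and the residual variance counted in k — the convention of
R's `AIC()` on `lm` objects, so subset ranking matches what `dredge`-style
tools produce.  AICc is available by flag; with n = 43 and up to ~12
parameters it materially changes selection, so the default (plain AIC, as
in the source analysis) is explicit.  Models within 2 AIC units of the best
are averaged with renormalized Akaike weights.  Coefficients are
**conditional** (subset) averages — each averaged only over the models that
contain it — with the Burnham–Anderson adjusted standard error
Σwᵢ√(SEᵢ² + (βᵢ−β̄)²); full (zero-substitution) averages are emitted
alongside.  Relative importance of a term is the summed weight of the
selected models containing it, so a term present in every selected model
has importance exactly 1.  Averaged-coefficient p-values use a normal
approximation; component-model p-values are t-based.

The sapwood-area determinants model is a single full fit (no averaging):
scaled log SA ~ scaled {sapwood growth, sapwood lifespan, log BA} +
species, on trees with *observed* SA only.  Sapwood growth and lifespan are
left untransformed (an assumption; SA and BA are modelled on log scale).

For the species without a sapwood boundary, SA is imputed from a regression
of log SA on all measurable traits — height, √TLA, SLA, leaf N, sapwood N,
sapwood growth, log BA — over the other species.  Sapwood growth is
included because annual ring growth needs no sapwood boundary; sapwood
lifespan is excluded because it does.  A species factor over the observed
species keeps the trait slopes free of intercept confounding; the masked
species receives the training-share-weighted average intercept.  The
imputed level therefore inherits a modest bias (the masked species' true
intercept is unknowable), which is why the downstream robustness check
compares sign and significance, not values, between analyses with and
without the imputed species.

The path analysis regresses growth on height, SA and TLA (transformed as in
the growth model) after subtracting species means from every variable, with
pairwise Pearson correlations among the predictors.  The model is
saturated, so no global fit statistic exists; its purpose is to rank the
direct effects while accounting for predictor correlations.

## The synthetic study population

The generator emulates the study conditions, not just convenient test
data.  Its defaults are the study's published summary quantities:

- species counts 15/11/9/8 (4 species, 43 trees), with the *Cariniana*
  analogue flagged sapwood-unobservable and masked on output (its SA is
  retained as hidden truth so imputation can be scored);
- marginal trait distributions calibrated to the published means, SDs and
  min–max envelopes (normal on the transformed scale, species mean offsets,
  a shared within-species correlation matrix with |r| ≤ 0.6 among size
  variables and a negative sapwood-growth–lifespan correlation);
- structural ground truth equal to the published standardized effects:
  growth ~ 0.73·z(log SA) + 0.17·z(√TLA) − 0.16·z(SLA) + 0.13·z(N_sapw)
  − 0.12·z(N_leaf) + 0.11·z(height) + species intercepts (0, −0.28, 0.56,
  0.07 on the z scale), and log SA ~ 0.45·z(sapwood growth) +
  0.18·z(lifespan) + 0.22·z(log BA) + species intercepts (−0.77, 1.42,
  0.50; the hidden *Cariniana* value, 0.8, is a generator choice near the
  ecologically similar low-density pioneer).

Three numerical choices matter for anyone re-deriving results:

1. **Envelope truncation vs. standardization.**  Hard truncation at the
   observed min–max would shrink every SD by 10–25% and hence bias
   standardized-coefficient recovery multiplicatively.  Draws therefore use
   a pre-truncation inflation and shift per trait, calibrated once so the
   post-truncation reference z-scores are ~N(0, 1); residual SDs (growth
   0.68, SA 0.30 on the z scale) are calibrated so the response z-variances
   are 1.  The standardized ground-truth coefficients are defined against
   the generator population's own moments — which is exactly what a
   standardized coefficient printed from a fitted model means.
2. **Symmetric residual truncation.**  Responses must respect the envelope
   and the physical bound SA ≤ 0.95·BA.  One-sided rejection would
   correlate residuals with predictors and bias recovery; instead residuals
   are truncated *symmetrically* around the structural mean (margin
   b = min(upper slack, lower slack)), which keeps E[ε|X] = 0
   (heteroscedastic, but OLS remains unbiased).  Trees whose structural SA
   mean sits against the feasibility wall are redrawn entirely — selection
   on predictors only, which OLS tolerates.
3. **Inversion to raw measurements.**  `invert_to_field_measurements`
   solves the derivation chain backwards: radii from BA, ring widths from
   the growth annulus, concentric sapwood lengths from SA and the lifespan
   identity, branch censuses from the BA:LA ratio, and heights plus per-tree
   wood density from the AGR identity AGR = 0.1·W·G·[H_s + s_u(H_t−H_s)].
   Wood density is drawn near the species mean and flexed within
   (0.12, 1.45) g cm⁻³ only when the drawn AGR/sapwood-growth combination
   demands it; combinations outside the physical envelope raise an error
   naming the constraint.  The inversion is exact to floating-point
   rounding, which is what the 1e-6 round-trip tests check.

**What the generator does not emulate.**  Measurement noise is off by
default (a config percentage enables it); real ring series have
crossdating error, missing rings and within-disc ring-width trends; the
natural-scale SDs of the log-normal-mixture responses (AGR, SA) come out
~15% below the printed SDs, because a truncated four-species mixture with
unit z-variance has lighter natural-scale tails than a single log-normal
(the printed SDs, from n = 43, themselves carry ~11% sampling error); and
the inversion's wood densities compress toward ~0.5 g cm⁻³ across species
rather than spanning the published 0.36–0.82 species means — making the
densest species' mean typical would require sapwood growth centred at the
envelope minimum, which is incompatible with the prescribed SA-model
variance structure, and coefficient recovery was prioritised.  Passing
tests therefore certify the derivation algebra and the estimator, not
field-data robustness.

## Problem sizes and seeds

Recovery harnesses use 50 replicate populations of n = 430 (species counts
× 10): large enough that the Monte-Carlo SE of a mean recovered coefficient
is ~0.005, small enough to run in seconds.  The round-trip check inverts
~1000 trees.  Every stochastic entry point takes an explicit seed;
replicate sub-seeds come from `numpy.random.SeedSequence.spawn`, so results
are reproducible and replicates independent.  Recovery harnesses disable SA
masking: they score the estimator against the generator truth, while
imputation quality is scored separately (imputed vs hidden values,
correlation ≈ 0.84 at n = 43).

## Known limitations

- The TLA:SA hydraulic-conductance ratio analysis is a derived column plus
  an ordinary species-factor fit, not a dedicated routine.
- The saturated path model covers exactly the published variable set
  (growth, height, SA, TLA); it is not a general SEM.
- With one species contributing a single tree, species-mean centering zeros
  its contribution (a warning is emitted).
- Imputed SA values carry a species-level offset (see above); analyses that
  depend on the imputed species' absolute SA level should prefer the
  drop-missing variant (`--drop-missing-sa`).
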