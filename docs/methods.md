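# Methods

`eeldiet` implements a data-driven optimization loop for larval diet
formulation: a mixture of nine ingredients is iteratively refined across
rearing trials to maximize both survival and growth of fish larvae, with
Gaussian-process surrogates proposing the next formulations to test.  This
note records the models, the numerical choices, and what the synthetic
validation does and does not show.

## The formulation space

A diet assigns a mass percent to each of nine ingredients (egg yolk powder,
skimmed milk powder, yeast extract, soy peptide, casein Na, CPSP fish
protein hydrolysate, fish oil, vitamin mix, taurine), summing to 100.  The
two additives are held essentially constant at ~2.2% each; the remaining
seven are the optimization variables.  All modelling uses normalized simplex
coordinates: the seven free mass percents divided by their sum, a
non-negative vector `x` with `Σx = 1`.

Numerical choices:

- A printed formulation row is accepted if its ingredient sum is within
  0.45 of 100 — the exact worst case of nine entries each rounded to 0.1%.
- Converting simplex coordinates back to mass percents rounds to 0.1% with
  a largest-remainder correction, so emitted formulations always total
  exactly 100.0.  The round trip simplex → mass → simplex is then exact to
  2×10⁻³ per coordinate.
- Ingredient bounds default to the per-ingredient min/max observed across
  the packaged formulation table — the only in-data evidence of the
  feasible region.  A YAML bounds file overrides them.

## Outcomes and standardization

Tanks stock ~250 larvae at 6 days post-hatch (dph); survivors and mean
total length (TL, mm) are recorded at 20/40/60/80 (and optionally 100) dph.
Outcomes are summarized over an early (6–40 dph) and a late (41–80 dph)
modelling period, plus a reporting-only overall period (6–80 dph):

- early survival = survivors at 40 dph / stocked;
- late survival = interval survival 41→80 dph, using the count stocked at
  41 dph as denominator (the restocked count when densities were equalized,
  otherwise the 40-dph survivors);
- cumulative survival after restocking chains the two:
  `S(80) = S(40) × survivors(80)/stocked(41)`;
- period TL is the TL at the period's final sampling point.  A missing
  terminal point flags the outcome as missing; nothing is imputed.

Each trial includes two reference diets (FSD, FSY).  Within every
(trial, period, trait), diet values are standardized as

    z = (x − mean(refs)) / SD(refs),

with the sample SD over the two reference values, |x₁ − x₂|/√2.  This
removes additive trial/batch effects exactly.  An alternative reading —
dividing by the SD of *all* diets in the trial — is exposed as
`sd_mode="trial"`; the reference-SD reading is the default because it is
the one stated unambiguously for the driver analysis.  With count-valued
survival data the two reference values can tie exactly, making z undefined;
the low-level operation raises, while the pipeline wrapper can degrade that
(trial, period, trait) to missing (`on_zero_sd="nan"`, the pipeline
default).

## Gaussian-process surrogates

One GP regression per trait and period, on the simplex coordinates.  Both
X and y are auto-scaled (zero mean, unit variance) with training-set
statistics; zero-variance explanatory columns are dropped and recorded in a
mask.  The kernel is selected from the eight-candidate closure
{squared exponential, Matérn ν = 3/2} × {isotropic, per-dimension
lengthscales} × {± additive dot-product term}, each plus a white-noise
term, by 10-fold cross-validation maximizing predictive R² on pooled
out-of-fold predictions.  Ties go to the lower-complexity candidate (fewer
terms, isotropic before per-dimension).  Folds are shuffled with a recorded
seed; hyperparameters maximize the marginal likelihood from 5 optimizer
restarts (a reproducibility/robustness trade-off; restarts and seed are
recorded in the model metadata).  Every CV report carries R², RMSE and MAE
for train and CV; RMSE ≥ MAE is asserted on each — it is a power-mean
inequality that any single-dataset report must satisfy (a published report
that violates it indicates transposed columns or mixed splits, and is not
reproduced here).

Two limits of kernel selection at these sample sizes, measured with the
package's own simulation oracles: an RBF kernel with a long lengthscale
mimics a linear kernel, so a planted linear truth selects a
dot-product-bearing candidate in only ~85–90% of replicates; and family
discrimination is asymmetric — a rough Matérn truth is recovered in a clear
majority of replicates, but a smooth RBF truth is not, because the Matérn
family fits smooth functions equally well.  The property tests assert the
majorities the oracle supports, not perfect discrimination.

## Acquisition

For each candidate `x` the surrogate gives a predictive mean μ and SD σ on
the z scale.  The probability of improvement over the incumbent is

    PI = Φ((μ − (f_best + ξ)) / σ),

with Φ the standard normal CDF, `f_best` the best observed z for that
trait/period (configurable alternative: 0, the reference-diet mean), and ξ
a relaxation parameter on the z scale — 10⁻³ favours exploration, 10⁻⁶
exploitation.  σ = 0 degenerates to the indicator μ > f_best + ξ.  The two
traits combine as the equally weighted sum of log PIs; weights are
configurable.

Candidates are generated by scoring a seeded uniform pool on the bounded
simplex (Dirichlet(1,…,1) draws with rejection against the bounds; a
hit-and-run walk takes over below 1% rejection yield), collapsing
near-duplicates closer than L1 0.01 (keeping the higher score), and
returning the top 100 in descending score.  The batch's coordinate-wise
mean, renormalized, is the representative average formulation.

## D-optimal initial design

The initial screen maximizes det(XᵀX) of a Scheffé mixture-model matrix
(degree 1 by default: the proportions, no intercept — 18 runs over 7
components leave few degrees of freedom for degree 2) by greedy Fedorov
exchange over a seeded candidate pool that mixes uniform draws with the
feasible extreme points.  The determinant is non-decreasing across
exchanges and the search stops at a local optimum; exact parity with
commercial design software is not attempted.

## Proximate composition and driver analysis

Diet-level proximate composition is a dry-mass-weighted linear mixture of
per-ingredient values (components on a dry-matter basis, moisture as
analyzed).  Yeast-extract protein corrects total Kjeldahl nitrogen for
nucleic-acid nitrogen (RNA × 0.146) before the ×6.25 conversion; crude
carbohydrate is the nitrogen-free-extract closure
NFE = 100 − (moisture + protein + lipid + ash + nucleic acids), flagged
(never clamped) when negative.  The packaged ingredient-profile table is a
synthetic, literature-plausible stand-in — the actual analytical values of
the real feed ingredients are not distributed with this package, so
composition arithmetic is validated against hand-computed mixtures, not
against published diet compositions.

Driver analysis regresses the standardized outcomes on the five
composition features (crude protein, lipid, ash, carbohydrate, nucleic
acids; % DM) with a random forest.  Hyperparameters come from a grid
(trees ∈ {200, 500}, depth ∈ {3, 5, ∞}, min leaf ∈ {1, 3, 5}) searched by
5-fold CV R²; the out-of-bag R² is logged alongside and can be made the
selection criterion, since the two are easily conflated in practice.
Importances are normalized impurity decreases (mean |Shapley| is also
reported).  Shapley attributions are exact: with only five features, all
2⁵ coalitions are enumerated, valuing a coalition by the path-dependent
tree-conditional expectation (unknown features average children by training
coverage).  Efficiency then guarantees per-row local accuracy — base value
plus attributions equals the prediction — to float precision.  Dependence
is summarized as 10-bin means of per-sample attributions with percentile
bootstrap CIs (200 resamples), a plain replacement for loess smoothing.

## Synthetic ground truth and what it shows

The simulator plants, per trait and period, a latent surface
baseline + linear trend + isotropic Gaussian bump on the simplex, with
*different* bump centres in the early and late periods — the framework's
central premise that the optimal formulation shifts with developmental
stage.  Observation noise is Gaussian; per-trial batch effects are additive
Gaussian shifts shared by all tanks of a trial; survivor counts are
binomial given the (clamped) latent survival, chained through the sampling
points so counts are integer and monotone within a stocking segment.

Defaults (chosen once as plausible for larval rearing at this scale):
survival baseline 35%/45% (early/late) with a 30-point bump of width 0.12;
TL baseline 19/29 mm with 3/4 mm bumps; observation SD 4% and 0.5 mm;
batch SD 6% and 0.8 mm; reference diets sit mid-range so optimized diets
land around z ≈ +1 to +2.

The simulator reproduces the statistical structure the pipeline assumes —
simplex geometry, two periods, two noisy objectives, batch effects,
references in every trial — but none of the biology: no mortality
dynamics within a period, no density dependence, no diet-switch carryover,
and independent period surfaces.  Passing tests therefore demonstrate that
the machinery recovers planted structure under its own assumptions, not
that those assumptions hold in a rearing hall.

## Benchmark against random search

`run_benchmark` compares the full BO loop (initial uniform screen, then
two 9-candidate rounds — the scale of the real screening campaigns)
against uniform-random selection at an identical budget, scoring each
strategy by the true latent value of the best formulation it tested.  BO
batches are diversified with a minimum pairwise L1 separation of 0.25:
when the surrogate is still flat, an undiversified batch collapses onto a
single pool point and wastes the round.  The benchmark's default truth is
a strong, wide optimum (bump width 0.20, effect size 1.5): a narrower bump
than a 28-formulation budget can resolve leaves both strategies at noise
level and the comparison uninformative, which the flat-surface null (win
rate exactly 0.5, ties counted as half-wins) makes explicit.  Problem
sizes throughout the test-suite simulations (pool sizes of a few thousand,
single-kernel fits in the benchmark loop) are chosen so the whole suite
exercises every code path at small scale.

## Known limitations

- Kernel-family identification is unreliable at n ≲ 50 in seven
  dimensions (see above); the CV selection optimizes prediction, not
  identification.
- The expert shortlisting step between candidate generation and the next
  trial is a human action; the package emits the 100-candidate batch and
  records a user-supplied selection, it does not model the judgment.
- The D-optimal module optimizes over a finite candidate pool; continuous
  coordinate-exchange refinements could improve the determinant further.
- Exact Shapley enumeration scales as 2^d and is capped at 15 features;
  the driver analysis uses 5.
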