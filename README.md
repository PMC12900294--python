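# eeldiet

Data-driven diet formulation for fish larvae: Bayesian optimization of a
nine-ingredient mixture to jointly improve larval survival and growth,
with Gaussian-process surrogates, a multi-objective
probability-of-improvement acquisition, D-optimal initial designs, and a
random-forest + Shapley analysis of the nutrient drivers.

Developing a working larval diet — the bottleneck of artificial seedling
production for species like the Japanese eel — has traditionally meant
heuristic trial and error over a high-dimensional formulation space, under
severe constraints on tank capacity and trial duration.  `eeldiet`
packages the alternative: treat the formulation as a point on a bounded
simplex, model the outcomes probabilistically, and let an acquisition
function decide which formulations the next rearing trial should test.

## The model

A diet is a mass-percent vector over nine ingredients; seven are free
variables, normalized to proportions `x` with `Σx = 1`.  Survival and mean
total length (TL) are summarized over an early (6–40 dph) and late
(41–80 dph) period and standardized within each trial against two
reference diets present in every trial:

    z = (x − mean(refs)) / SD(refs)

which removes batch effects between rearing rounds.  For each trait and
period a Gaussian-process regression `z ~ GP(x)` is fitted on auto-scaled
data, its kernel selected from {RBF, Matérn ν=3/2} × {isotropic, ARD} ×
{± linear term} (all with white noise) by 10-fold cross-validation.
Candidates are scored by probability of improvement per trait,

    PI = Φ((μ − (f_best + ξ)) / σ),

and ranked by the equally weighted multi-objective acquisition
`log PI_survival + log PI_TL`; ξ ∈ [10⁻⁶, 10⁻³] trades exploitation
against exploration.  Each round emits 100 candidates per period plus
their representative average formulation.  A D-optimal (Fedorov exchange,
Scheffé degree-1) design seeds the first trials; after the campaign, a
random-forest regression of the standardized outcomes on estimated
proximate composition (crude protein/lipid/ash/carbohydrate, nucleic
acids) with exact Shapley attributions identifies which nutrients drove
the gains.  A synthetic larval-response simulator with planted,
stage-specific optima stands in for the rearing trials, so the whole loop
is testable end to end.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a four-trial screening campaign on a synthetic truth, fit the
four surrogates, and generate the next round's candidates:

```python
import numpy as np
import eeldiet as e
from eeldiet.acquisition import AcquisitionConfig, sample_bounded_simplex
from eeldiet.formulations import SimplexPoint, from_simplex
from eeldiet.pipeline import RoundConfig, run_bo_round
from eeldiet.synthetic import CampaignProtocol, TrialPlan

bounds = e.default_bounds()
truth = e.make_ground_truth(seed=7, bounds=bounds, bump_width=0.2)

rng = np.random.default_rng(7)
points = sample_bounded_simplex(bounds, 36, rng)
diets = {f"S{i+1}": SimplexPoint(p / p.sum(), bounds=bounds)
         for i, p in enumerate(points)}
ids = list(diets)
protocol = CampaignProtocol(trials=tuple(
    TrialPlan(f"T{t+1}", tuple(ids[9*t:9*t+9]) + ("FSD", "FSY"))
    for t in range(4)
))
records = e.simulate_campaign(truth, protocol, diets, seed=7)

cfg = RoundConfig(acquisition=AcquisitionConfig(pool_size=20_000, seed=7),
                  bounds=bounds, seed=7)
result = run_bo_round(records, diets, cfg)
print(result.cv_summary().to_string(index=False))
print(from_simplex(result.periods["6-40"].representative,
                   diet_id="next-round").as_series().to_string())
```

prints

```
period    trait                              kernel     cv_r2   cv_rmse   cv_mae
  6-40 survival Matern(nu=1.5) + White + DotProduct -0.124748  7.293306 3.991929
  6-40       tl       RBF[ard] + White + DotProduct  0.205634 12.342574 7.747334
 41-80 survival Matern(nu=1.5) + White + DotProduct -0.040033  3.323398 2.014698
 41-80       tl              Matern(nu=1.5) + White  0.332448 12.096036 8.391348
egg_yolk_powder        10.6
skimmed_milk_powder     5.1
yeast_extract          15.1
soy_peptide             5.4
casein_na              44.7
cpsp                   12.2
fish_oil                2.5
vitamin_mix             2.2
taurine                 2.2
```

Each row of the summary is one surrogate: its CV-selected kernel and the
predictive R²/RMSE/MAE of the pooled out-of-fold predictions (on the
z-score scale — RMSE units are reference-SDs, so magnitudes vary with how
close the two reference diets happened to land in each trial).  Predictive
skill at 36 diets is modest and period/trait-dependent, which is exactly
the regime the acquisition is built for: it weighs the surrogate's
uncertainty, not just its mean.  The second block is the representative
average formulation of the early period's 100-candidate batch, scaled back
to mass percents (totalling exactly 100.0); against this seed's planted
early optimum of ~42% casein Na with moderate egg yolk and CPSP, the batch
average has already shifted to 44.7% casein Na after a single round.

The same loop is available from the shell:

```sh
eeldiet design --n-runs 18 --seed 1 --out design.csv
eeldiet simulate --seed 1 --out-dir run/
eeldiet standardize --records run/tank_records.csv --out run/z.csv
eeldiet acquire --records run/tank_records.csv --formulations run/formulations.csv \
        --period 6-40 --xi 1e-3 --seed 1 --out-dir run/
eeldiet benchmark --n-seeds 20
```

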