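"""Synthetic larval-response simulator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes, so every
stage is testable end-to-end without rearing data: a seven-ingredient
bounded simplex, two developmental periods (6–40 and 41–80 dph) with
*different* latent optima, two noisy objectives (survival %, total length
mm), additive per-trial batch effects, and the two reference diets (FSD,
FSY) present in every trial.

Each latent surface is baseline + linear trend + an isotropic Gaussian bump
centred on a known optimum.  Survivor counts are binomial draws from the
(clamped) latent survival, giving integer, monotone tank counts; TL is
Gaussian around the latent growth endpoint.  Everything is deterministic
given the seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .formulations import (
    FREE_INGREDIENTS,
    DietFormulation,
    IngredientBounds,
    SimplexPoint,
    load_formulations,
    to_simplex,
)
from .trials import PERIOD_EARLY, PERIOD_LATE, TankRecord

TRAITS = ("survival", "tl")
MODEL_PERIODS = (PERIOD_EARLY, PERIOD_LATE)

#: Default planted optima (normalized proportions of the seven free
#: ingredients); distinct by period — the framework's central premise.
DEFAULT_OPTIMA = {
    PERIOD_EARLY: np.array([0.195, 0.073, 0.082, 0.032, 0.418, 0.166, 0.034]),
    PERIOD_LATE: np.array([0.231, 0.211, 0.141, 0.002, 0.349, 0.051, 0.015]),
}

#: (baseline, bump height, bump width) per trait and period, in trait units
#: (% for survival, mm for TL at the period's growth endpoint).
DEFAULT_SURFACE = {
    ("survival", PERIOD_EARLY): (35.0, 30.0, 0.12),
    ("survival", PERIOD_LATE): (45.0, 30.0, 0.12),
    ("tl", PERIOD_EARLY): (19.0, 3.0, 0.12),
    ("tl", PERIOD_LATE): (29.0, 4.0, 0.12),
}

DEFAULT_NOISE_SD = {"survival": 4.0, "tl": 0.5}
DEFAULT_BATCH_SD = {"survival": 6.0, "tl": 0.8}


class SyntheticError(ValueError):
    pass


def _stable_int(*parts) -> int:
    data = "|".join(str(p) for p in parts).encode()
    return zlib.crc32(data)


@dataclass(frozen=True)
class LatentSurface:
    """baseline + trend·p + height · exp(−‖p − optimum‖² / 2w²)."""

    baseline: float
    trend: np.ndarray
    optimum: np.ndarray
    height: float
    width: float

    def __call__(self, points) -> np.ndarray:
        P = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((P - self.optimum) ** 2).sum(axis=1)
        vals = (
            self.baseline
            + P @ self.trend
            + self.height * np.exp(-d2 / (2.0 * self.width**2))
        )
        return vals


@dataclass(frozen=True)
class GroundTruth:
    """Seed-deterministic latent response surfaces plus the noise model."""

    seed: int
    surfaces: dict[tuple[str, str], LatentSurface]  # keyed (trait, period)
    noise_sd: dict[str, float]
    batch_sd: dict[str, float]
    references: dict[str, SimplexPoint]
    bounds: IngredientBounds | None = field(default=None)

    def latent(self, trait: str, period: str, points) -> np.ndarray:
        vals = self.surfaces[(trait, period)](points)
        if trait == "survival":
            vals = np.clip(vals, 0.0, 100.0)
        return vals

    def batch_effect(self, trial_id: str, trait: str, period: str) -> float:
        rng = np.random.default_rng(
            [self.seed, _stable_int(trial_id), _stable_int(trait, period)]
        )
        return float(rng.normal(0.0, self.batch_sd[trait]))

    def optimum(self, period: str) -> np.ndarray:
        return self.surfaces[("survival", period)].optimum


def make_ground_truth(
    seed: int = 0,
    optima: dict[str, np.ndarray] | None = None,
    effect_size: float = 1.0,
    noise_sd: dict[str, float] | None = None,
    batch_sd: dict[str, float] | None = None,
    bounds: IngredientBounds | None = None,
    trend_scale: float = 2.0,
    bump_width: float | None = None,
) -> GroundTruth:
    """Build a synthetic truth object.

    ``effect_size`` scales the bump heights and the linear trend (0 gives a
    flat surface); ``optima`` overrides the planted optimum per period and
    must lie within ``bounds`` when bounds are given; ``bump_width``
    overrides the default bump width (0.12) — wider bumps are resolvable at
    smaller experimental budgets.
    """
    optima = {**DEFAULT_OPTIMA, **(optima or {})}
    for period, opt in optima.items():
        opt = np.asarray(opt, dtype=float)
        if abs(opt.sum() - 1.0) > 1e-6 or (opt < 0).any():
            raise SyntheticError(f"optimum for {period} is not on the simplex")
        if bounds is not None:
            lo, hi = bounds.normalized()
            if (opt < lo - 1e-9).any() or (opt > hi + 1e-9).any():
                raise SyntheticError(f"optimum for {period} lies outside bounds")
        optima[period] = opt
    noise_sd = {**DEFAULT_NOISE_SD, **(noise_sd or {})}
    batch_sd = {**DEFAULT_BATCH_SD, **(batch_sd or {})}
    rng = np.random.default_rng(seed)
    surfaces = {}
    for trait in TRAITS:
        for period in MODEL_PERIODS:
            base, height, width = DEFAULT_SURFACE[(trait, period)]
            if bump_width is not None:
                width = bump_width
            trend = rng.uniform(-1.0, 1.0, size=len(FREE_INGREDIENTS))
            scale = trend_scale if trait == "survival" else trend_scale / 5.0
            surfaces[(trait, period)] = LatentSurface(
                baseline=base,
                trend=trend * scale * effect_size,
                optimum=optima[period],
                height=height * effect_size,
                width=width,
            )
    refs = {
        f.diet_id: to_simplex(f)
        for f in load_formulations()
        if f.diet_id in ("FSD", "FSY")
    }
    return GroundTruth(
        seed=seed, surfaces=surfaces, noise_sd=noise_sd,
        batch_sd=batch_sd, references=refs, bounds=bounds,
    )


def _as_point(formulation) -> SimplexPoint:
    if isinstance(formulation, SimplexPoint):
        return formulation
    if isinstance(formulation, DietFormulation):
        return to_simplex(formulation)
    raise SyntheticError(f"cannot interpret formulation {formulation!r}")


def simulate_tank(
    truth: GroundTruth,
    formulation,
    trial: str,
    period: str,
    seed: int,
    stocked: int = 250,
) -> tuple[int, float]:
    """One tank's endpoint for one period: (survivor count, mean TL mm).

    Survival percent is latent + batch + noise clamped to [0, 100], then
    converted to an integer count by a binomial draw over the stocked
    number; TL is latent + batch + noise floored at 0.1 mm.
    """
    p = _as_point(formulation).proportions
    rng = np.random.default_rng([seed, _stable_int(trial, period)])
    s_lat = float(truth.latent("survival", period, p)[0])
    s = s_lat + truth.batch_effect(trial, "survival", period)
    s += rng.normal(0.0, truth.noise_sd["survival"])
    s = float(np.clip(s, 0.0, 100.0))
    survivors = int(rng.binomial(stocked, s / 100.0))
    t_lat = float(truth.latent("tl", period, p)[0])
    t = t_lat + truth.batch_effect(trial, "tl", period)
    t += rng.normal(0.0, truth.noise_sd["tl"])
    return survivors, max(float(t), 0.1)


@dataclass(frozen=True)
class TrialPlan:
    trial_id: str
    diet_ids: tuple[str, ...]
    replicates: int = 1
    stocked: int = 250
    sampling_dph: tuple[int, ...] = (20, 40, 60, 80)
    restock_at_41: int | None = None  # cap on larvae kept at 41 dph


@dataclass(frozen=True)
class CampaignProtocol:
    """Trial layout: which diets, how many tanks, when sampled."""

    trials: tuple[TrialPlan, ...]
    reference_ids: tuple[str, str] = ("FSD", "FSY")

    def __post_init__(self) -> None:
        for plan in self.trials:
            missing = [r for r in self.reference_ids if r not in plan.diet_ids]
            if missing:
                raise SyntheticError(
                    f"trial {plan.trial_id}: reference diets {missing} absent"
                )


def _chain_fraction(total_frac: float, exponent: float) -> float:
    """Survival over a sub-interval, assuming constant hazard over the period."""
    return float(np.clip(total_frac, 0.0, 1.0) ** exponent)


def simulate_campaign(
    truth: GroundTruth,
    protocol: CampaignProtocol,
    formulations: dict[str, SimplexPoint],
    seed: int = 0,
) -> list[TankRecord]:
    """Simulate tank records for a whole multi-trial campaign.

    Counts are chained binomials through the sampling points (monotone
    non-increasing within each stocking segment); reference diets use the
    truth's stored formulations unless overridden.
    """
    forms = {**{k: v for k, v in truth.references.items()}, **formulations}
    records = []
    for plan in protocol.trials:
        for diet_id in plan.diet_ids:
            if diet_id not in forms:
                raise SyntheticError(
                    f"trial {plan.trial_id} references undefined diet {diet_id!r}"
                )
        for diet_id in plan.diet_ids:
            p = forms[diet_id].proportions
            for rep in range(plan.replicates):
                rng = np.random.default_rng(
                    [seed, truth.seed, _stable_int(plan.trial_id, diet_id, rep)]
                )
                rec = _simulate_one_tank(truth, p, plan, diet_id, rep, rng)
                records.append(rec)
    return records


def _noisy_pct(truth, p, trial_id, trait, period, rng) -> float:
    lat = float(truth.latent(trait, period, p)[0])
    val = lat + truth.batch_effect(trial_id, trait, period)
    val += rng.normal(0.0, truth.noise_sd[trait])
    return val


def _simulate_one_tank(truth, p, plan, diet_id, rep, rng) -> TankRecord:
    s_early = np.clip(
        _noisy_pct(truth, p, plan.trial_id, "survival", PERIOD_EARLY, rng), 0, 100
    ) / 100.0
    s_late = np.clip(
        _noisy_pct(truth, p, plan.trial_id, "survival", PERIOD_LATE, rng), 0, 100
    ) / 100.0
    tl40 = max(_noisy_pct(truth, p, plan.trial_id, "tl", PERIOD_EARLY, rng), 0.1)
    tl80 = max(_noisy_pct(truth, p, plan.trial_id, "tl", PERIOD_LATE, rng), 0.1)

    survivors: dict[int, int] = {}
    mean_tl: dict[int, float] = {}
    # early segment: 6 -> 40 dph, constant hazard split at the sampling points
    n20 = int(rng.binomial(plan.stocked, _chain_fraction(s_early, 14 / 34)))
    n40 = int(rng.binomial(n20, _chain_fraction(s_early, 20 / 34)))
    if 20 in plan.sampling_dph:
        survivors[20] = n20
        mean_tl[20] = round(max(0.55 * tl40, 0.1), 2)
    survivors[40] = n40
    mean_tl[40] = round(tl40, 2)

    restocked = None
    n41 = n40
    if plan.restock_at_41 is not None:
        restocked = min(plan.restock_at_41, n40)
        n41 = restocked
    n60 = int(rng.binomial(n41, _chain_fraction(s_late, 19 / 39)))
    n80 = int(rng.binomial(n60, _chain_fraction(s_late, 20 / 39)))
    if 60 in plan.sampling_dph:
        survivors[60] = n60
        mean_tl[60] = round(max(tl40 + 0.5 * (tl80 - tl40), 0.1), 2)
    if 80 in plan.sampling_dph:
        survivors[80] = n80
        mean_tl[80] = round(tl80, 2)
    if 100 in plan.sampling_dph:
        n100 = int(rng.binomial(n80, _chain_fraction(s_late, 20 / 39)))
        survivors[100] = n100
        mean_tl[100] = round(max(1.15 * tl80, 0.1), 2)
    return TankRecord(
        trial_id=plan.trial_id,
        diet_id=diet_id,
        tank_id=f"{plan.trial_id}-{diet_id}-{rep + 1}",
        stocked=plan.stocked,
        restocked_at_41=restocked,
        survivors=survivors,
        mean_tl=mean_tl,
    )


def default_protocol(
    n_trials: int = 2,
    diets_per_trial: int = 9,
    diet_prefix: str = "S",
    replicates: int = 1,
) -> tuple[CampaignProtocol, list[str]]:
    """A Phase-I-shaped protocol skeleton: n_trials single-tank screening
    trials, each with its own block of test diets plus the two references."""
    trials = []
    all_ids = []
    for t in range(n_trials):
        ids = tuple(
            f"{diet_prefix}{t * diets_per_trial + j + 1}" for j in range(diets_per_trial)
        )
        all_ids.extend(ids)
        trials.append(
            TrialPlan(
                trial_id=f"T{t + 1}",
                diet_ids=ids + ("FSD", "FSY"),
                replicates=replicates,
            )
        )
    return CampaignProtocol(trials=tuple(trials)), all_ids
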