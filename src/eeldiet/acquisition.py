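"""Multi-objective probability-of-improvement acquisition on the diet simplex.

Each candidate formulation is scored by the probability of improving on the
best observed standardized outcome for each trait,

    PI = Φ((μ − (f_best + ξ)) / σ),

and the two traits are combined as an equally weighted sum of log
probabilities, log PI_survival + log PI_TL.  The relaxation parameter ξ
tunes the explore/exploit balance: larger values (1e-3) promote
exploration, smaller (1e-6) exploitation.  Candidates are drawn uniformly
from the bounded simplex, scored in batch, near-duplicates collapsed, and
the top ``n_select`` returned; their coordinate-wise mean (renormalized) is
the representative average formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .formulations import FREE_INGREDIENTS, IngredientBounds, SimplexPoint
from .surrogate import GPSurrogateResults

XI_EXPLORE = 1e-3
XI_EXPLOIT = 1e-6

#: Floor inside the log to keep the combined score finite.
LOG_PI_FLOOR = 1e-300


class AcquisitionError(ValueError):
    pass


@dataclass(frozen=True)
class AcquisitionConfig:
    """Knobs of the candidate generator.

    xi lives on the standardized (z) objective scale, consistent with the
    surrogates' training targets.
    """

    xi: float = XI_EXPLORE
    weights: tuple[float, float] = (1.0, 1.0)
    pool_size: int = 100_000
    n_select: int = 100
    dedupe_l1: float = 0.01
    seed: int = 0
    f_best_mode: str = "observed"  # or "reference": improvement over z = 0

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise AcquisitionError("xi must be non-negative")
        if any(w < 0 for w in self.weights):
            raise AcquisitionError("weights must be non-negative")
        if self.n_select <= 0 or self.pool_size < self.n_select:
            raise AcquisitionError("need pool_size >= n_select > 0")


@dataclass(frozen=True)
class Candidate:
    point: SimplexPoint
    pi_survival: float
    pi_tl: float
    score: float


def probability_of_improvement(mu, sd, f_best: float, xi: float):
    """PI = Φ((μ − (f_best + ξ))/σ); σ = 0 degenerates to an indicator."""
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    target = f_best + xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mu - target) / sd
    pi = np.where(sd > 0, norm.cdf(z), (mu > target).astype(float))
    return pi if pi.ndim else float(pi)


def combined_log_pi(pi_s, pi_tl, weights: tuple[float, float] = (1.0, 1.0)):
    """Weighted sum of log PIs, floored to stay finite at PI = 0."""
    pi_s = np.maximum(np.asarray(pi_s, dtype=float), LOG_PI_FLOOR)
    pi_tl = np.maximum(np.asarray(pi_tl, dtype=float), LOG_PI_FLOOR)
    out = weights[0] * np.log(pi_s) + weights[1] * np.log(pi_tl)
    return out if out.ndim else float(out)


def sample_bounded_simplex(
    bounds: IngredientBounds | None, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform samples from the bounded 7-simplex.

    Dirichlet(1, …, 1) draws with rejection against the normalized bounds; a
    hit-and-run walk takes over when the rejection yield falls below 1%.
    """
    k = len(FREE_INGREDIENTS)
    if bounds is None:
        return rng.dirichlet(np.ones(k), size=n)
    lo, hi = bounds.normalized()
    if lo.sum() > 1 + 1e-9 or hi.sum() < 1 - 1e-9:
        raise AcquisitionError("bounds leave no feasible point on the simplex")
    kept: list[np.ndarray] = []
    total_drawn = 0
    total_accepted = 0
    needed = n
    while needed > 0:
        batch = max(4 * needed, 1000)
        draws = rng.dirichlet(np.ones(k), size=batch)
        ok = ((draws >= lo - 1e-12) & (draws <= hi + 1e-12)).all(axis=1)
        total_drawn += batch
        accepted = draws[ok]
        total_accepted += len(accepted)
        if len(accepted):
            kept.append(accepted[:needed])
            needed -= min(len(accepted), needed)
        if total_drawn >= 10_000 and total_accepted / total_drawn < 0.01:
            break
    if needed > 0:
        kept.append(_hit_and_run(lo, hi, needed, rng))
    return np.vstack(kept)[:n]


def _feasible_start(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """A strictly interior feasible point: lower bounds plus proportional slack."""
    slack = 1.0 - lo.sum()
    room = hi - lo
    if room.sum() <= 0 or slack < 0:
        raise AcquisitionError("bounds leave no feasible point on the simplex")
    return lo + room * (slack / room.sum())


def _hit_and_run(lo, hi, n: int, rng: np.random.Generator, thin: int = 10) -> np.ndarray:
    """Hit-and-run sampler on {x : lo <= x <= hi, sum x = 1}."""
    k = lo.size
    x = _feasible_start(lo, hi)
    out = np.empty((n, k))
    for i in range(n * thin + 50):
        d = rng.standard_normal(k)
        d -= d.mean()  # stay on the sum-1 hyperplane
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            continue
        d /= nrm
        with np.errstate(divide="ignore", invalid="ignore"):
            t_hi = np.where(d > 0, (hi - x) / d, np.where(d < 0, (lo - x) / d, np.inf))
            t_lo = np.where(d > 0, (lo - x) / d, np.where(d < 0, (hi - x) / d, -np.inf))
        tmax = t_hi.min()
        tmin = t_lo.max()
        if tmax > tmin:
            x = np.clip(x + rng.uniform(tmin, tmax) * d, lo, hi)
            x /= x.sum()
        j = i - 50
        if j >= 0 and j % thin == 0 and j // thin < n:
            out[j // thin] = x
    return out


def _dedupe_topk(points: np.ndarray, scores: np.ndarray, k: int, min_l1: float
                 ) -> np.ndarray:
    """Indices of the k best-scoring points pairwise at least min_l1 apart (L1)."""
    order = np.argsort(-scores)
    kept: list[int] = []
    kept_pts = np.empty((0, points.shape[1]))
    for idx in order:
        if kept and np.abs(kept_pts - points[idx]).sum(axis=1).min() < min_l1:
            continue
        kept.append(idx)
        kept_pts = points[kept]
        if len(kept) == k:
            break
    return np.array(kept, dtype=int)


def generate_candidates(
    surr_survival: GPSurrogateResults,
    surr_tl: GPSurrogateResults,
    bounds: IngredientBounds | None,
    cfg: AcquisitionConfig = AcquisitionConfig(),
) -> list[Candidate]:
    """Ranked batch of candidate formulations maximizing the combined log-PI.

    A seeded uniform pool over the bounded simplex is scored under both
    surrogates; near-duplicates (L1 distance < cfg.dedupe_l1) are collapsed
    keeping the higher score; exactly cfg.n_select candidates are returned
    in descending score order.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = sample_bounded_simplex(bounds, cfg.pool_size, rng)
    mu_s, sd_s = surr_survival.predict(pool)
    mu_t, sd_t = surr_tl.predict(pool)
    if cfg.f_best_mode == "observed":
        f_best_s = float(surr_survival.model.y.max())
        f_best_t = float(surr_tl.model.y.max())
    elif cfg.f_best_mode == "reference":
        f_best_s = f_best_t = 0.0
    else:
        raise AcquisitionError(f"unknown f_best_mode {cfg.f_best_mode!r}")
    pi_s = probability_of_improvement(mu_s, sd_s, f_best_s, cfg.xi)
    pi_t = probability_of_improvement(mu_t, sd_t, f_best_t, cfg.xi)
    scores = combined_log_pi(pi_s, pi_t, cfg.weights)
    keep = _dedupe_topk(pool, scores, cfg.n_select, cfg.dedupe_l1)
    if len(keep) < cfg.n_select:
        raise AcquisitionError(
            f"pool yielded only {len(keep)} distinct feasible candidates "
            f"(requested {cfg.n_select}); enlarge pool_size or loosen dedupe_l1"
        )
    return [
        Candidate(
            point=SimplexPoint(pool[i] / pool[i].sum(), bounds=bounds),
            pi_survival=float(pi_s[i]),
            pi_tl=float(pi_t[i]),
            score=float(scores[i]),
        )
        for i in keep
    ]


def representative_formulation(cands: list[Candidate]) -> SimplexPoint:
    """Coordinate-wise mean of candidate points, renormalized to sum one."""
    if not cands:
        raise AcquisitionError("empty candidate list")
    mean = np.mean([c.point.proportions for c in cands], axis=0)
    return SimplexPoint(mean / mean.sum())


def candidates_to_frame(cands: list[Candidate]) -> pd.DataFrame:
    """One row per candidate: 7 proportions, both PIs, combined score."""
    rows = []
    for c in cands:
        row = dict(zip(FREE_INGREDIENTS, c.point.proportions.tolist()))
        row.update(pi_survival=c.pi_survival, pi_tl=c.pi_tl, score=c.score)
        rows.append(row)
    return pd.DataFrame(rows)


def parallel_coordinates_export(cands: list[Candidate], highlight: list[int] | None = None
                                ) -> dict:
    """Parallel-coordinates structure: one axis per ingredient, one line per candidate."""
    return {
        "axes": list(FREE_INGREDIENTS),
        "lines": [c.point.proportions.tolist() for c in cands],
        "scores": [c.score for c in cands],
        "highlight": highlight or [],
    }
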