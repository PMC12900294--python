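"""D-optimal mixture designs over the bounded ingredient simplex.

The initial diet screen picks formulations that maximize det(XᵀX) of a
Scheffé mixture-model matrix (degree 1: the proportions themselves, no
intercept; degree 2: plus all pairwise products).  A greedy Fedorov
exchange over a seeded candidate pool serves as the optimizer: starting
from a random non-singular subset, points are swapped with pool points
whenever the swap increases the determinant, until a local optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .acquisition import sample_bounded_simplex
from .formulations import FREE_INGREDIENTS, IngredientBounds, SimplexPoint


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class MixtureModelSpec:
    scheffe_degree: int = 1

    def __post_init__(self) -> None:
        if self.scheffe_degree not in (1, 2):
            raise DesignError("scheffe_degree must be 1 or 2")

    def n_parameters(self, k: int) -> int:
        return k + (k * (k - 1) // 2 if self.scheffe_degree == 2 else 0)


def mixture_model_matrix(points: np.ndarray, spec: MixtureModelSpec) -> np.ndarray:
    """Scheffé model matrix: proportions (no intercept), plus pairwise products
    at degree 2."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if spec.scheffe_degree == 1:
        return P
    pairs = [P[:, i] * P[:, j] for i, j in combinations(range(P.shape[1]), 2)]
    return np.column_stack([P, *pairs])


def log_det_information(points: np.ndarray, spec: MixtureModelSpec) -> float:
    """log det(XᵀX) of the design; -inf for a singular design."""
    X = mixture_model_matrix(points, spec)
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return logdet if sign > 0 else -np.inf


def d_optimal_design(
    bounds: IngredientBounds | None,
    n_runs: int,
    spec: MixtureModelSpec = MixtureModelSpec(),
    pool_size: int = 2000,
    seed: int = 0,
    include_vertices: bool = True,
    max_passes: int = 20,
    n_components: int | None = None,
) -> np.ndarray:
    """Greedy Fedorov-exchange D-optimal design on the bounded simplex.

    The candidate pool mixes uniform draws with the simplex vertices (when
    feasible under the bounds), since degree-1 optima sit at extreme points.
    det(XᵀX) is non-decreasing across exchanges; the search stops at a local
    optimum.  Deterministic for a given seed.  Returns an (n_runs, k) array
    of simplex rows; :func:`design_to_points` wraps the seven-ingredient
    case into :class:`~eeldiet.formulations.SimplexPoint` objects.
    """
    k = n_components if n_components is not None else len(FREE_INGREDIENTS)
    n_par = spec.n_parameters(k)
    if n_runs < n_par:
        raise DesignError(f"n_runs = {n_runs} < {n_par} model parameters")
    rng = np.random.default_rng(seed)
    if bounds is None:
        pool = rng.dirichlet(np.ones(k), size=pool_size)
    else:
        pool = sample_bounded_simplex(bounds, pool_size, rng)
    if include_vertices:
        extremes = _extreme_candidates(bounds, k)
        if len(extremes):
            pool = np.vstack([extremes, pool])
    if pool.shape[1] != k:
        raise DesignError(f"bounds imply {pool.shape[1]} components, expected {k}")

    # random non-singular start
    design_idx = None
    for _ in range(200):
        idx = rng.choice(len(pool), size=n_runs, replace=False)
        if np.isfinite(log_det_information(pool[idx], spec)):
            design_idx = idx
            break
    if design_idx is None:
        raise DesignError("could not find a non-singular starting design")

    design = pool[design_idx].copy()
    best = log_det_information(design, spec)
    for _ in range(max_passes):
        improved = False
        for i in range(n_runs):
            saved = design[i].copy()
            # best replacement for row i from the whole pool
            gains = np.full(len(pool), -np.inf)
            for j in range(len(pool)):
                design[i] = pool[j]
                gains[j] = log_det_information(design, spec)
            j_best = int(np.argmax(gains))
            if gains[j_best] > best + 1e-12:
                design[i] = pool[j_best]
                best = gains[j_best]
                improved = True
            else:
                design[i] = saved
        if not improved:
            break
    if not np.isfinite(best):
        raise DesignError("final design matrix is singular")
    return design / design.sum(axis=1, keepdims=True)


def design_to_points(design: np.ndarray,
                     bounds: IngredientBounds | None = None) -> list[SimplexPoint]:
    """Wrap the rows of a seven-component design into SimplexPoints."""
    return [SimplexPoint(row, bounds=bounds) for row in design]


def _extreme_candidates(bounds: IngredientBounds | None, k: int) -> np.ndarray:
    """Vertices of the (possibly bounded) simplex that satisfy the bounds."""
    if bounds is None:
        return np.eye(k)
    if len(FREE_INGREDIENTS) != k:
        return np.empty((0, k))
    lo, hi = bounds.normalized()
    verts = []
    for v in np.eye(k):
        if ((v >= lo - 1e-9) & (v <= hi + 1e-9)).all():
            verts.append(v)
    # one-ingredient-at-upper-bound points, remainder spread at lower bounds
    for i in range(k):
        x = lo.copy()
        x[i] = hi[i]
        slack = 1.0 - x.sum()
        if slack < -1e-9:
            continue
        room = np.minimum(hi - x, 1.0)
        room[i] = 0.0
        if slack > 1e-12 and room.sum() > 0:
            x = x + room * min(slack / room.sum(), 1.0)
        if abs(x.sum() - 1.0) < 1e-9 and ((x >= lo - 1e-9) & (x <= hi + 1e-9)).all():
            verts.append(x / x.sum())
    return np.array(verts) if verts else np.empty((0, k))
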