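"""Diet formulations on the bounded ingredient simplex.

A larval diet is a mixture of nine ingredients expressed in mass percent of
the total diet.  Seven of them (egg yolk powder, skimmed milk powder, yeast
extract, soy peptide, casein Na, CPSP, fish oil) are free optimization
variables; the two additives (vitamin mix, taurine) are held essentially
constant at ~2.2% each.  All surrogate modelling and acquisition happens in
normalized simplex coordinates: the seven free mass percents divided by
their sum, a non-negative vector summing to one.

This module owns the two coordinate systems, the conversions between them,
and ingredient bounds in either system.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

INGREDIENTS: tuple[str, ...] = (
    "egg_yolk_powder",
    "skimmed_milk_powder",
    "yeast_extract",
    "soy_peptide",
    "casein_na",
    "cpsp",
    "fish_oil",
    "vitamin_mix",
    "taurine",
)

FREE_INGREDIENTS: tuple[str, ...] = INGREDIENTS[:7]
FIXED_ADDITIVES: tuple[str, ...] = INGREDIENTS[7:]

#: Default mass percent of each fixed additive (majority of the formulation
#: table; a few rows use 2.1%, accepted by the [2.0, 2.3] window).
DEFAULT_ADDITIVE_PCT = 2.2

#: Tolerance on the printed row total: nine ingredients each rounded to
#: 0.1% can drift the sum by up to 9 × 0.05 = 0.45 from 100.
TOTAL_TOL = 0.45

ADDITIVE_WINDOW = (2.0, 2.3)


class FormulationError(ValueError):
    """Invalid diet formulation or simplex point."""


@dataclass(frozen=True)
class DietFormulation:
    """A labelled diet: mass percent per ingredient, summing to 100."""

    diet_id: str
    mass_pct: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(INGREDIENTS) - set(self.mass_pct)
        if missing:
            raise FormulationError(
                f"diet {self.diet_id!r}: missing ingredients {sorted(missing)}"
            )
        unknown = set(self.mass_pct) - set(INGREDIENTS)
        if unknown:
            raise FormulationError(
                f"diet {self.diet_id!r}: unknown ingredients {sorted(unknown)}"
            )
        vals = np.array([self.mass_pct[k] for k in INGREDIENTS], dtype=float)
        if (vals < 0).any():
            raise FormulationError(f"diet {self.diet_id!r}: negative mass percent")
        total = vals.sum()
        if abs(total - 100.0) > TOTAL_TOL:
            raise FormulationError(
                f"diet {self.diet_id!r}: ingredient sum {total:.2f} outside "
                f"100 ± {TOTAL_TOL}"
            )
        lo, hi = ADDITIVE_WINDOW
        for add in FIXED_ADDITIVES:
            v = self.mass_pct[add]
            if not (lo <= v <= hi):
                raise FormulationError(
                    f"diet {self.diet_id!r}: {add} = {v} outside [{lo}, {hi}]"
                )

    @property
    def free_mass(self) -> np.ndarray:
        return np.array([self.mass_pct[k] for k in FREE_INGREDIENTS], dtype=float)

    @property
    def fixed_total(self) -> float:
        return float(sum(self.mass_pct[k] for k in FIXED_ADDITIVES))

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.mass_pct[k] for k in INGREDIENTS}, name=self.diet_id)


@dataclass(frozen=True)
class IngredientBounds:
    """Lower/upper mass-percent bounds for each free ingredient."""

    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self) -> None:
        for k in FREE_INGREDIENTS:
            lo = self.lower.get(k, 0.0)
            hi = self.upper.get(k, 100.0)
            if not (0.0 <= lo <= hi <= 100.0):
                raise FormulationError(f"bounds for {k}: need 0 <= {lo} <= {hi} <= 100")
        free_total = 100.0 - 2 * DEFAULT_ADDITIVE_PCT
        lo_sum = sum(self.lower.get(k, 0.0) for k in FREE_INGREDIENTS)
        hi_sum = sum(self.upper.get(k, 100.0) for k in FREE_INGREDIENTS)
        if not (lo_sum <= free_total <= hi_sum):
            raise FormulationError(
                f"infeasible bounds: free ingredients must sum to {free_total:.1f} "
                f"but bounds allow [{lo_sum:.1f}, {hi_sum:.1f}]"
            )

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.lower.get(k, 0.0) for k in FREE_INGREDIENTS])
        hi = np.array([self.upper.get(k, 100.0) for k in FREE_INGREDIENTS])
        return lo, hi

    def normalized(self, free_total: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Bounds in simplex coordinates: mass bounds / free-ingredient total."""
        if free_total is None:
            free_total = 100.0 - 2 * DEFAULT_ADDITIVE_PCT
        lo, hi = self.arrays()
        return lo / free_total, np.minimum(hi / free_total, 1.0)


@dataclass(frozen=True)
class SimplexPoint:
    """Seven free-ingredient proportions summing to one."""

    proportions: np.ndarray
    bounds: IngredientBounds | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", p)
        if p.shape != (len(FREE_INGREDIENTS),):
            raise FormulationError(
                f"simplex point needs {len(FREE_INGREDIENTS)} coordinates, got {p.shape}"
            )
        if (p < 0).any():
            raise FormulationError("simplex proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise FormulationError(f"simplex proportions sum to {p.sum()!r}, not 1")
        if self.bounds is not None:
            lo, hi = self.bounds.normalized()
            # rounding in mass-percent space can push a coordinate a hair out
            if (p < lo - 2e-3).any() or (p > hi + 2e-3).any():
                raise FormulationError("simplex point violates attached bounds")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(FREE_INGREDIENTS))


def _packaged(name: str):
    return importlib.resources.files("eeldiet.data").joinpath(name)


def load_formulations(source=None) -> list[DietFormulation]:
    """Read a formulation table (CSV) into validated :class:`DietFormulation`s.

    ``source`` is a path or file-like; by default the packaged formulation
    table (41 diets including the two references FSD and FSY) is loaded.
    When a ``total`` column is present it is checked against the recomputed
    ingredient sum.
    """
    if source is None:
        source = _packaged("diet_formulations.csv")
    df = pd.read_csv(source)
    expected = {"diet_id", *INGREDIENTS}
    cols = set(df.columns) - {"total"}
    if cols != expected:
        extra, missing = sorted(cols - expected), sorted(expected - cols)
        raise FormulationError(
            f"formulation table schema mismatch: unknown columns {extra}, "
            f"missing columns {missing}"
        )
    out = []
    for _, row in df.iterrows():
        mass = {k: float(row[k]) for k in INGREDIENTS}
        if "total" in df.columns and not pd.isna(row["total"]):
            recomputed = sum(mass.values())
            if abs(recomputed - float(row["total"])) > TOTAL_TOL:
                raise FormulationError(
                    f"diet {row['diet_id']!r}: printed total {row['total']} "
                    f"disagrees with recomputed sum {recomputed:.2f}"
                )
        out.append(DietFormulation(str(row["diet_id"]), mass))
    return out


def to_simplex(f: DietFormulation, bounds: IngredientBounds | None = None) -> SimplexPoint:
    """Normalize the seven free-ingredient mass percents to sum one."""
    free = f.free_mass
    s = free.sum()
    if s <= 0:
        raise FormulationError(f"diet {f.diet_id!r}: all free ingredients are zero")
    return SimplexPoint(free / s, bounds=bounds)


def _round_largest_remainder(values: np.ndarray, target: float, decimals: int = 1) -> np.ndarray:
    """Round to ``decimals`` while preserving the exact total via largest remainder."""
    scale = 10**decimals
    scaled = values * scale
    floored = np.floor(scaled)
    units_short = int(round(target * scale - floored.sum()))
    order = np.argsort(-(scaled - floored))
    out = floored.copy()
    if units_short > 0:
        out[order[:units_short]] += 1
    elif units_short < 0:
        # over target after flooring cannot happen; guard for negative drift
        order_low = np.argsort(scaled - floored)
        out[order_low[:-units_short]] -= 1
    return out / scale


def from_simplex(
    p: SimplexPoint,
    fixed_additives: dict[str, float] | None = None,
    diet_id: str = "candidate",
) -> DietFormulation:
    """Scale simplex proportions back to a mass-percent formulation.

    Free ingredients are scaled to ``100 - sum(fixed additives)`` and rounded
    to 0.1% with a largest-remainder correction so the printed total is
    exactly 100.0.
    """
    if fixed_additives is None:
        fixed_additives = {k: DEFAULT_ADDITIVE_PCT for k in FIXED_ADDITIVES}
    fixed_total = sum(fixed_additives.values())
    if fixed_total >= 100.0:
        raise FormulationError(f"fixed additives total {fixed_total} >= 100")
    free_total = 100.0 - fixed_total
    free = _round_largest_remainder(p.proportions * free_total, free_total)
    mass = dict(zip(FREE_INGREDIENTS, free.tolist()))
    mass.update({k: float(v) for k, v in fixed_additives.items()})
    return DietFormulation(diet_id, mass)


def default_bounds(formulations: list[DietFormulation] | None = None) -> IngredientBounds:
    """Per-ingredient min/max mass percent observed across a formulation table.

    The only in-data evidence of the feasible region when no explicit bounds
    file is configured.
    """
    if formulations is None:
        formulations = load_formulations()
    free = np.array([f.free_mass for f in formulations])
    return IngredientBounds(
        lower=dict(zip(FREE_INGREDIENTS, free.min(axis=0).tolist())),
        upper=dict(zip(FREE_INGREDIENTS, free.max(axis=0).tolist())),
    )


def load_bounds(source) -> IngredientBounds:
    """Read a YAML bounds file keyed by ingredient name with lower/upper."""
    with open(source) as fh:
        raw = yaml.safe_load(fh)
    lower, upper = {}, {}
    for k, v in raw.items():
        if k not in FREE_INGREDIENTS:
            raise FormulationError(f"bounds file names unknown free ingredient {k!r}")
        lower[k] = float(v["lower"])
        upper[k] = float(v["upper"])
    return IngredientBounds(lower, upper)
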