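"""Proximate composition arithmetic for formulated diets.

Per-ingredient analytical values (moisture as analyzed; crude protein,
crude lipid, crude ash, nucleic acids and crude carbohydrate on a dry-matter
basis) are combined into diet-level estimates by a dry-mass-weighted linear
mixture.  Two standard pieces of feed chemistry are included: the Kjeldahl
protein conversion with a nucleic-acid nitrogen correction for yeast
extracts, and the nitrogen-free-extract (NFE) closure for carbohydrate.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formulations import INGREDIENTS, DietFormulation

#: Kjeldahl nitrogen-to-protein conversion factor.
KJELDAHL_FACTOR = 6.25

#: Fraction of RNA mass that is nitrogen, used to correct yeast total N.
RNA_NITROGEN_FRACTION = 0.146

#: Dry-matter components of a profile, in canonical order.
DM_COMPONENTS = (
    "crude_protein",
    "crude_lipid",
    "crude_ash",
    "nucleic_acids",
    "crude_carbohydrate",
)


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class ProximateProfile:
    """Proximate composition: moisture as-analyzed, components % of dry matter."""

    moisture: float
    crude_protein: float
    crude_lipid: float
    crude_ash: float
    nucleic_acids: float = 0.0
    crude_carbohydrate: float = 0.0

    def __post_init__(self) -> None:
        vals = [getattr(self, c) for c in ("moisture", *DM_COMPONENTS)]
        if any(v < 0 for v in vals):
            raise CompositionError("proximate components must be non-negative")
        dm_sum = sum(getattr(self, c) for c in DM_COMPONENTS)
        if abs(dm_sum - 100.0) > 0.5:
            raise CompositionError(
                f"dry-matter components sum to {dm_sum:.2f}, outside 100 ± 0.5"
            )

    @property
    def dry_matter_fraction(self) -> float:
        return (100.0 - self.moisture) / 100.0

    def as_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in ("moisture", *DM_COMPONENTS)})


def yeast_crude_protein(total_n: float, rna: float) -> float:
    """Crude protein (%) of a yeast extract from total Kjeldahl N and RNA content.

    Nucleic-acid nitrogen (RNA × 0.146) is subtracted from total nitrogen
    before the N × 6.25 conversion.  With rna = 0 this reduces to the plain
    Kjeldahl estimate.
    """
    protein_n = total_n - rna * RNA_NITROGEN_FRACTION
    if protein_n < 0:
        raise CompositionError(
            f"protein nitrogen negative ({protein_n:.3f}): total N {total_n} "
            f"inconsistent with RNA {rna}"
        )
    return protein_n * KJELDAHL_FACTOR


@dataclass(frozen=True)
class NFEResult:
    value: float
    negative: bool

    def __float__(self) -> float:
        return self.value


def nfe(moisture: float, crude_protein: float, crude_lipid: float,
        crude_ash: float, nucleic_acids: float) -> NFEResult:
    """Nitrogen-free extract by difference.

    NFE = 100 − (moisture + crude protein + crude lipid + crude ash +
    nucleic acids).  A negative closure is returned flagged, never clamped:
    it signals inconsistent analytics upstream.
    """
    parts = (moisture, crude_protein, crude_lipid, crude_ash, nucleic_acids)
    if any(not (0 <= v <= 100) for v in parts):
        raise CompositionError("all NFE inputs must lie in [0, 100]")
    value = 100.0 - sum(parts)
    return NFEResult(value=value, negative=value < 0)


def diet_proximate(
    f: DietFormulation, profiles: dict[str, ProximateProfile]
) -> ProximateProfile:
    """Estimate a diet's proximate composition from its ingredient profiles.

    Each dry-matter component is the dry-mass-share-weighted mean of the
    ingredient values; moisture is the as-fed mass-weighted mean.
    """
    for name in INGREDIENTS:
        if f.mass_pct[name] > 0 and name not in profiles:
            raise CompositionError(f"no proximate profile for ingredient {name!r}")
    names = [n for n in INGREDIENTS if f.mass_pct[n] > 0]
    mass = np.array([f.mass_pct[n] for n in names])
    moist = np.array([profiles[n].moisture for n in names])
    dry_mass = mass * (100.0 - moist) / 100.0
    dry_share = dry_mass / dry_mass.sum()
    mass_share = mass / mass.sum()
    comp = {
        c: float(dry_share @ np.array([getattr(profiles[n], c) for n in names]))
        for c in DM_COMPONENTS
    }
    return ProximateProfile(moisture=float(mass_share @ moist), **comp)


def load_ingredient_profiles(source=None) -> dict[str, ProximateProfile]:
    """Read per-ingredient profiles from CSV.

    With no ``source``, loads the packaged synthetic ingredient table — a
    literature-plausible stand-in used for demonstrations and tests, not
    analytical measurements of the actual feed ingredients.
    """
    if source is None:
        source = importlib.resources.files("eeldiet.data").joinpath(
            "ingredient_profiles_synthetic.csv"
        )
    df = pd.read_csv(source)
    out = {}
    for _, row in df.iterrows():
        out[str(row["ingredient"])] = ProximateProfile(
            moisture=float(row["moisture"]),
            crude_protein=float(row["crude_protein"]),
            crude_lipid=float(row["crude_lipid"]),
            crude_ash=float(row["crude_ash"]),
            nucleic_acids=float(row.get("nucleic_acids", 0.0)),
            crude_carbohydrate=float(row["crude_carbohydrate"]),
        )
    return out


def diet_composition_table(
    formulations: list[DietFormulation],
    profiles: dict[str, ProximateProfile] | None = None,
) -> pd.DataFrame:
    """Proximate composition (% DM) for every diet in a formulation list."""
    if profiles is None:
        profiles = load_ingredient_profiles()
    rows = {f.diet_id: diet_proximate(f, profiles).as_series() for f in formulations}
    return pd.DataFrame(rows).T.rename_axis("diet_id")
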