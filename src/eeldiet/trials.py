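"""Tank-level trial data: period outcomes and reference standardization.

Rearing trials stock ~250 larvae per tank at 6 days post-hatch (dph), count
survivors and measure mean total length (TL, mm) at 20/40/60/80 (and
optionally 100) dph.  Outcomes are summarized over two modelling periods —
early (6–40 dph) and late (41–80 dph) — plus an overall 6–80 dph reporting
period, then standardized within each trial against the two reference diets
(FSD, FSY) to remove batch effects:

    z = (x − mean(references)) / SD(references)

Later trials equalize densities at 41 dph ("restocking"); cumulative
survival after that point chains the survival to 40 dph with the interval
survival using the restocked count as the new denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_DIETS: tuple[str, str] = ("FSD", "FSY")

PERIOD_EARLY = "6-40"
PERIOD_LATE = "41-80"
PERIOD_OVERALL = "6-80"
PERIODS = (PERIOD_EARLY, PERIOD_LATE, PERIOD_OVERALL)

#: The two periods actually modelled (the overall period is reporting-only).
MODEL_PERIODS_CHOICES = [PERIOD_EARLY, PERIOD_LATE]

#: Terminal sampling point (dph) defining each period's endpoint.
PERIOD_ENDPOINT = {PERIOD_EARLY: 40, PERIOD_LATE: 80, PERIOD_OVERALL: 80}


class TrialDataError(ValueError):
    pass


@dataclass
class TankRecord:
    """Counts and mean TL for one tank across sampling points."""

    trial_id: str
    diet_id: str
    tank_id: str
    stocked: int = 250
    restocked_at_41: int | None = None
    survivors: dict[int, int] = field(default_factory=dict)
    mean_tl: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stocked <= 0:
            raise TrialDataError(f"tank {self.tank_id}: stocked must be positive")
        pre = sorted(d for d in self.survivors if d <= 40)
        post = sorted(d for d in self.survivors if d > 40)
        cap = self.stocked
        for seg in (pre, post):
            if seg is post:
                cap = self.restocked_at_41 if self.restocked_at_41 is not None else (
                    self.survivors.get(40, self.stocked)
                )
            prev = cap
            for d in seg:
                n = self.survivors[d]
                if not (0 <= n <= prev):
                    raise TrialDataError(
                        f"tank {self.tank_id}: survivors at {d} dph ({n}) exceed "
                        f"{prev} or are negative (non-increasing within segment)"
                    )
                prev = n
        for d, tl in self.mean_tl.items():
            if not tl > 0:
                raise TrialDataError(f"tank {self.tank_id}: TL at {d} dph must be > 0")

    @property
    def stocked_at_41(self) -> int | None:
        if self.restocked_at_41 is not None:
            return self.restocked_at_41
        return self.survivors.get(40)


def survival_rate(survivors: int, stocked: int) -> float:
    """Percent surviving relative to the stocked count."""
    if stocked <= 0:
        raise TrialDataError("stocked count must be positive")
    if not (0 <= survivors <= stocked):
        raise TrialDataError(f"survivors {survivors} outside [0, {stocked}]")
    return 100.0 * survivors / stocked

def chained_survival(s40: float, stocked41: int, survivors_t: int) -> float:
    """Cumulative survival after restocking at 41 dph.

    Multiplies the cumulative survival to 40 dph by the post-41 interval
    survival, with the restocked count as the new denominator.
    """
    if not (0.0 <= s40 <= 100.0):
        raise TrialDataError(f"survival to 40 dph {s40} outside [0, 100]")
    if stocked41 <= 0:
        raise TrialDataError("count stocked at 41 dph must be positive")
    if not (0 <= survivors_t <= stocked41):
        raise TrialDataError(f"survivors {survivors_t} outside [0, {stocked41}]")
    return s40 * survivors_t / stocked41


def _tank_period_outcomes(rec: TankRecord) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    s40 = rec.survivors.get(40)
    s80 = rec.survivors.get(80)
    early_surv = survival_rate(s40, rec.stocked) if s40 is not None else np.nan

    late_surv = overall_surv = np.nan
    if s80 is not None:
        n41 = rec.stocked_at_41
        if n41 is not None and n41 > 0:
            late_surv = 100.0 * s80 / n41
            if rec.restocked_at_41 is not None:
                if not np.isnan(early_surv):
                    overall_surv = chained_survival(early_surv, n41, s80)
            else:
                overall_surv = survival_rate(s80, rec.stocked)
        elif n41 == 0:
            # everything died before restocking; overall survival is simply 0
            overall_surv = 0.0 if rec.restocked_at_41 is None else np.nan

    out[PERIOD_EARLY] = {"survival": early_surv, "mean_tl": rec.mean_tl.get(40, np.nan)}
    out[PERIOD_LATE] = {"survival": late_surv, "mean_tl": rec.mean_tl.get(80, np.nan)}
    out[PERIOD_OVERALL] = {"survival": overall_surv, "mean_tl": rec.mean_tl.get(80, np.nan)}
    return out


def period_outcomes(records: list[TankRecord]) -> pd.DataFrame:
    """Per-trial, per-diet outcomes for the three periods.

    Tank replicates are averaged.  Diets missing the terminal sampling point
    of a period carry NaN there (flagged missing, never imputed).
    """
    rows = []
    for rec in records:
        per = _tank_period_outcomes(rec)
        for period, vals in per.items():
            rows.append(
                {
                    "trial_id": rec.trial_id,
                    "diet_id": rec.diet_id,
                    "tank_id": rec.tank_id,
                    "period": period,
                    "survival": vals["survival"],
                    "mean_tl": vals["mean_tl"],
                }
            )
    tanks = pd.DataFrame(rows)
    return (
        tanks.groupby(["trial_id", "diet_id", "period"], sort=False)[["survival", "mean_tl"]]
        .mean()
        .reset_index()
    )


def standardize_z(
    values: pd.Series,
    reference_ids: tuple[str, str] = REFERENCE_DIETS,
    sd_mode: str = "references",
) -> pd.Series:
    """Z-scores of per-diet trait values within one trial.

    The center is always the mean of the two reference diets.  ``sd_mode``
    selects the denominator: ``"references"`` (default) uses the sample SD of
    the two reference values, |x1 − x2|/√2; ``"trial"`` uses the sample SD of
    all diets in the trial.
    """
    missing = [r for r in reference_ids if r not in values.index]
    if missing:
        raise TrialDataError(f"reference diets missing from trial values: {missing}")
    refs = values.loc[list(reference_ids)].astype(float)
    if refs.isna().any():
        raise TrialDataError("reference diet values must be finite")
    center = refs.mean()
    if sd_mode == "references":
        sd = refs.std(ddof=1)
    elif sd_mode == "trial":
        sd = values.dropna().astype(float).std(ddof=1)
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if not sd > 0:
        raise TrialDataError("standardization SD is zero (undefined z-scores)")
    return (values - center) / sd


def standardize_outcomes(
    outcomes: pd.DataFrame,
    reference_ids: tuple[str, str] = REFERENCE_DIETS,
    sd_mode: str = "references",
    on_zero_sd: str = "raise",
) -> pd.DataFrame:
    """Standardize survival and mean TL per trial × period against references.

    Input is the frame from :func:`period_outcomes`; output adds
    ``z_survival`` and ``z_tl`` columns.  Standardization is applied
    independently within every (trial, period) for each trait.  A (trial,
    period, trait) whose references are missing yields NaN z-scores; a
    zero reference SD raises by default, or yields NaN with
    ``on_zero_sd="nan"`` (exact reference ties happen with count-valued
    survival data).
    """
    if on_zero_sd not in ("raise", "nan"):
        raise ValueError(f"unknown on_zero_sd policy {on_zero_sd!r}")
    out = outcomes.copy()
    for col, zcol in (("survival", "z_survival"), ("mean_tl", "z_tl")):
        zparts = []
        for (trial, period), grp in out.groupby(["trial_id", "period"], sort=False):
            vals = grp.set_index("diet_id")[col]
            try:
                z = standardize_z(vals, reference_ids, sd_mode)
            except TrialDataError as exc:
                refs_missing = vals.reindex(list(reference_ids)).isna().all()
                zero_sd = "SD is zero" in str(exc)
                if refs_missing or (zero_sd and on_zero_sd == "nan"):
                    z = pd.Series(np.nan, index=vals.index)
                else:
                    raise
            zparts.append(pd.Series(z.values, index=grp.index))
        out[zcol] = pd.concat(zparts).sort_index()
    return out


def _z_wide(standardized: pd.DataFrame) -> pd.DataFrame:
    """One row per (trial, diet); 6 columns: trait × period z-scores."""
    wide = standardized.pivot_table(
        index=["trial_id", "diet_id"],
        columns="period",
        values=["z_survival", "z_tl"],
        sort=False,
    )
    cols = [
        (trait, period)
        for trait in ("z_survival", "z_tl")
        for period in PERIODS
        if (trait, period) in wide.columns
    ]
    wide = wide[cols]
    wide.columns = [f"{t}_{p}" for t, p in wide.columns]
    return wide


def pairwise_correlations(
    standardized: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among the six standardized trait × period variables.

    Pairwise-complete: each cell uses the diets observed for both variables.
    Cells with fewer than ``min_pairs`` complete pairs are NaN.  Returns
    (r, p) matrices, symmetric with unit diagonal.
    """
    wide = _z_wide(standardized)
    names = list(wide.columns)
    k = len(names)
    r = pd.DataFrame(np.eye(k), index=names, columns=names)
    p = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            pair = wide[[names[i], names[j]]].dropna()
            if len(pair) < min_pairs or pair.var().min() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def load_trial_protocol(source=None) -> pd.DataFrame:
    """Read the packaged trial-protocol table (eight feeding trials).

    Columns: trial_id, phase, objective, diets (``;``-separated; ``->``
    marks a diet switch at 41 dph), replicates, total_tanks, sampling_dph,
    restock_at_41.
    """
    if source is None:
        import importlib.resources

        source = importlib.resources.files("eeldiet.data").joinpath(
            "trial_protocol.csv"
        )
    df = pd.read_csv(source)
    df["diet_list"] = df["diets"].str.split(";")
    df["sampling_points"] = df["sampling_dph"].apply(
        lambda s: tuple(int(x) for x in str(s).split(";"))
    )
    return df


def protocol_formulation_counts(
    protocol: pd.DataFrame, reference_ids: tuple[str, str] = REFERENCE_DIETS
) -> dict[str, int]:
    """Distinct non-reference formulations tested, by phase.

    A switch series (``A->B``) contributes its component diets.  Returns
    counts for phase I, the *new* formulations introduced in phase II, and
    the distinct total across the four screening/exploration trials
    (phases I + II).
    """
    def diets_of(phases):
        out = set()
        for _, row in protocol[protocol["phase"].isin(phases)].iterrows():
            for entry in row["diet_list"]:
                for diet in entry.split("->"):
                    diet = diet.strip()
                    if diet not in reference_ids:
                        out.add(diet)
        return out

    phase1 = diets_of({"I"})
    phase2 = diets_of({"II"})
    return {
        "phase_I": len(phase1),
        "phase_II_new": len(phase2 - phase1),
        "screening_total": len(phase1 | phase2),
    }


def read_tank_records(source) -> list[TankRecord]:
    """Read the long-format tank-record CSV.

    Columns: ``trial_id,diet_id,tank_id,stocked,restocked41,dph,survivors,mean_tl``
    with one row per tank × sampling point; restocked41 empty when no
    restocking occurred.
    """
    df = pd.read_csv(source)
    records = []
    keys = ["trial_id", "diet_id", "tank_id"]
    for (trial, diet, tank), grp in df.groupby(keys, sort=False):
        stocked = int(grp["stocked"].iloc[0])
        restocked = grp["restocked41"].dropna()
        restocked_at_41 = int(restocked.iloc[0]) if len(restocked) else None
        survivors = {
            int(r["dph"]): int(r["survivors"])
            for _, r in grp.iterrows()
            if not pd.isna(r["survivors"])
        }
        mean_tl = {
            int(r["dph"]): float(r["mean_tl"])
            for _, r in grp.iterrows()
            if not pd.isna(r["mean_tl"])
        }
        records.append(
            TankRecord(str(trial), str(diet), str(tank), stocked,
                       restocked_at_41, survivors, mean_tl)
        )
    return records


def write_tank_records(records: list[TankRecord], path) -> None:
    rows = []
    for rec in records:
        for dph in sorted(set(rec.survivors) | set(rec.mean_tl)):
            rows.append(
                {
                    "trial_id": rec.trial_id,
                    "diet_id": rec.diet_id,
                    "tank_id": rec.tank_id,
                    "stocked": rec.stocked,
                    "restocked41": rec.restocked_at_41,
                    "dph": dph,
                    "survivors": rec.survivors.get(dph),
                    "mean_tl": rec.mean_tl.get(dph),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
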