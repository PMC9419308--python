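"""Reading, validating and aggregating subject-level tables.

Three tables describe a cohort: an intake matrix (subjects x FFQ items or
food groups, g/day), a covariate table (demographics, anthropometry, energy
intake) and a biomarker table (the six measurements the ATP III rule needs).
Ingestion validates categorical levels against a fixed schema, aligns the
tables on subject identifier, aggregates FFQ items into the canonical 39 food
groups, and applies the implausible-energy exclusion rule
(< 800 or > 4200 kcal/day, strict comparisons — the boundary values are kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .groups import CANONICAL_GROUPS

__all__ = [
    "FoodGroupTable",
    "COVARIATE_LEVELS",
    "default_food_group_table",
    "load_tables",
    "aggregate_groups",
    "apply_exclusions",
]

#: allowed levels per categorical covariate, in reference-first order
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "education": ("under_diploma", "diploma", "graduated"),
    "occupation": ("employed", "household", "retired", "unemployed"),
    "marital": ("single", "married", "other"),
    "smoking": ("never", "ex", "current"),
    "activity": ("light", "moderate", "heavy"),
}

BIOMARKER_COLUMNS = ("WC", "SBP", "DBP", "TG", "FBS", "HDL")


@dataclass
class FoodGroupTable:
    """FFQ item -> food group assignment plus the canonical group order.

    The default table is an identity map over the 39 canonical groups (input
    already aggregated); studies with item-level data supply their own
    item-to-group map as a two-column CSV.
    """

    mapping: dict[str, str] = field(
        default_factory=lambda: {g: g for g in CANONICAL_GROUPS}
    )
    groups: tuple[str, ...] = CANONICAL_GROUPS

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValidationError("food-group names must be unique")
        bad = sorted(set(self.mapping.values()) - set(self.groups))
        if bad:
            raise ValidationError(f"mapping targets unknown group(s): {', '.join(bad)}")

    @classmethod
    def from_csv(cls, path: str | Path, groups: tuple[str, ...] = CANONICAL_GROUPS):
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValidationError("group map CSV needs two columns: item, group")
        mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        return cls(mapping=mapping, groups=groups)


def default_food_group_table() -> FoodGroupTable:
    return FoodGroupTable()


def _validate_covariates(cov: pd.DataFrame) -> None:
    for col, levels in COVARIATE_LEVELS.items():
        if col not in cov.columns:
            raise ValidationError(f"covariate table is missing column {col!r}")
        bad = sorted(set(cov[col].astype(str).unique()) - set(levels))
        if bad:
            raise ValidationError(
                f"covariate {col!r} has unknown value(s) {bad}; allowed: {list(levels)}"
            )
    if (cov["bmi"] <= 0).any():
        raise ValidationError("BMI must be positive")


def _validate_biomarkers(bio: pd.DataFrame) -> None:
    for col in BIOMARKER_COLUMNS:
        if col not in bio.columns:
            raise ValidationError(f"biomarker table is missing column {col!r}")
        if (bio[col] <= 0).any():
            raise ValidationError(f"biomarker {col!r} must be strictly positive")
    bad = bio.index[bio["SBP"] <= bio["DBP"]]
    if len(bad):
        raise ValidationError(
            f"SBP must exceed DBP; violated for subject(s): {', '.join(map(str, bad[:5]))}"
        )


def load_tables(
    paths: dict[str, str | Path],
    missing_policy: str = "exclude",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three cohort tables, aligned by subject id.

    ``paths`` must contain keys "intakes", "covariates" and "biomarkers".
    Subject identifiers must match exactly across tables; the returned row
    order is canonicalized by sorted identifier.  ``missing_policy``:
    "exclude" drops subjects with any missing intake value; "mean" imputes the
    column mean instead.
    """
    required = {"intakes", "covariates", "biomarkers"}
    missing_keys = required - set(paths)
    if missing_keys:
        raise ValidationError(f"missing table path(s): {', '.join(sorted(missing_keys))}")
    sep = lambda p: "\t" if str(p).endswith((".tsv", ".txt")) else ","
    tables = {
        key: pd.read_csv(paths[key], sep=sep(paths[key]), index_col=0) for key in sorted(required)
    }
    intakes, covariates, biomarkers = (
        tables["intakes"],
        tables["covariates"],
        tables["biomarkers"],
    )
    ids = [set(t.index) for t in (intakes, covariates, biomarkers)]
    if not ids[0] == ids[1] == ids[2]:
        union = ids[0] | ids[1] | ids[2]
        inter = ids[0] & ids[1] & ids[2]
        diff = sorted(map(str, union - inter))
        raise ValidationError(
            f"subject identifiers differ across tables; unmatched: {', '.join(diff[:10])}"
        )
    order = sorted(intakes.index)
    intakes = intakes.loc[order]
    covariates = covariates.loc[order]
    biomarkers = biomarkers.loc[order]
    if intakes.isna().any().any():
        if missing_policy == "exclude":
            keep = intakes.dropna().index
            intakes, covariates, biomarkers = (
                intakes.loc[keep],
                covariates.loc[keep],
                biomarkers.loc[keep],
            )
        elif missing_policy == "mean":
            intakes = intakes.fillna(intakes.mean())
        else:
            raise ValidationError(f"unknown missing policy {missing_policy!r}")
    if (intakes < 0).any().any():
        raise ValidationError("intakes must be non-negative g/day")
    _validate_covariates(covariates)
    _validate_biomarkers(biomarkers)
    return intakes, covariates, biomarkers


def aggregate_groups(item_intakes: pd.DataFrame, table: FoodGroupTable) -> pd.DataFrame:
    """Sum FFQ item intakes into food groups, columns in canonical order.

    Input already at group level (columns equal the group set) passes through
    unchanged apart from column ordering.
    """
    unmapped = [c for c in item_intakes.columns if c not in table.mapping]
    if unmapped:
        raise ValidationError(f"unmapped item column(s): {', '.join(map(str, unmapped))}")
    grouped = item_intakes.T.groupby(
        item_intakes.columns.map(table.mapping)
    ).sum().T
    present = [g for g in table.groups if g in grouped.columns]
    return grouped[present]


def apply_exclusions(
    intakes: pd.DataFrame,
    covariates: pd.DataFrame,
    biomarkers: pd.DataFrame,
    energy_low: float = 800.0,
    energy_high: float = 4200.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop subjects with implausible energy intake from all three tables.

    Strict comparisons: energy < ``energy_low`` or > ``energy_high`` excludes;
    the boundary values themselves are retained.  Returns the filtered tables
    plus an exclusion log (subject_id, energy, reason).
    """
    if "energy" not in covariates.columns:
        raise ValidationError("covariate table has no 'energy' column")
    energy = covariates["energy"].astype(float)
    low = energy < energy_low
    high = energy > energy_high
    excluded = energy[low | high]
    log = pd.DataFrame(
        {
            "energy": excluded,
            "reason": ["energy_too_low" if v < energy_low else "energy_too_high" for v in excluded],
        },
        index=excluded.index,
    )
    log.index.name = "subject_id"
    keep = ~(low | high)
    return (
        intakes.loc[keep],
        covariates.loc[keep],
        biomarkers.loc[keep],
        log,
    )
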