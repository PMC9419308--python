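"""Metabolic-syndrome classification under the NCEP-ATP III rule.

Five binary risk components are derived from the biomarker table with strict
comparisons against sex-specific cutoffs:

* central obesity      — waist circumference > 102 cm (men) / > 88 cm (women)
* hypertension         — SBP > 130 mmHg OR DBP > 80 mmHg
* hypertriglyceridemia — triglyceride > 150 mg/dl
* hyperglycemia        — fasting glucose > 110 mg/dl
* low HDL              — HDL < 40 mg/dl (men) / < 50 mg/dl (women)

Metabolic syndrome is present when three or more components are.  All cutoffs
live in :class:`MetSCutoffs` so JNC/IDF-style variants are a single edit; the
blood-pressure rule is configurable to AND for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .errors import ValidationError

__all__ = ["MetSCutoffs", "classify_components", "classify_mets", "classify"]

COMPONENTS = (
    "central_obesity",
    "hypertension",
    "hypertriglyceridemia",
    "hyperglycemia",
    "low_hdl",
)

BIOMARKER_COLUMNS = ("WC", "SBP", "DBP", "TG", "FBS", "HDL")


@dataclass(frozen=True)
class MetSCutoffs:
    wc_male: float = 102.0  # cm
    wc_female: float = 88.0
    sbp: float = 130.0  # mmHg
    dbp: float = 80.0
    tg: float = 150.0  # mg/dl
    fbg: float = 110.0  # mg/dl
    hdl_male: float = 40.0  # mg/dl
    hdl_female: float = 50.0
    threshold: int = 3  # components required for MetS
    bp_rule: str = "or"  # "or": either pressure elevated qualifies

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name in ("threshold", "bp_rule"):
                continue
            if value <= 0:
                raise ValidationError(f"cutoff {name} must be positive")
        if not 1 <= self.threshold <= 5:
            raise ValidationError("component threshold must be in 1..5")
        if self.bp_rule not in ("or", "and"):
            raise ValidationError("bp_rule must be 'or' or 'and'")


def classify_components(
    biomarkers: pd.DataFrame,
    sex: pd.Series,
    cutoffs: MetSCutoffs | None = None,
) -> pd.DataFrame:
    """Binary ATP III component flags per subject (strict comparisons)."""
    cutoffs = cutoffs or MetSCutoffs()
    for col in BIOMARKER_COLUMNS:
        if col not in biomarkers.columns:
            raise ValidationError(f"missing biomarker column: {col}")
        if biomarkers[col].isna().any():
            raise ValidationError(f"missing values in biomarker column: {col}")
    if sex.isna().any():
        raise ValidationError("missing sex values")
    female = sex.astype(str).str.lower().eq("female")
    wc_cut = female.map({True: cutoffs.wc_female, False: cutoffs.wc_male})
    hdl_cut = female.map({True: cutoffs.hdl_female, False: cutoffs.hdl_male})
    sbp_high = biomarkers["SBP"] > cutoffs.sbp
    dbp_high = biomarkers["DBP"] > cutoffs.dbp
    hypertension = (sbp_high | dbp_high) if cutoffs.bp_rule == "or" else (sbp_high & dbp_high)
    flags = pd.DataFrame(
        {
            "central_obesity": biomarkers["WC"] > wc_cut,
            "hypertension": hypertension,
            "hypertriglyceridemia": biomarkers["TG"] > cutoffs.tg,
            "hyperglycemia": biomarkers["FBS"] > cutoffs.fbg,
            "low_hdl": biomarkers["HDL"] < hdl_cut,
        },
        index=biomarkers.index,
    )
    return flags.astype(bool)


def classify_mets(flags: pd.DataFrame, threshold: int = 3) -> pd.DataFrame:
    """MetS flag and component count from the five component flags."""
    missing = [c for c in COMPONENTS if c not in flags.columns]
    if missing:
        raise ValidationError(f"missing component flag(s): {', '.join(missing)}")
    count = flags[list(COMPONENTS)].astype(int).sum(axis=1)
    return pd.DataFrame(
        {"component_count": count, "mets": count >= threshold}, index=flags.index
    )


def classify(
    biomarkers: pd.DataFrame,
    sex: pd.Series,
    cutoffs: MetSCutoffs | None = None,
) -> pd.DataFrame:
    """Component flags, component count and MetS flag in one table."""
    cutoffs = cutoffs or MetSCutoffs()
    flags = classify_components(biomarkers, sex, cutoffs)
    summary = classify_mets(flags, cutoffs.threshold)
    return pd.concat([flags, summary], axis=1)
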