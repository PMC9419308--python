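"""Tertile logistic regression, trend tests and descriptive summaries.

For every (outcome, network, adjustment model) cell, a maximum-likelihood
logistic regression is fitted with tertile indicator variables (first tertile
as reference) plus the model's covariates; odds ratios are exp(coefficient)
with Wald 95% intervals exp(coef +/- 1.96 SE) and two-sided Wald p-values.
The trend test replaces the tertile indicators with a single continuous
exposure equal to each subject's tertile median score.

Adjustment models:

* model 1 — crude;
* model 2 — age, sex, education, occupation, marital status, smoking,
  menopause, physical activity;
* model 3 — age, sex, education, occupation, marital status, smoking,
  menopause, BMI, energy intake.

Categorical covariates enter as indicator sets with the first schema level as
reference; menopause is 0 for all men and is dropped (with a warning flag)
in an all-male stratum.  Separation or non-convergence produces a flagged
result, never a silent failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError
from .ingest import COVARIATE_LEVELS
from .scoring import NetworkScore, TERTILE_LABELS

__all__ = [
    "ModelSpec",
    "FitResult",
    "default_model_specs",
    "crude_odds_ratio",
    "fit_tertile_model",
    "p_trend",
    "run_all",
    "summarize_by_tertile",
    "summarize_by_sex",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    covariates: tuple[str, ...] = ()


def default_model_specs() -> tuple[ModelSpec, ModelSpec, ModelSpec]:
    return (
        ModelSpec(1, ()),
        ModelSpec(
            2,
            ("age", "sex", "education", "occupation", "marital", "smoking", "menopause", "activity"),
        ),
        ModelSpec(
            3,
            ("age", "sex", "education", "occupation", "marital", "smoking", "menopause", "bmi", "energy"),
        ),
    )


@dataclass
class FitResult:
    """Per-exposure-term OR estimates from one logistic fit."""

    terms: dict[str, dict]  # term -> {or, ci_low, ci_high, p, coef, se}
    converged: bool
    flags: tuple[str, ...] = ()


def _design(
    covariates: pd.DataFrame | None,
    spec: ModelSpec,
) -> tuple[pd.DataFrame, list[str]]:
    """Covariate design-matrix columns for one model spec (no exposure)."""
    flags: list[str] = []
    cols: dict[str, np.ndarray] = {}
    if covariates is None and spec.covariates:
        raise ValidationError(f"model {spec.model_id} needs a covariate table")
    for name in spec.covariates:
        if name in ("age", "bmi", "energy"):
            cols[name] = covariates[name].to_numpy(dtype=float)
        elif name == "menopause":
            v = covariates[name].to_numpy(dtype=float)
            if v.std() == 0:
                flags.append("menopause_dropped_constant")
                continue
            cols[name] = v
        elif name in COVARIATE_LEVELS:
            levels = COVARIATE_LEVELS[name]
            observed = covariates[name].astype(str)
            for level in levels[1:]:  # first level is the reference
                ind = (observed == level).to_numpy(dtype=float)
                if ind.std() == 0:
                    continue  # unobserved or universal level: no information
                cols[f"{name}[{level}]"] = ind
        else:
            raise ValidationError(f"unknown covariate {name!r} in model {spec.model_id}")
    index = covariates.index if covariates is not None else None
    return pd.DataFrame(cols, index=index), flags


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[sm.Logit, object, bool, list[str]]:
    flags: list[str] = []
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception as exc:  # perfect separation, singular hessian, ...
            flags.append(f"fit_failed:{type(exc).__name__}")
            return model, None, False, flags
    if not converged:
        flags.append("not_converged")
    bad = ~np.isfinite(res.bse)
    if bad.any():
        flags.append("non_finite_se")
    return model, res, converged, flags


def _wald_row(res, term: str) -> dict:
    coef = float(res.params[term])
    se = float(res.bse[term])
    return {
        "or": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - Z95 * se)),
        "ci_high": float(np.exp(coef + Z95 * se)),
        "p": float(2 * stats.norm.sf(abs(coef / se))) if se > 0 else np.nan,
        "coef": coef,
        "se": se,
    }


def crude_odds_ratio(outcome: pd.Series, exposure: pd.Series) -> dict:
    """Unadjusted logistic OR for a binary exposure (Wald CI and p).

    For a 2x2 table this is the maximum-likelihood estimate of the
    cross-product ratio.
    """
    y = outcome.astype(int).to_numpy()
    x = pd.DataFrame({"exposure": exposure.astype(float).to_numpy()}, index=exposure.index)
    _, res, converged, flags = _fit_logit(y, x)
    if res is None:
        return {"or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "coef": np.nan, "se": np.nan, "converged": False, "flags": tuple(flags)}
    row = _wald_row(res, "exposure")
    row.update({"converged": converged, "flags": tuple(flags)})
    return row


def fit_tertile_model(
    outcome: pd.Series,
    tertiles: pd.Series,
    covariates: pd.DataFrame | None,
    spec: ModelSpec,
) -> FitResult:
    """OR (Wald 95% CI, p) for T2 and T3 versus the T1 reference."""
    y = outcome.astype(int).to_numpy()
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("outcome must be binary")
    t = tertiles.astype(str)
    X_cov, flags = _design(covariates, spec)
    X = pd.DataFrame(
        {
            "T2": (t == "T2").astype(float).to_numpy(),
            "T3": (t == "T3").astype(float).to_numpy(),
        },
        index=tertiles.index,
    )
    if not X_cov.empty:
        X = pd.concat([X, X_cov], axis=1)
    _, res, converged, fit_flags = _fit_logit(y, X)
    flags += fit_flags
    if res is None:
        nanrow = {"or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "coef": np.nan, "se": np.nan}
        return FitResult({"T2": dict(nanrow), "T3": dict(nanrow)}, False, tuple(flags))
    return FitResult(
        {"T2": _wald_row(res, "T2"), "T3": _wald_row(res, "T3")},
        converged,
        tuple(flags),
    )


def p_trend(
    outcome: pd.Series,
    tertiles: pd.Series,
    medians: dict[str, float],
    covariates: pd.DataFrame | None,
    spec: ModelSpec,
) -> dict:
    """Median-coded trend test across tertiles.

    Each subject carries their tertile's median score as a single continuous
    exposure; the two-sided Wald p for its coefficient is the trend p-value.
    """
    med = [medians[lab] for lab in TERTILE_LABELS]
    if not (med[0] < med[1] < med[2]):
        raise ValidationError(f"tertile medians must be strictly increasing, got {med}")
    y = outcome.astype(int).to_numpy()
    X_cov, flags = _design(covariates, spec)
    X = pd.DataFrame(
        {"trend": tertiles.astype(str).map(medians).to_numpy(dtype=float)},
        index=tertiles.index,
    )
    if not X_cov.empty:
        X = pd.concat([X, X_cov], axis=1)
    _, res, converged, fit_flags = _fit_logit(y, X)
    flags += fit_flags
    if res is None:
        return {"p_trend": np.nan, "coef": np.nan, "converged": False, "flags": tuple(flags)}
    row = _wald_row(res, "trend")
    return {
        "p_trend": row["p"],
        "coef": row["coef"],
        "converged": converged,
        "flags": tuple(flags),
    }


def run_all(
    outcomes: pd.DataFrame,
    network_scores: dict[str, NetworkScore],
    covariates: pd.DataFrame | None,
    specs: tuple[ModelSpec, ...] | None = None,
) -> pd.DataFrame:
    """Full cross of outcomes x networks x models, long format.

    ``outcomes`` holds one binary column per outcome (MetS and components);
    ``network_scores`` maps network id to its :class:`NetworkScore`.
    """
    specs = specs or default_model_specs()
    rows = []
    for outcome_name in outcomes.columns:
        y = outcomes[outcome_name]
        for net_name, ns in network_scores.items():
            for spec in specs:
                fit = fit_tertile_model(y, ns.tertiles, covariates, spec)
                trend = p_trend(y, ns.tertiles, ns.medians, covariates, spec)
                for term in ("T2", "T3"):
                    r = fit.terms[term]
                    mask = ns.tertiles == term
                    rows.append(
                        {
                            "outcome": outcome_name,
                            "network": net_name,
                            "model": spec.model_id,
                            "tertile": term,
                            "or": r["or"],
                            "ci_low": r["ci_low"],
                            "ci_high": r["ci_high"],
                            "p": r["p"],
                            "p_trend": trend["p_trend"],
                            "n": int(mask.sum()),
                            "events": int(y[mask].sum()),
                            "converged": fit.converged and trend["converged"],
                            "flags": ";".join(fit.flags + tuple(trend["flags"])),
                        }
                    )
    return pd.DataFrame(rows)


def summarize_by_tertile(
    values: pd.DataFrame,
    tertiles: pd.Series,
) -> pd.DataFrame:
    """Mean +/- SD of each continuous variable per tertile with one-way ANOVA p."""
    rows = []
    for col in values.columns:
        groups = [values.loc[tertiles == lab, col].to_numpy(dtype=float) for lab in TERTILE_LABELS]
        f, p = stats.f_oneway(*groups)
        row = {"variable": col, "F": float(f), "p": float(p)}
        for lab, g in zip(TERTILE_LABELS, groups):
            row[f"{lab}_mean"] = float(np.mean(g))
            row[f"{lab}_sd"] = float(np.std(g, ddof=1))
            row[f"{lab}_n"] = int(len(g))
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def summarize_by_sex(covariates: pd.DataFrame, extra_binary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Categorical frequencies by sex with chi-square p (no continuity correction).

    ``extra_binary`` may add outcome flags (MetS, components) to the summary.
    A warning flag is recorded when any expected cell count drops below 5.
    """
    sex = covariates["sex"].astype(str)
    frames = {c: covariates[c].astype(str) for c in covariates.columns if c not in ("age", "bmi", "energy", "sex")}
    if extra_binary is not None:
        for c in extra_binary.columns:
            frames[c] = extra_binary[c].map({True: "yes", False: "no"}).astype(str)
    rows = []
    for name, series in frames.items():
        table = pd.crosstab(series, sex)
        chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
        for level in table.index:
            row = {"variable": name, "level": level, "chi2": float(chi2), "p": float(p),
                   "sparse_cells": bool((expected < 5).any())}
            for s in table.columns:
                count = int(table.loc[level, s])
                row[f"{s}_n"] = count
                row[f"{s}_pct"] = 100.0 * count / table.loc[level].sum() if table.loc[level].sum() else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
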