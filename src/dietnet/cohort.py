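"""Synthetic cohorts with planted dietary-network structure and planted effects.

Every downstream stage of the pipeline is validated against cohorts generated
here, because the generator knows the ground truth: which food-group pairs are
conditionally dependent (a planted block-sparse precision matrix), what the
marginal intake distributions look like, and how strongly adherence to each
planted network raises the odds of metabolic syndrome.

Intakes are drawn on a latent multivariate-Gaussian scale from the planted
precision matrix and affine-mapped to the configured per-group mean/SD in
grams/day.  Optional truncation at zero mimics the non-negativity of real
intakes but biases partial correlations, so it is off by default in recovery
settings.  Outcomes are generated by drawing the MetS flag from a logistic
model in the planted network-score tertiles (plus optional covariate effects),
then drawing a consistent set of ATP III component states and continuous
biomarker values on the correct side of each diagnostic cut.

Two planted structures ship with the package:

* :func:`figure_structure` — three blocks (healthy / unhealthy / saturated
  fats) with the partial-correlation magnitudes of a published dietary-network
  figure (values above 0.30 clamped to 0.30, without which the implied
  precision matrix is not positive definite);
* :func:`recovery_structure` — the same block topologies with edge values
  restricted to {0.06, 0.15, 0.30} and a connected 0.15 backbone per block,
  designed so that structure-recovery benchmarks have a well-defined target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NotPositiveDefiniteError, ValidationError
from .groups import CANONICAL_GROUPS, DEFAULT_MARGINALS
from .mets import COMPONENTS, MetSCutoffs
from .scoring import assign_tertiles, compute_score, pca_loadings

__all__ = [
    "Block",
    "PlantedStructure",
    "NetworkEffect",
    "OutcomeModel",
    "CovariateModel",
    "CohortConfig",
    "SyntheticCohort",
    "figure_structure",
    "recovery_structure",
    "build_planted_precision",
    "simulate_intakes",
    "simulate_covariates",
    "simulate_outcomes",
    "simulate_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# planted structure


@dataclass(frozen=True)
class Block:
    """A named set of food groups with target within-block partial correlations."""

    name: str
    edges: tuple[tuple[str, str, float], ...]  # (group_a, group_b, rho)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted({n for a, b, _ in self.edges for n in (a, b)}))


@dataclass(frozen=True)
class PlantedStructure:
    blocks: tuple[Block, ...]
    background: float = 0.0  # partial correlation for all non-block pairs

    def __post_init__(self) -> None:
        if not -1 < self.background < 1:
            raise ValidationError("background partial correlation must lie in (-1, 1)")
        seen: set[str] = set()
        for block in self.blocks:
            for a, b, rho in block.edges:
                if not -1 < rho < 1:
                    raise ValidationError(
                        f"block {block.name!r}: partial correlation {rho} for "
                        f"({a}, {b}) outside (-1, 1)"
                    )
            overlap = seen & set(block.nodes)
            if overlap:
                raise ValidationError(
                    f"block {block.name!r} shares nodes with another block: {sorted(overlap)}"
                )
            seen |= set(block.nodes)

    def block_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks)

    def edge_set(self) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for block in self.blocks:
            for a, b, rho in block.edges:
                key = (a, b) if a <= b else (b, a)
                out[key] = rho
        return out


_HEALTHY_FIG = (
    ("cooked_vegetables", "mushroom", 0.23),
    ("cooked_vegetables", "legumes", 0.20),
    ("cooked_vegetables", "cooked_potatoes", 0.14),
    ("cooked_vegetables", "grains", 0.03),
    ("grains", "mushroom", 0.11),
    ("grains", "legumes", 0.14),
    ("cooked_vegetables", "fresh_fruits", -0.10),
    ("cooked_vegetables", "green_leafy_vegetables", 0.19),
    ("cooked_vegetables", "garlic", 0.11),
    ("cooked_vegetables", "low_fat_dairy", 0.13),
    ("cooked_vegetables", "cabbage", 0.16),
    ("cooked_vegetables", "other_vegetables", 0.16),
    ("dried_fruits", "nuts", 0.16),
    ("nuts", "green_leafy_vegetables", -0.05),
    ("nuts", "fresh_fruits", 0.15),
    ("fresh_fruits", "green_leafy_vegetables", 0.30),
    ("green_leafy_vegetables", "low_fat_dairy", 0.07),
)

# values printed as 0.97/0.99/0.9 in the source figure are clamped to 0.30:
# the unit-diagonal precision implied by the printed values is not positive
# definite, so they cannot be planted as-is.
_UNHEALTHY_FIG = (
    ("processed_meat", "coffee", 0.06),
    ("processed_meat", "vegetable_oils_olive", 0.30),
    ("vegetable_oils_olive", "coffee", -0.05),
    ("vegetable_oils_olive", "carbonated_drinks", -0.16),
    ("vegetable_oils_olive", "fish", 0.30),
    ("processed_meat", "sauce", 0.15),
    ("processed_meat", "carbonated_drinks", 0.20),
    ("processed_meat", "cookies_cakes", 0.03),
    ("carbonated_drinks", "french_fries", 0.03),
    ("carbonated_drinks", "cookies_cakes", 0.30),
    ("carbonated_drinks", "high_fat_dairy", 0.12),
    ("cookies_cakes", "sauce", 0.01),
    ("cookies_cakes", "chips_puffs", 0.06),
    ("cookies_cakes", "high_fat_dairy", 0.11),
    ("french_fries", "chips_puffs", 0.08),
    ("french_fries", "high_fat_dairy", 0.07),
    ("fruit_juice", "canned_fruits", 0.25),
    ("fruit_juice", "high_fat_dairy", 0.14),
    ("fruit_juice", "cookies_cakes", 0.18),
)

_SATFAT_FIG = (
    ("butter", "margarine", 0.06),
    ("butter", "animal_fat", 0.03),
)


def figure_structure() -> PlantedStructure:
    """Three planted blocks with figure-like partial-correlation magnitudes."""
    return PlantedStructure(
        blocks=(
            Block("healthy", _HEALTHY_FIG),
            Block("unhealthy", _UNHEALTHY_FIG),
            Block("saturated_fats", _SATFAT_FIG),
        )
    )


_HEALTHY_REC = (
    ("cooked_vegetables", "mushroom", 0.15),
    ("cooked_vegetables", "legumes", 0.15),
    ("cooked_vegetables", "cooked_potatoes", 0.15),
    ("cooked_vegetables", "grains", 0.06),
    ("grains", "mushroom", 0.15),
    ("grains", "legumes", 0.15),
    ("cooked_vegetables", "fresh_fruits", -0.15),
    ("cooked_vegetables", "green_leafy_vegetables", 0.15),
    ("cooked_vegetables", "garlic", 0.15),
    ("cooked_vegetables", "low_fat_dairy", 0.15),
    ("cooked_vegetables", "cabbage", 0.15),
    ("cooked_vegetables", "other_vegetables", 0.15),
    ("dried_fruits", "nuts", 0.15),
    ("nuts", "fresh_fruits", 0.15),
    ("fresh_fruits", "green_leafy_vegetables", 0.30),
)

_UNHEALTHY_REC = (
    ("processed_meat", "coffee", 0.06),
    ("processed_meat", "vegetable_oils_olive", 0.30),
    ("vegetable_oils_olive", "carbonated_drinks", -0.15),
    ("vegetable_oils_olive", "fish", 0.30),
    ("processed_meat", "sauce", 0.15),
    ("processed_meat", "carbonated_drinks", 0.15),
    ("carbonated_drinks", "french_fries", 0.15),
    ("carbonated_drinks", "cookies_cakes", 0.30),
    ("carbonated_drinks", "high_fat_dairy", 0.15),
    ("cookies_cakes", "high_fat_dairy", 0.15),
    ("french_fries", "chips_puffs", 0.15),
    ("fruit_juice", "canned_fruits", 0.30),
    ("fruit_juice", "high_fat_dairy", 0.15),
    ("fruit_juice", "cookies_cakes", 0.15),
)

_SATFAT_REC = (
    ("butter", "margarine", 0.15),
    ("butter", "animal_fat", 0.15),
    ("margarine", "animal_fat", 0.06),
)


def recovery_structure() -> PlantedStructure:
    """Planted blocks with |rho| in {0.06, 0.15, 0.30} and a 0.15 backbone.

    Same topologies as :func:`figure_structure` but every block stays
    connected through edges of at least 0.15, so the three-network count is a
    property of the structure rather than of marginal edge detectability.
    """
    return PlantedStructure(
        blocks=(
            Block("healthy", _HEALTHY_REC),
            Block("unhealthy", _UNHEALTHY_REC),
            Block("saturated_fats", _SATFAT_REC),
        )
    )


def build_planted_precision(
    structure: PlantedStructure,
    groups: tuple[str, ...] = CANONICAL_GROUPS,
    boost: bool = False,
) -> pd.DataFrame:
    """Unit-diagonal precision matrix realizing the planted partial correlations.

    With unit diagonal, the off-diagonal entry for a planted edge is simply
    the negated partial correlation.  The matrix is verified to be positive
    definite; an infeasible request is rejected naming the offending block
    unless ``boost=True``, in which case the diagonal is inflated until SPD —
    which shrinks every planted edge magnitude by the same factor, so callers
    must re-check realized partial correlations.
    """
    groups = tuple(groups)
    idx = {g: i for i, g in enumerate(groups)}
    for block in structure.blocks:
        unknown = [n for n in block.nodes if n not in idx]
        if unknown:
            raise ValidationError(
                f"block {block.name!r} references unknown food group(s): {', '.join(unknown)}"
            )
    p = len(groups)
    omega = np.full((p, p), -structure.background)
    np.fill_diagonal(omega, 1.0)
    in_block = np.zeros((p, p), dtype=bool)
    for block in structure.blocks:
        members = [idx[n] for n in block.nodes]
        for a in members:
            for b in members:
                if a != b:
                    in_block[a, b] = True
                    omega[a, b] = 0.0  # within-block pairs default to 0
        for a, b, rho in block.edges:
            omega[idx[a], idx[b]] = omega[idx[b], idx[a]] = -rho
    if structure.background == 0.0:
        omega[~in_block & ~np.eye(p, dtype=bool)] = 0.0
    eigmin = float(np.linalg.eigvalsh(omega).min())
    if eigmin <= 1e-10:
        if not boost:
            offender = _offending_block(structure, groups)
            raise NotPositiveDefiniteError(
                f"requested partial correlations are infeasible (min eigenvalue "
                f"{eigmin:.3g}); offending block: {offender}"
            )
        delta = -eigmin + 1e-6
        omega = (omega + delta * np.eye(p)) / (1.0 + delta)
    return pd.DataFrame(omega, index=groups, columns=groups)


def _offending_block(structure: PlantedStructure, groups: tuple[str, ...]) -> str:
    for block in structure.blocks:
        sub = PlantedStructure(blocks=(block,), background=0.0)
        nodes = block.nodes
        idx = {g: i for i, g in enumerate(nodes)}
        k = np.eye(len(nodes))
        for a, b, rho in block.edges:
            k[idx[a], idx[b]] = k[idx[b], idx[a]] = -rho
        if np.linalg.eigvalsh(k).min() <= 1e-10:
            return block.name
    return "(interaction with background)"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class NetworkEffect:
    """Planted exposure-outcome effect for one named network (tertile coding)."""

    logor_t2: float = 0.0
    logor_t3: float = 0.0


@dataclass
class OutcomeModel:
    """Logistic model generating the MetS flag.

    ``intercept`` is on the log-odds scale for a reference (tertile-1,
    covariate-reference) subject; ``network_effects`` maps planted block names
    to tertile log-odds ratios; ``covariate_effects`` maps a subset of
    {age, bmi, energy, female} to per-unit log-odds effects on centered
    values (age - 45 years, bmi - 28 kg/m2, energy - 2200 kcal/day).
    """

    intercept: float = -1.1
    network_effects: dict[str, NetworkEffect] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class CovariateModel:
    """Sampling distributions for the covariate table."""

    p_female: float = 0.69
    age_range: tuple[float, float] = (20.0, 59.0)
    education_p: tuple[float, ...] = (0.306, 0.328, 0.366)  # under_diploma/diploma/graduated
    occupation_p: tuple[float, ...] = (0.259, 0.560, 0.150, 0.031)
    marital_p: tuple[float, ...] = (0.108, 0.810, 0.082)  # single/married/other
    smoking_p: tuple[float, ...] = (0.906, 0.042, 0.052)  # never/ex/current
    activity_p: tuple[float, ...] = (0.60, 0.35, 0.05)  # light/moderate/heavy
    menopause_p: float = 0.476  # among women; structurally 0 for men
    bmi_mean: float = 27.9
    bmi_sd: float = 5.2
    energy_mean: float = 2200.0
    energy_sd: float = 550.0

    def __post_init__(self) -> None:
        for name in ("education_p", "occupation_p", "marital_p", "smoking_p", "activity_p"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1 (got {sum(probs)})")
        if not 0 <= self.p_female <= 1 or not 0 <= self.menopause_p <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class BiomarkerBands:
    """Ranges for drawing continuous biomarkers given a binary component state.

    Each pair is (low, high) of a uniform band strictly on the corresponding
    side of the ATP III cut; only the binary state carries the planted effect.
    """

    wc_margin: float = 25.0  # width above the cut when positive
    wc_floor: float = 65.0
    sbp_pos: tuple[float, float] = (131.0, 175.0)
    dbp_pos: tuple[float, float] = (81.0, 105.0)
    tg_pos: tuple[float, float] = (151.0, 400.0)
    tg_neg: tuple[float, float] = (50.0, 149.5)
    fbs_pos: tuple[float, float] = (111.0, 250.0)
    fbs_neg: tuple[float, float] = (70.0, 109.5)
    hdl_floor: float = 25.0
    hdl_ceiling: float = 80.0
    gap: float = 0.5  # keep draws strictly away from every cut


@dataclass
class CohortConfig:
    n_subjects: int = 850
    seed: int = 0
    marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    truncate_at_zero: bool = False
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    bands: BiomarkerBands = field(default_factory=BiomarkerBands)
    cutoffs: MetSCutoffs = field(default_factory=MetSCutoffs)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be positive")
        for g, (mu, sd) in self.marginals.items():
            if sd <= 0:
                raise ValidationError(f"marginal SD for {g!r} must be > 0")


@dataclass
class SyntheticCohort:
    intakes: pd.DataFrame
    covariates: pd.DataFrame
    biomarkers: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        if not (
            self.intakes.index.equals(self.covariates.index)
            and self.intakes.index.equals(self.biomarkers.index)
        ):
            raise ValidationError("cohort tables must share identical subject indices")


# ---------------------------------------------------------------------------
# simulation


def _subject_index(n: int) -> pd.Index:
    return pd.Index([f"S{i:05d}" for i in range(1, n + 1)], name="subject_id")


def simulate_intakes(
    config: CohortConfig,
    precision: pd.DataFrame,
) -> pd.DataFrame:
    """Draw intakes from the planted Gaussian model, mapped to g/day marginals.

    Rows are i.i.d. multivariate-Gaussian draws with the given precision; each
    latent column is rescaled to unit variance and affine-mapped to the
    configured (mean, SD), which leaves all partial correlations untouched.
    """
    groups = tuple(precision.columns)
    missing = [g for g in groups if g not in config.marginals]
    if missing:
        raise ValidationError(f"no marginal configured for group(s): {', '.join(missing)}")
    omega = precision.to_numpy(dtype=float)
    p = omega.shape[0]
    if omega.shape != (p, p) or p != len(groups):
        raise ValidationError(
            f"precision matrix is {omega.shape}, expected ({len(groups)}, {len(groups)})"
        )
    eig = np.linalg.eigvalsh(omega)
    if eig.min() <= 0:
        raise NotPositiveDefiniteError("precision matrix must be SPD to simulate intakes")
    cov = np.linalg.inv(omega)
    scale = 1.0 / np.sqrt(np.diag(cov))
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng([config.seed, 0])
    latent = rng.standard_normal((config.n_subjects, p)) @ chol.T
    latent *= scale  # unit marginal variance
    means = np.array([config.marginals[g][0] for g in groups])
    sds = np.array([config.marginals[g][1] for g in groups])
    values = latent * sds + means
    if config.truncate_at_zero:
        np.clip(values, 0.0, None, out=values)
    return pd.DataFrame(values, index=_subject_index(config.n_subjects), columns=list(groups))


_EDUCATION = ("under_diploma", "diploma", "graduated")
_OCCUPATION = ("employed", "household", "retired", "unemployed")
_MARITAL = ("single", "married", "other")
_SMOKING = ("never", "ex", "current")
_ACTIVITY = ("light", "moderate", "heavy")


def simulate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Draw the covariate table (demographics, anthropometry, energy intake).

    Menopause is structurally zero for men.  Covariates are drawn
    independently of diet; real cohorts confound the two, which is exactly why
    the adjusted models exist, but the null coupling keeps planted effects
    interpretable.
    """
    cm = config.covariates
    n = config.n_subjects
    rng = np.random.default_rng([config.seed, 1])
    female = rng.random(n) < cm.p_female
    age = rng.uniform(*cm.age_range, size=n)
    education = rng.choice(_EDUCATION, size=n, p=cm.education_p)
    occupation = rng.choice(_OCCUPATION, size=n, p=cm.occupation_p)
    marital = rng.choice(_MARITAL, size=n, p=cm.marital_p)
    smoking = rng.choice(_SMOKING, size=n, p=cm.smoking_p)
    activity = rng.choice(_ACTIVITY, size=n, p=cm.activity_p)
    menopause = np.where(female, rng.random(n) < cm.menopause_p, False)
    bmi = np.maximum(rng.normal(cm.bmi_mean, cm.bmi_sd, size=n), 15.0)
    energy = np.maximum(rng.normal(cm.energy_mean, cm.energy_sd, size=n), 500.0)
    return pd.DataFrame(
        {
            "age": age,
            "sex": np.where(female, "female", "male"),
            "education": education,
            "occupation": occupation,
            "marital": marital,
            "smoking": smoking,
            "menopause": menopause.astype(int),
            "activity": activity,
            "bmi": bmi,
            "energy": energy,
        },
        index=_subject_index(n),
    )


def _true_network_tertiles(
    intakes: pd.DataFrame,
    structure: PlantedStructure,
    names: list[str],
) -> dict[str, pd.Series]:
    """Tertiles of the loading-weighted score of each planted network."""
    from .ggm import standardize

    z, _ = standardize(intakes)
    tertiles: dict[str, pd.Series] = {}
    for block in structure.blocks:
        if block.name not in names:
            continue
        loadings = pca_loadings(z[list(block.nodes)])
        score = compute_score(z, loadings)
        tertiles[block.name] = assign_tertiles(score).tertiles
    return tertiles


def simulate_outcomes(
    intakes: pd.DataFrame,
    covariates: pd.DataFrame,
    config: CohortConfig,
    structure: PlantedStructure,
) -> tuple[pd.DataFrame, dict]:
    """Generate biomarkers whose implied MetS status follows the planted model.

    The MetS flag is Bernoulli with log-odds linear in the planted network
    tertiles and configured covariate effects; the component count and states
    are drawn consistently with the flag, and continuous biomarker values are
    placed uniformly within a band strictly on the correct side of each ATP III
    cut.  Returns the biomarker table and the per-subject truth record.
    """
    if not intakes.index.equals(covariates.index):
        raise ValidationError("intake and covariate tables are not aligned")
    om = config.outcome_model
    available = [b.name for b in structure.blocks]
    unknown = [name for name in om.network_effects if name not in available]
    if unknown:
        raise ValidationError(
            f"unknown network name(s) in outcome model: {', '.join(unknown)}; "
            f"available: {', '.join(available)}"
        )
    n = len(intakes)
    rng = np.random.default_rng([config.seed, 2])
    tertiles = _true_network_tertiles(intakes, structure, list(om.network_effects))
    lp = np.full(n, om.intercept, dtype=float)
    for name, eff in om.network_effects.items():
        t = tertiles[name].to_numpy()
        lp += np.where(t == "T2", eff.logor_t2, 0.0)
        lp += np.where(t == "T3", eff.logor_t3, 0.0)
    centers = {"age": 45.0, "bmi": 28.0, "energy": 2200.0}
    for cov_name, beta in om.covariate_effects.items():
        if cov_name == "female":
            lp += beta * (covariates["sex"].to_numpy() == "female")
        elif cov_name in centers:
            lp += beta * (covariates[cov_name].to_numpy(dtype=float) - centers[cov_name])
        else:
            raise ValidationError(
                f"unsupported covariate effect {cov_name!r}; "
                f"supported: female, {', '.join(centers)}"
            )
    prob = 1.0 / (1.0 + np.exp(-lp))
    mets = rng.random(n) < prob
    counts = np.where(
        mets,
        rng.choice([3, 4, 5], size=n, p=[0.6, 0.3, 0.1]),
        rng.choice([0, 1, 2], size=n, p=[0.35, 0.40, 0.25]),
    )
    flags = np.zeros((n, 5), dtype=bool)
    for i in range(n):
        chosen = rng.choice(5, size=counts[i], replace=False)
        flags[i, chosen] = True
    female = covariates["sex"].to_numpy() == "female"
    biomarkers = _draw_biomarkers(flags, female, config, rng)
    truth = {
        "structure": structure,
        "outcome_model": om,
        "network_tertiles": tertiles,
        "mets": pd.Series(mets, index=intakes.index, name="mets_true"),
        "component_flags": pd.DataFrame(flags, index=intakes.index, columns=list(COMPONENTS)),
    }
    return biomarkers, truth


def _draw_biomarkers(
    flags: np.ndarray,
    female: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    bands, cuts = config.bands, config.cutoffs
    n = flags.shape[0]
    obesity, hypertension, tg_high, glu_high, hdl_low = flags.T
    wc_cut = np.where(female, cuts.wc_female, cuts.wc_male)
    wc = np.where(
        obesity,
        rng.uniform(wc_cut + bands.gap, wc_cut + bands.wc_margin),
        rng.uniform(bands.wc_floor, wc_cut - bands.gap),
    )
    # blood pressure: positive state elevates SBP, DBP or both; negative state
    # stays strictly under both cuts, with SBP > DBP throughout.
    dbp_lo = rng.uniform(55.0, cuts.dbp - bands.gap, size=n)
    sbp_lo = np.minimum(dbp_lo + rng.uniform(15.0, 50.0, size=n), cuts.sbp - bands.gap)
    mode = rng.integers(0, 3, size=n)  # 0: SBP high, 1: DBP high, 2: both
    sbp_hi = rng.uniform(*bands.sbp_pos, size=n)
    dbp_hi = rng.uniform(*bands.dbp_pos, size=n)
    sbp = np.where(hypertension, np.where(mode == 1, np.maximum(dbp_hi + 10.0, sbp_lo), sbp_hi), sbp_lo)
    dbp = np.where(hypertension, np.where(mode == 0, dbp_lo, dbp_hi), dbp_lo)
    sbp = np.maximum(sbp, dbp + 5.0)
    tg = np.where(tg_high, rng.uniform(*bands.tg_pos, size=n), rng.uniform(*bands.tg_neg, size=n))
    fbs = np.where(glu_high, rng.uniform(*bands.fbs_pos, size=n), rng.uniform(*bands.fbs_neg, size=n))
    hdl_cut = np.where(female, cuts.hdl_female, cuts.hdl_male)
    hdl = np.where(
        hdl_low,
        rng.uniform(bands.hdl_floor, hdl_cut - bands.gap),
        rng.uniform(hdl_cut + bands.gap, bands.hdl_ceiling),
    )
    return pd.DataFrame(
        {"WC": wc, "SBP": sbp, "DBP": dbp, "TG": tg, "FBS": fbs, "HDL": hdl},
    )


def simulate_cohort(
    config: CohortConfig,
    structure: PlantedStructure | None = None,
    groups: tuple[str, ...] = CANONICAL_GROUPS,
) -> SyntheticCohort:
    """End-to-end cohort generation: intakes, covariates, biomarkers, truth."""
    structure = structure or recovery_structure()
    precision = build_planted_precision(structure, groups)
    intakes = simulate_intakes(config, precision)
    covariates = simulate_covariates(config)
    biomarkers, truth = simulate_outcomes(intakes, covariates, config, structure)
    biomarkers.index = intakes.index
    truth["precision"] = precision
    return SyntheticCohort(intakes, covariates, biomarkers, truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write intakes.csv, covariates.csv, biomarkers.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in (
        ("intakes", cohort.intakes),
        ("covariates", cohort.covariates),
        ("biomarkers", cohort.biomarkers),
    ):
        path = outdir / f"{name}.csv"
        table.to_csv(path)
        paths[name] = path
    structure: PlantedStructure = cohort.truth["structure"]
    om: OutcomeModel = cohort.truth["outcome_model"]
    truth_json = {
        "blocks": [
            {"name": b.name, "edges": [[a, c, rho] for a, c, rho in b.edges]}
            for b in structure.blocks
        ],
        "background": structure.background,
        "outcome_model": {
            "intercept": om.intercept,
            "network_effects": {
                name: {"logor_t2": e.logor_t2, "logor_t3": e.logor_t3}
                for name, e in om.network_effects.items()
            },
            "covariate_effects": dict(om.covariate_effects),
        },
    }
    path = outdir / "truth.json"
    path.write_text(json.dumps(truth_json, indent=2))
    paths["truth"] = path
    return paths
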