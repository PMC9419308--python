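"""End-to-end orchestration: config, staged execution, exports, manifest.

A run either reads the three cohort tables from disk or simulates a synthetic
cohort, then executes the full chain — standardize, select the glasso penalty,
estimate the precision matrix, convert to partial correlations, extract
dietary networks, detect link communities and central groups, build
PCA-weighted network scores with tertiles, classify ATP III components and
metabolic syndrome, and fit the tertile logistic models with trend tests —
writing every table plus a manifest that records all tunable conventions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .association import default_model_specs, run_all, summarize_by_sex, summarize_by_tertile
from .cohort import (
    CohortConfig,
    NetworkEffect,
    OutcomeModel,
    PlantedStructure,
    figure_structure,
    recovery_structure,
    simulate_cohort,
)
from .errors import ValidationError
from .ggm import (
    DietaryNetworkSet,
    GGMConfig,
    estimate_precision,
    extract_networks,
    precision_to_partial,
    select_lambda,
    standardize,
)
from .ingest import apply_exclusions, load_tables
from .linkcomm import centrality_report, cluster_edges, cut_at_max_density
from .mets import MetSCutoffs, classify
from .scoring import assign_tertiles, compute_score, pca_loadings

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]

_STRUCTURES = {"recovery": recovery_structure, "figure": figure_structure}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    Exactly one of ``input_paths`` (dict with intakes/covariates/biomarkers
    CSVs) or ``simulate`` (a :class:`CohortConfig`) must be given.
    """

    outdir: str | Path = "results/run"
    seed: int = 0
    input_paths: dict | None = None
    simulate: CohortConfig | None = None
    structure: str | PlantedStructure = "recovery"
    ggm: GGMConfig = field(default_factory=GGMConfig)
    cutoffs: MetSCutoffs = field(default_factory=MetSCutoffs)
    weighted_communities: bool = False
    apply_energy_exclusions: bool = True

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulate is None):
            raise ValidationError(
                "exactly one of 'input_paths' and 'simulate' must be configured"
            )

    def planted_structure(self) -> PlantedStructure:
        if isinstance(self.structure, PlantedStructure):
            return self.structure
        try:
            return _STRUCTURES[self.structure]()
        except KeyError:
            raise ValidationError(
                f"unknown structure preset {self.structure!r}; options: {sorted(_STRUCTURES)}"
            ) from None


@dataclass
class PipelineResult:
    networks: DietaryNetworkSet
    lam: float
    partial: pd.DataFrame
    communities: dict[str, object]
    centrality: pd.DataFrame
    scores: pd.DataFrame
    loadings: pd.DataFrame
    mets: pd.DataFrame
    associations: pd.DataFrame
    descriptives_tertile: dict[str, pd.DataFrame]
    descriptives_sex: pd.DataFrame
    manifest: dict
    outdir: Path


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(
        outdir=raw.pop("outdir", "results/run"),
        seed=int(raw.pop("seed", 0)),
        input_paths=raw.pop("input_paths", None),
        simulate=None if sim is None else _cohort_config(sim),
        structure=raw.pop("structure", "recovery"),
        ggm=GGMConfig(**raw.pop("ggm", {})),
        cutoffs=MetSCutoffs(**raw.pop("cutoffs", {})),
        weighted_communities=bool(raw.pop("weighted_communities", False)),
        apply_energy_exclusions=bool(raw.pop("apply_energy_exclusions", True)),
    )
    if raw:
        raise ValidationError(f"unknown config key(s): {', '.join(sorted(raw))}")
    return cfg


def _cohort_config(block: dict) -> CohortConfig:
    block = dict(block)
    om = block.pop("outcome_model", None)
    outcome = OutcomeModel()
    if om:
        outcome = OutcomeModel(
            intercept=float(om.get("intercept", -1.1)),
            network_effects={
                k: NetworkEffect(**v) for k, v in om.get("network_effects", {}).items()
            },
            covariate_effects=dict(om.get("covariate_effects", {})),
        )
    return CohortConfig(
        n_subjects=int(block.pop("n_subjects", 850)),
        seed=int(block.pop("seed", 0)),
        truncate_at_zero=bool(block.pop("truncate_at_zero", False)),
        outcome_model=outcome,
    )


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write the output bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate
            if sim_cfg.seed == 0 and config.seed != 0:
                sim_cfg.seed = config.seed
            structure = config.planted_structure()
            cohort = simulate_cohort(sim_cfg, structure)
            intakes, covariates, biomarkers = (
                cohort.intakes,
                cohort.covariates,
                cohort.biomarkers,
            )
        else:
            intakes, covariates, biomarkers = load_tables(config.input_paths)
        if config.apply_energy_exclusions:
            intakes, covariates, biomarkers, exclusion_log = apply_exclusions(
                intakes, covariates, biomarkers
            )
            _write_csv(exclusion_log, outdir / "exclusions.tsv")

        stage = "standardize"
        z, zparams = standardize(intakes)

        stage = "select_lambda"
        if config.ggm.lam == "auto":
            selection = select_lambda(z, config.ggm)
            lam = selection.lam
            _write_csv(selection.table, outdir / "lambda_selection.csv", index=False)
        else:
            lam = float(config.ggm.lam)

        stage = "estimate_precision"
        precision = estimate_precision(z, lam, config.ggm)
        _write_csv(precision.matrix, outdir / "precision.csv")

        stage = "partial_correlations"
        partial = precision_to_partial(precision)
        _write_csv(partial, outdir / "partial_correlations.csv")

        stage = "extract_networks"
        networks = extract_networks(partial, config.ggm)
        _write_csv(networks.edge_table(), outdir / "network_edges.tsv", index=False)
        graph = networks.to_graph()
        if graph.number_of_nodes():
            nx.write_graphml(graph, outdir / "networks.graphml")

        stage = "link_communities"
        communities: dict[str, object] = {}
        comm_rows, cent_frames = [], []
        for net in networks:
            dendro = cluster_edges(net, weighted=config.weighted_communities)
            comm = cut_at_max_density(dendro)
            communities[net.network_id] = comm
            for c_idx, nodes in enumerate(comm.node_sets, start=1):
                comm_rows += [(net.network_id, c_idx, node) for node in nodes]
            report = centrality_report(comm, net).reset_index()
            report.insert(0, "network_id", net.network_id)
            cent_frames.append(report)
        _write_csv(
            pd.DataFrame(comm_rows, columns=["network_id", "community_id", "node"]),
            outdir / "communities.tsv",
            index=False,
        )
        centrality = (
            pd.concat(cent_frames, ignore_index=True)
            if cent_frames
            else pd.DataFrame(columns=["network_id", "node", "membership", "degree", "central"])
        )
        _write_csv(centrality, outdir / "centrality.tsv", index=False)

        stage = "scores"
        loadings_rows, score_frames, network_scores = [], [], {}
        for net in networks:
            lv = pca_loadings(z[list(net.nodes)])
            loadings_rows += [
                (net.network_id, g, float(l)) for g, l in lv.loadings.items()
            ]
            score = compute_score(z, lv)
            ns = assign_tertiles(score)
            network_scores[net.network_id] = ns
            score_frames.append(
                pd.DataFrame(
                    {"network": net.network_id, "score": ns.scores, "tertile": ns.tertiles}
                )
            )
        loadings = pd.DataFrame(loadings_rows, columns=["network", "group", "loading"])
        _write_csv(loadings, outdir / "loadings.csv", index=False)
        scores = (
            pd.concat(score_frames)
            if score_frames
            else pd.DataFrame(columns=["network", "score", "tertile"])
        )
        _write_csv(scores, outdir / "scores.csv")

        stage = "classify_mets"
        mets_table = classify(biomarkers, covariates["sex"], config.cutoffs)
        _write_csv(mets_table, outdir / "mets.csv")

        stage = "associations"
        outcome_cols = [
            "mets",
            "hypertension",
            "hyperglycemia",
            "hypertriglyceridemia",
            "central_obesity",
        ]
        outcomes = mets_table[outcome_cols].astype(bool)
        associations = run_all(outcomes, network_scores, covariates, default_model_specs())
        _write_csv(associations, outdir / "associations.csv", index=False)

        stage = "descriptives"
        desc_tert = {
            net_id: summarize_by_tertile(biomarkers, ns.tertiles)
            for net_id, ns in network_scores.items()
        }
        for net_id, table in desc_tert.items():
            _write_csv(table, outdir / f"descriptives_{net_id}.csv")
        desc_sex = summarize_by_sex(covariates, outcomes)
        _write_csv(desc_sex, outdir / "descriptives_by_sex.csv", index=False)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest = _manifest(config, lam, networks)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        networks=networks,
        lam=lam,
        partial=partial,
        communities=communities,
        centrality=centrality,
        scores=scores,
        loadings=loadings,
        mets=mets_table,
        associations=associations,
        descriptives_tertile=desc_tert,
        descriptives_sex=desc_sex,
        manifest=manifest,
        outdir=outdir,
    )


def _manifest(config: RunConfig, lam: float, networks: DietaryNetworkSet) -> dict:
    cfg_repr = {
        "seed": config.seed,
        "mode": "simulate" if config.simulate is not None else "ingest",
        "structure": config.structure if isinstance(config.structure, str) else "custom",
        "lambda": lam,
        "lambda_selection": config.ggm.criterion if config.ggm.lam == "auto" else "fixed",
        "ebic_gamma": config.ggm.ebic_gamma,
        "strong_threshold": config.ggm.strong_threshold,
        "strong_edge_filter": config.ggm.strong_edge_filter,
        "min_network_size": config.ggm.min_network_size,
        "zero_tol": config.ggm.zero_tol,
        "quantile_type": 7,
        "standardization": "population_sd",
        "loading_sign_convention": "positive_loading_sum",
        "bp_rule": config.cutoffs.bp_rule,
        "cutoffs": {
            "wc_male": config.cutoffs.wc_male,
            "wc_female": config.cutoffs.wc_female,
            "sbp": config.cutoffs.sbp,
            "dbp": config.cutoffs.dbp,
            "tg": config.cutoffs.tg,
            "fbg": config.cutoffs.fbg,
            "hdl_male": config.cutoffs.hdl_male,
            "hdl_female": config.cutoffs.hdl_female,
            "threshold": config.cutoffs.threshold,
        },
        "weighted_communities": config.weighted_communities,
        "n_networks": len(networks),
        "version": __version__,
    }
    digest = hashlib.sha256(
        json.dumps(cfg_repr, sort_keys=True).encode()
    ).hexdigest()[:16]
    cfg_repr["config_hash"] = digest
    return cfg_repr
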