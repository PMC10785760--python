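"""End-to-end orchestration of the chemical-wide / metabolome-wide analysis.

Stages, in the order they run:

1. synthetic cohort generation (or loading user TSVs)
2. preprocessing — QC filter, batch standardization, left-censored
   imputation of both metabolome tables; LOD imputation of the panel
3. kinetics — TCDD back-extrapolation to TCDD_max
4. chlorine screen — spectral clustering and envelope detection
5. related compounds — Spearman selection, exposure network, communities
6. MWAS — every targeted and related exposure × both LC modes, BH 20%
7. pathway enrichment — per subclass per mode
8. integration — pathway PC1 scores × immune markers (factory A), network

Every intermediate table is written as TSV, the networks as GraphML +
edge TSV, and a JSON manifest records parameters, seeds and the row
counts flowing through each stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chlorine import IsotopeConstants, cluster_spectra, suspect_list
from .enrichment import PathwayDB, enrich_by_subclass
from .integration import (
    build_integration_network,
    pathway_pc1_scores,
    pls_association,
)
from .kinetics import tcdd_max_series
from .mwas import aggregate_subclass, categorize_features, run_full_mwas
from .network import export_network, modularity
from .preprocess import (
    correct_batches,
    filter_features,
    impute_left_censored,
    impute_targeted_lod,
)
from .related import build_exposure_network, community_network, spearman_select
from .synthetic import SimConfig, SyntheticStudy, generate_study
from .tables import ConfigurationError, FeatureTable


@dataclass
class PipelineConfig:
    """One config drives the whole run; the global seed fans out per stage."""

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    # preprocessing
    cv_max: float = 1.0
    min_detect: float = 0.6
    # kinetics
    t_half: float = 7.1
    background: float | None = None      # None -> factory-B mean
    # chlorine screen
    sigma_rt: float = 2.0
    sigma_r: float = 0.5
    cluster_cut: float = 0.5
    mass_tol: float = 0.005
    ratio_tol: float = 0.30
    # related compounds
    p_max: float = 0.002
    # MWAS
    model: int = 1
    fdr: float = 0.20
    # enrichment
    n_perm: int = 1000
    min_overlap: int = 4
    enrich_alpha: float = 0.05
    # integration
    n_comp: int = 3
    score_threshold: float = 0.3
    p_threshold: float = 0.05
    integration_subset: str = "A"        # factory label or "all"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        if not 0 < self.fdr < 1 or not 0 < self.p_max < 1:
            raise ConfigurationError("thresholds must lie in (0, 1)")

    def stage_seed(self, stage: int) -> int:
        return int((int(self.seed) * 1000003 + stage * 7919 + 1) % (2**31 - 1))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    """In-memory handles to every stage's products."""

    config: PipelineConfig
    study: SyntheticStudy
    metabolome: dict                      # mode -> preprocessed FeatureTable (ln)
    panel_imputed: object
    tcdd_max: pd.Series
    suspects: pd.DataFrame
    suspect_abundance: pd.DataFrame
    related: object
    exposure_network: object
    mwas: object
    subclass_sets: object
    subclass_features: dict
    enrichment: pd.DataFrame
    annotations: dict
    pathway_scores: object
    association_scores: pd.DataFrame
    integration_edges: pd.DataFrame
    integration_network: object
    manifest: dict


def _preprocess_mode(table: FeatureTable, cfg: PipelineConfig, stage_seed: int):
    filtered, removal_log = filter_features(table, cfg.cv_max, cfg.min_detect)
    corrected, warn_log = correct_batches(filtered)
    imputed = impute_left_censored(corrected, seed=stage_seed)
    return imputed, removal_log, warn_log


def build_sig_feature_map(
    enrichment: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    subclass_features: dict[str, dict[str, list[str]]],
    db: PathwayDB,
) -> dict[str, dict[str, list[str]]]:
    """pathway → mode → significant features annotated to its metabolites."""
    out: dict[str, dict[str, set[str]]] = {}
    passing = enrichment[enrichment["pass"]]
    for _, row in passing.iterrows():
        pid, mode, sub = row["pathway_id"], row["mode"], row["subclass"]
        mets = db.members.get(pid, set())
        ann = annotations[mode]
        sig = set(subclass_features[sub][mode])
        feats = set(
            ann.loc[
                ann["metabolite_id"].isin(mets) & ann["feature_id"].isin(sig),
                "feature_id",
            ]
        )
        out.setdefault(pid, {}).setdefault(mode, set()).update(feats)
    return {
        pid: {mode: sorted(fs) for mode, fs in modes.items()}
        for pid, modes in out.items()
    }


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: Path | str | None = None,
    study: SyntheticStudy | None = None,
) -> PipelineResult:
    """Execute every stage; optionally write all artifacts under ``outdir``."""
    cfg = config if config is not None else PipelineConfig()
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k != "sim"
        },
        "sim": dataclasses.asdict(cfg.sim),
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts

    try:
        # 1. synthetic inputs -------------------------------------------------
        if study is None:
            study = generate_study(cfg.sim)
        record(
            "synthetic",
            subjects=len(study.subjects),
            chem_features=study.chem.features.shape[0],
            c18neg_features=study.c18neg.features.shape[0],
            hilicpos_features=study.hilicpos.features.shape[0],
            pathways=int(study.pathway_db["pathway_id"].nunique()),
            markers=study.markers.shape[1],
        )

        # 2. preprocessing ----------------------------------------------------
        metabolome: dict[str, FeatureTable] = {}
        logs = {}
        for i, (mode, raw) in enumerate(
            (("C18neg", study.c18neg), ("HILICpos", study.hilicpos))
        ):
            table, removed, warned = _preprocess_mode(raw, cfg, cfg.stage_seed(20 + i))
            metabolome[mode] = table
            logs[mode] = {"removed": removed, "warnings": warned}
            record(
                f"preprocess_{mode}",
                input_features=raw.features.shape[0],
                removed=len(removed),
                retained=table.features.shape[0],
            )
        panel_imputed = impute_targeted_lod(study.panel)
        record(
            "preprocess_panel",
            censored_cells=int(study.panel.below_lod.to_numpy().sum()),
        )

        # 3. kinetics ---------------------------------------------------------
        tcdd_max = tcdd_max_series(
            study.subjects, panel_imputed, t_half=cfg.t_half, background=cfg.background
        )
        record("kinetics", subjects=len(tcdd_max))

        # 4. chlorine screen --------------------------------------------------
        consts = IsotopeConstants(mass_tol=cfg.mass_tol, ratio_tol=cfg.ratio_tol)
        clusters, cluster_warnings = cluster_spectra(
            study.chem, sigma_rt=cfg.sigma_rt, sigma_r=cfg.sigma_r, cut=cfg.cluster_cut
        )
        suspects, abundances = suspect_list(clusters, consts)
        suspect_abundance = pd.DataFrame(abundances)
        record("chlorine_screen", clusters=len(clusters), suspects=len(suspects))

        # 5. related compounds ------------------------------------------------
        related, rel_warnings = spearman_select(
            suspect_abundance, panel_imputed, p_max=cfg.p_max
        )
        exposure_net = build_exposure_network(
            panel_imputed, related, suspect_abundance, p_max=cfg.p_max
        )
        exposure_net, exp_labels = community_network(
            exposure_net, seed=cfg.stage_seed(50)
        )
        record(
            "related_compounds",
            related=len(related.all_compounds),
            pcdd_related=len(related.subclass_sets["PCDD"]),
            pcdf_related=len(related.subclass_sets["PCDF"]),
            pcb_related=len(related.subclass_sets["PCB"]),
            network_nodes=exposure_net.number_of_nodes(),
            network_edges=exposure_net.number_of_edges(),
            communities=len(set(exp_labels.values())),
        )

        # 6. MWAS -------------------------------------------------------------
        panel_ln = np.log(panel_imputed.concentrations)
        panel_ln["TCDD_max"] = np.log(tcdd_max)
        related_ab = suspect_abundance[sorted(related.all_compounds)]
        results = run_full_mwas(
            metabolome, panel_ln, related_ab, study.subjects,
            model=cfg.model, fdr=cfg.fdr,
        )
        subclass_sets = aggregate_subclass(results, related)
        subclass_features = categorize_features(subclass_sets)
        record(
            "mwas",
            exposures=len(results.exposure_kind),
            significant_pairs=int(
                sum(t["significant"].sum() for t in results.tables.values())
            ),
        )

        # 7. pathway enrichment ----------------------------------------------
        db = PathwayDB.from_frame(study.pathway_db)
        enrichment, annotations = enrich_by_subclass(
            subclass_features, metabolome, db,
            n_perm=cfg.n_perm, seed=cfg.stage_seed(70),
            min_overlap=cfg.min_overlap, alpha=cfg.enrich_alpha,
        )
        record(
            "pathway_enrichment",
            tested=len(enrichment),
            passing=int(enrichment["pass"].sum()) if len(enrichment) else 0,
        )

        # 8. integration -------------------------------------------------------
        if cfg.integration_subset == "all":
            subset = study.subjects.index
        else:
            subset = study.subjects.index[
                study.subjects["factory"] == cfg.integration_subset
            ]
        sig_map = build_sig_feature_map(enrichment, annotations, subclass_features, db)
        if sig_map:
            pscores = pathway_pc1_scores(metabolome, enrichment, sig_map, subset)
        else:
            pscores = None
        if pscores is not None and pscores.scores.shape[1] > 0:
            assoc, edges = pls_association(
                pscores.scores, study.markers.loc[subset],
                n_comp=cfg.n_comp, score_threshold=cfg.score_threshold,
                p_threshold=cfg.p_threshold,
            )
        else:
            assoc = pd.DataFrame()
            edges = pd.DataFrame(columns=["pathway_id", "marker_id", "score", "p"])
        integration_net = build_integration_network(
            edges, study.marker_categories, seed=cfg.stage_seed(80)
        )
        record(
            "integration",
            pathways=0 if pscores is None else pscores.scores.shape[1],
            edges=len(edges),
            network_nodes=integration_net.number_of_nodes(),
            communities=len(
                set(nx_labels.values())
            ) if (nx_labels := dict(integration_net.nodes(data="community"))) else 0,
        )
    except ConfigurationError:
        raise
    except Exception as err:  # annotate with the failing stage
        done = list(manifest["stages"])
        stage = done[-1] if done else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {err}") from err

    result = PipelineResult(
        config=cfg, study=study, metabolome=metabolome,
        panel_imputed=panel_imputed, tcdd_max=tcdd_max, suspects=suspects,
        suspect_abundance=suspect_abundance, related=related,
        exposure_network=exposure_net, mwas=results,
        subclass_sets=subclass_sets, subclass_features=subclass_features,
        enrichment=enrichment, annotations=annotations,
        pathway_scores=pscores, association_scores=assoc,
        integration_edges=edges, integration_network=integration_net,
        manifest=manifest,
    )
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    """Write every stage's tables, the two networks, and the manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    result.study.write(outdir / "inputs")
    for mode, table in result.metabolome.items():
        table.write(outdir / f"preprocessed_{mode}")
    result.panel_imputed.write(outdir / "panel_imputed")
    result.tcdd_max.to_csv(outdir / "tcdd_max.tsv", sep="\t")
    result.suspects.to_csv(outdir / "suspected_chlorinated.tsv", sep="\t")
    result.suspect_abundance.to_csv(outdir / "suspect_abundance.tsv", sep="\t")
    result.related.to_frame().to_csv(outdir / "related_compounds.tsv", sep="\t", index=False)
    export_network(result.exposure_network, outdir / "exposure_network")
    result.mwas.to_frame().to_csv(outdir / "mwas_results.tsv", sep="\t", index=False)
    result.subclass_sets.per_congener.to_csv(outdir / "subclass_summary.tsv", sep="\t")
    result.enrichment.to_csv(outdir / "pathway_enrichment.tsv", sep="\t", index=False)
    if result.pathway_scores is not None:
        result.pathway_scores.scores.to_csv(outdir / "pathway_pc1_scores.tsv", sep="\t")
    result.integration_edges.to_csv(outdir / "integration_edges.tsv", sep="\t", index=False)
    export_network(result.integration_network, outdir / "integration_network")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
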