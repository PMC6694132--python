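"""Configuration-driven orchestration of the full synthetic pipeline.

``run_pipeline`` executes the stages in dependency order — synthetic data
generation, then the three computational stages (co-expression, epistasis,
regional expression), then integration into the edge list + node-attribute
table, then the prioritization use case — and writes a provenance manifest
(config hash, seed, per-stage row counts) alongside the artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import brainexpr, coexpression, epistasis, graphfeat, integration, synthdata
from .types import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the synthetic end-to-end run.

    Thresholds default to the study's published values: RRA score < 1e-5,
    region co-expression adjusted p <= 0.01 plus the quartile rule,
    epistasis p < 1e-8 (ventricle / Braak) and < 1e-5 (cognitive traits),
    MAF product > 0.01, QC at missing > 0.1 / MAF < 0.05 / HWE p <= 1e-3,
    genic margin 5000 bp, MI >= 0.45, GWAS p <= 0.05, reduced-version
    |rho| >= 0.8, case-study co-expression cut 0.5.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"

    # synthetic-data scale
    n_genes: int = 60
    n_pseudogenes: int = 4
    overlap_fraction: float = 0.1
    n_expression_datasets: int = 6
    samples_per_dataset: int = 40
    module_genes: int = 5
    module_rho: float = 0.9
    noise_sd: float = 0.3
    n_regions: int = 231
    samples_per_region: int = 2
    n_brains: int = 6
    region_effect: float = 1.0
    n_upregulated: int = 5
    n_individuals: int = 500
    n_snps: int = 40
    planted_beta_ab: float = 1.0
    missing_rate: float = 0.02
    n_ppi: int = 60
    pbs_fraction: float = 0.3
    gwas_n_snps: int = 100
    ps_n_genes: int = 10

    # stage thresholds (published defaults)
    rra_alpha: float = 1e-5
    region_p_threshold: float = 0.01
    qc_max_missing: float = 0.1
    qc_min_maf: float = 0.05
    qc_hwe_alpha: float = 1e-3
    maf_product_min: float = 0.01
    epistasis_p_severe: float = 1e-8
    epistasis_p_cognitive: float = 1e-5
    bin_margin: int = 5000
    bin_alpha: float = 0.05
    min_mi: float = 0.45
    gwas_alpha: float = 0.05
    reduced_cutoff: float = 0.8
    case_study_coexpr_cutoff: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # nested sections flatten
                flat.update(value)
            else:
                flat[key] = value
        if "seed" not in flat:
            raise ValueError("config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        params = dataclasses.asdict(self)
        params.pop("out_dir")
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    edges: pd.DataFrame
    nodes_wide: pd.DataFrame
    nodes_long: pd.DataFrame
    zscores: pd.DataFrame
    features: pd.DataFrame
    metrics: dict[str, float]
    ranked_unknowns: pd.DataFrame
    summary: dict
    manifest: dict
    ground_truth: dict = field(default_factory=dict)


def _combine_region_datasets(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    values = pd.concat([d.values for d in datasets], axis=1)
    ann = pd.concat([d.sample_annotations for d in datasets], axis=0)
    return ExpressionDataset(dataset_id="BRAIN_COMBINED", values=values, sample_annotations=ann)


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage on freshly generated synthetic data."""
    stage = "synthdata"
    try:
        result = _run(config, write=write)
    except Exception as exc:  # pragma: no cover - error surface
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return result


def _run(config: PipelineConfig, write: bool) -> PipelineResult:
    cfg = config
    rows: dict[str, int] = {}

    # --- stage: synthetic data -------------------------------------------
    annotation = synthdata.gen_gene_annotation(
        cfg.n_genes, cfg.n_pseudogenes, cfg.overlap_fraction, seed=cfg.seed
    )
    non_pseudo = [g.ensg_id for g in annotation.genes if not g.is_pseudogene]
    module = non_pseudo[: cfg.module_genes]
    cohorts, coexpr_truth = synthdata.gen_expression_cohorts(
        annotation,
        n_datasets=cfg.n_expression_datasets,
        samples_per_dataset=cfg.samples_per_dataset,
        modules=[(module, cfg.module_rho)],
        noise_sd=cfg.noise_sd,
        seed=cfg.seed + 1,
    )
    upregulated = non_pseudo[cfg.module_genes : cfg.module_genes + cfg.n_upregulated]
    regions = synthdata.default_regions(cfg.n_regions)
    brain_datasets, region_truth = synthdata.gen_region_expression(
        annotation,
        regions=regions,
        upregulated_genes=upregulated,
        effect=cfg.region_effect,
        samples_per_region=cfg.samples_per_region,
        n_datasets=cfg.n_brains,
        seed=cfg.seed + 2,
    )
    cohort = synthdata.gen_genotypes_and_traits(
        annotation,
        n_individuals=cfg.n_individuals,
        n_snps=cfg.n_snps,
        epistatic_pairs=[
            synthdata.PlantedPair("rs000001", "rs000002", beta_ab=cfg.planted_beta_ab)
        ],
        missing_rate=cfg.missing_rate,
        seed=cfg.seed + 3,
    )
    omics = synthdata.gen_ppi_and_tables(
        annotation,
        n_ppi=cfg.n_ppi,
        pbs_fraction=cfg.pbs_fraction,
        gwas_n_snps=cfg.gwas_n_snps,
        ps_n_genes=cfg.ps_n_genes,
        seed=cfg.seed + 4,
    )
    rows["synthetic_genes"] = len(annotation.genes)

    # --- stage: co-expression --------------------------------------------
    adn = coexpression.aggregate_global_coexpression(
        cohorts, annotation.probe_map, alpha=cfg.rra_alpha
    )
    rows["adn_pairs"] = len(adn)
    region_tables: dict[str, pd.DataFrame] = {}
    combined = _combine_region_datasets(brain_datasets)
    for region in synthdata.DISEASE_REGIONS:
        table = coexpression.region_coexpression(
            combined, region, annotation.probe_map, p_threshold=cfg.region_p_threshold
        )
        region_tables[region] = table
        rows[f"aba_{region.lower()}_pairs"] = len(table)

    # --- stage: epistasis -------------------------------------------------
    genotypes_qc, qc_report = epistasis.qc_filter(
        cohort.genotypes,
        max_missing=cfg.qc_max_missing,
        min_maf=cfg.qc_min_maf,
        hwe_alpha=cfg.qc_hwe_alpha,
    )
    rows["snps_after_qc"] = len(genotypes_qc.snps)
    assignments = epistasis.map_snps_to_bins(
        genotypes_qc.snps, annotation, margin=cfg.bin_margin
    )
    derived = epistasis.derive_trait_values(cohort.trait_series)
    braak_adj = epistasis.adjust_braak(cohort.braak_scores, cohort.ages)
    ventricle_adj = epistasis.adjust_ventricle(cohort.ventricle_series, cohort.covariates)
    rows["derived_phenotypes"] = derived.shape[1]

    scans = {
        # synthetic quantitative phenotype carrying the planted interaction,
        # analysed at the severe-phenotype threshold
        "ADNI_VER": (cohort.phenotype, cfg.epistasis_p_severe),
        "TGEN": (braak_adj, cfg.epistasis_p_severe),
        "HBTRC": (braak_adj, cfg.epistasis_p_severe),
        f"ADNI_CT_{synthdata.TRAIT_REGISTRY[0]}_latest": (
            derived[f"{synthdata.TRAIT_REGISTRY[0]}_latest"],
            cfg.epistasis_p_cognitive,
        ),
    }
    epi_tables: dict[str, pd.DataFrame] = {}
    for source, (pheno, threshold) in scans.items():
        results = epistasis.scan_pairs(
            genotypes_qc, pheno,
            maf_product_min=cfg.maf_product_min, p_threshold=threshold,
        )
        epi_tables[source] = epistasis.binwise_bonferroni(
            results, assignments, alpha=cfg.bin_alpha
        )
        rows[f"epistasis_{source.lower()}_bins"] = len(epi_tables[source])
    # note: _ventricle_adj/_braak_adj stand in for the cohort phenotypes; the
    # planted pair lives in the composite scan phenotype
    del ventricle_adj, qc_report

    # --- stage: regional expression --------------------------------------
    mean_tables = [brainexpr.region_means(d) for d in brain_datasets]
    zscores = brainexpr.zscore_and_collapse(mean_tables, annotation.probe_map)
    rows["zscore_genes"] = len(zscores)

    # --- stage: integration -----------------------------------------------
    ppi = omics.ppi
    pbs_part = ppi[ppi["score_kind"] == "pbs"]
    mi_part = integration.filter_ppi_by_score(
        ppi[ppi["score_kind"] == "mi"], min_mi=cfg.min_mi
    )
    protein_mapping = {k: v for k, v in annotation.protein_map.items()}
    stage_outputs: list[tuple[pd.DataFrame, str, str]] = []
    for source, part in [
        ("PBA", pbs_part),
        ("IAH", mi_part[mi_part["source"] == "IAH"]),
        ("ADIA", mi_part[mi_part["source"] == "ADIA"]),
        ("SIA", mi_part[mi_part["source"] == "SIA"]),
    ]:
        mapped, _rep = integration.map_identifiers(
            part, protein_mapping, ["protein_a", "protein_b"]
        )
        stage_outputs.append(
            (mapped.rename(columns={"protein_a": "ensg_a", "protein_b": "ensg_b"}), "PPI", source)
        )
    stage_outputs.append((adn, "co-expression", "ADN"))
    for region, table in region_tables.items():
        stage_outputs.append((table, "co-expression", f"ABA_{region}"))
    for source, table in epi_tables.items():
        for itype in ("epistasis", "IGRI"):
            part = table[table["interaction_type"] == itype][["bin_a", "bin_b", "p_value"]]
            stage_outputs.append((part, itype, source))

    registry = integration.default_registry()
    edges = integration.assemble_edges(stage_outputs, registry)
    nodes_long, nodes_wide = integration.assemble_node_attributes(
        omics.gwas, omics.positive_selection, zscores,
        annotation.genes, gwas_alpha=cfg.gwas_alpha, n_regions=cfg.n_regions,
    )
    edges, nodes_wide, pseudo_report = integration.filter_pseudogenes(edges, nodes_wide)
    nodes_long = nodes_long[nodes_long["ensg"].isin(set(nodes_wide["ensg"]))].reset_index(
        drop=True
    )
    summary = integration.summarize(edges, nodes_wide)
    rows["edges"] = len(edges)
    rows["nodes"] = len(nodes_wide)

    # --- stage: prioritization use case -----------------------------------
    graph = graphfeat.prepare_case_study_graph(
        edges, coexpr_cutoff=cfg.case_study_coexpr_cutoff
    )
    gwas_genes = set(
        omics.gwas.loc[omics.gwas["p"] <= cfg.gwas_alpha, "ensg"].astype(str)
    )
    adia_edges = edges[edges["data_source"] == "ADIA"]
    ad_ppi_genes = set(adia_edges["ensg_a"]) | set(adia_edges["ensg_b"])
    node_set = set(graph.nodes)
    positives_pool = (gwas_genes | ad_ppi_genes) & node_set
    remaining = sorted(node_set - positives_pool)
    # synthetic stand-in for the external essential non-disease gene list
    import numpy as np

    rng = np.random.default_rng(cfg.seed + 5)
    negative_list = list(
        rng.choice(remaining, size=max(2, len(remaining) // 2), replace=False)
    )
    labels = graphfeat.assemble_labels(gwas_genes, ad_ppi_genes, negative_list, node_set)
    features = graphfeat.build_feature_table(graph, labels, zscores)
    metrics, scores = graphfeat.fit_and_evaluate(features, labels, seed=cfg.seed)
    ranked = graphfeat.rank_unknowns(scores, labels)
    rows["labelled_nodes"] = len(labels.positive) + len(labels.negative)

    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "row_counts": rows,
        "summary": summary,
    }

    result = PipelineResult(
        edges=edges,
        nodes_wide=nodes_wide,
        nodes_long=nodes_long,
        zscores=zscores,
        features=features,
        metrics=metrics,
        ranked_unknowns=ranked,
        summary=summary,
        manifest=manifest,
        ground_truth={
            "coexpressed_modules": coexpr_truth.coexpressed_modules,
            "disease_region_genes": region_truth.disease_region_genes,
            "epistatic_pairs": cohort.ground_truth.epistatic_pairs,
            "gwas_signal_snps": omics.ground_truth.gwas_signal_snps,
        },
    )
    if write:
        _write_artifacts(cfg, result)
    return result


def _write_artifacts(cfg: PipelineConfig, result: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comment = f"config_hash={cfg.hash()} seed={cfg.seed}"
    integration.write_edges(result.edges, str(out / "edges.tsv"), comment=comment)
    integration.write_nodes(result.nodes_wide, str(out / "nodes.tsv"), comment=comment)
    integration.write_nodes(result.nodes_long, str(out / "nodes_long.tsv"), comment=comment)
    brainexpr.write_region_ztable(result.zscores, str(out / "region_zscores.tsv"))
    result.features.to_csv(out / "features.tsv", sep="\t")
    result.ranked_unknowns.to_csv(out / "ranked_unknowns.tsv", sep="\t")
    pd.DataFrame([result.metrics]).to_csv(out / "metrics.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=int))
    reduced = integration.reduced_version(result.edges, cutoff=cfg.reduced_cutoff)
    integration.write_edges(reduced, str(out / "edges_reduced.tsv"), comment=comment)


# ---------------------------------------------------------------------------
# File validation
# ---------------------------------------------------------------------------


def validate_files(
    edges_path: str | Path,
    nodes_path: str | Path,
    n_regions: int = 231,
) -> list[str]:
    """Validate integrated edge-list / node-table files against the schema.

    Checks: column schema; per-source score domains (MI in [0.45, 1], PBS in
    [0, 10], correlations in [-1, 1], RRA/p scores in (0, 1]); node-table
    width of ``6 + n_regions`` fields; absence of pseudogene biotypes;
    intergenic composite id syntax.  Returns a list of violation messages
    (empty = conforming).
    """
    violations: list[str] = []
    edges = integration.read_edges(edges_path)
    nodes = integration.read_nodes(nodes_path)

    expected_edge_cols = ["ensg_a", "ensg_b", "score", "interaction_type", "data_source"]
    if list(edges.columns) != expected_edge_cols:
        violations.append(f"edges: unexpected columns {list(edges.columns)}")
        return violations

    registry = integration.default_registry()
    known_sources = set(registry["data_source_id"])
    for lineno, row in enumerate(edges.itertuples(index=False), start=2):
        src, score = row.data_source, float(row.score)
        if src not in known_sources:
            violations.append(f"edges line {lineno}: unknown data source {src!r}")
            continue
        if src in ("IAH", "ADIA", "SIA"):
            if not 0.45 <= score <= 1.0:
                violations.append(f"edges line {lineno}: MI score {score} outside [0.45, 1]")
        elif src == "PBA":
            if not 0.0 <= score <= 10.0:
                violations.append(f"edges line {lineno}: PBS score {score} outside [0, 10]")
        elif src.startswith("ABA_"):
            if not -1.0 <= score <= 1.0:
                violations.append(f"edges line {lineno}: correlation {score} outside [-1, 1]")
        else:  # RRA scores and epistasis p-values
            if not 0.0 < score <= 1.0:
                violations.append(f"edges line {lineno}: score {score} outside (0, 1]")
        if row.interaction_type == "IGRI":
            if "-" not in str(row.ensg_a) and "-" not in str(row.ensg_b):
                violations.append(f"edges line {lineno}: IGRI row without composite id")
        elif row.interaction_type not in ("PPI", "co-expression", "epistasis"):
            violations.append(
                f"edges line {lineno}: unknown interaction type {row.interaction_type!r}"
            )

    expected_width = 6 + n_regions
    if nodes.shape[1] != expected_width:
        violations.append(
            f"nodes: width {nodes.shape[1]} != expected {expected_width} fields"
        )
    if "biotype" in nodes.columns:
        bad = nodes["biotype"].astype(str).str.contains("pseudogene")
        for lineno in (nodes.index[bad] + 2).tolist():
            violations.append(f"nodes line {lineno}: pseudogene biotype present")
    return violations
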