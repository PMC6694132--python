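"""Seeded generators for every input the integration pipeline consumes.

Real inputs to this kind of integration effort — expression cohorts with
disease/healthy labels, brain-region-annotated microarrays, cohort genotypes
with longitudinal phenotypes, yeast two-hybrid and curated PPI lists, GWAS
summary tables, gene models — sit behind access agreements or are too large
for a desk run.  This module emulates each of them at a small scale with
*planted* ground-truth signals (co-expressed modules, epistatic SNP pairs,
disease-region upregulation, GWAS hits) so that every downstream estimator
can be tested for recovery, not just for not crashing.

All generators take an integer seed and are deterministic given
(arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BIOTYPES,
    ExpressionDataset,
    GeneModel,
    GenotypeMatrix,
    GroundTruth,
    SnpRecord,
    TraitSeries,
)

# ---------------------------------------------------------------------------
# Registries fixed by the study design
# ---------------------------------------------------------------------------

#: The 23 longitudinal cognitive traits assessed in the ADNI-style cohort.
#: Each yields two derived phenotypes (latest value and slope), hence 46
#: derived epistasis phenotype datasets.
TRAIT_REGISTRY = (
    "ADAS11",
    "ADAD13",
    "CDRSB",
    "Ecog_PtDivatt",
    "Ecog_PtLang",
    "Ecog_PtMem",
    "Ecog_PtOrgan",
    "Ecog_PtPlan",
    "Ecog_PtVisspat",
    "Ecog_PtTotal",
    "Ecog_SPDivatt",
    "Ecog_SPLang",
    "Ecog_SPMem",
    "Ecog_SPOrgan",
    "Ecog_SPPlan",
    "Ecog_SPVisspat",
    "Ecog_SPTotal",
    "FAQ",
    "MOCA",
    "MMSE",
    "RAVLT_Immediate",
    "RAVLT_Learning",
    "RAVLT_Forgetting",
)

#: The seven hippocampal-circuit regions affected by Alzheimer's disease.
DISEASE_REGIONS = ("CA1", "CA2", "CA3", "CA4", "DG", "subiculum", "SptN")


def default_regions(n_regions: int = 231) -> list[str]:
    """Region ontology: the 7 disease regions plus anonymous background regions."""
    if n_regions < len(DISEASE_REGIONS):
        raise ValueError("need at least the 7 disease regions")
    extra = [f"R{i:03d}" for i in range(len(DISEASE_REGIONS) + 1, n_regions + 1)]
    return list(DISEASE_REGIONS) + extra


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass
class Annotation:
    """Synthetic gene models plus the identifier maps onto the ENSG namespace."""

    genes: list[GeneModel]
    probe_map: dict[str, str]  # probe id -> ENSG (many-to-one)
    protein_map: dict[str, str]  # protein id -> ENSG

    @property
    def ensg_ids(self) -> list[str]:
        return [g.ensg_id for g in self.genes]

    def by_id(self, ensg: str) -> GeneModel:
        return next(g for g in self.genes if g.ensg_id == ensg)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.ensg_id, g.gene_name, g.chromosome, g.start, g.end, g.biotype)
                for g in self.genes
            ],
            columns=["ensg_id", "gene_name", "chromosome", "start", "end", "biotype"],
        )


def gen_gene_annotation(
    n_genes: int,
    n_pseudogenes: int = 0,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> Annotation:
    """Lay out ``n_genes`` gene models on one synthetic chromosome.

    Genes are placed left to right with random lengths and intergenic gaps;
    ``overlap_fraction`` of the adjacent gene pairs are made to overlap
    (shared genomic interval), which exercises multi-assignment of SNPs to
    genes downstream.  ``n_pseudogenes`` random genes are given a pseudogene
    biotype so the pseudogene filter has something to remove.

    The returned probe map contains 1-2 probes per gene (at least one gene
    always has two, exercising one-to-many probe collapse); the protein map
    is one protein per gene.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if n_pseudogenes < 0 or n_pseudogenes > n_genes:
        raise ValueError("n_pseudogenes must be in [0, n_genes]")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(2_000, 12_000, size=n_genes)
    # Gaps wide enough that non-overlapping neighbours sit clear of the
    # default 5 kb genic margin, leaving room for intergenic SNPs.
    gaps = rng.integers(12_000, 40_000, size=n_genes)

    overlapping = np.zeros(n_genes, dtype=bool)
    if overlap_fraction > 0:
        n_overlap = int(round(overlap_fraction * (n_genes - 1)))
        idx = rng.choice(np.arange(1, n_genes), size=n_overlap, replace=False)
        overlapping[idx] = True

    pseudo_idx = set(
        rng.choice(n_genes, size=n_pseudogenes, replace=False).tolist()
    )

    genes: list[GeneModel] = []
    cursor = 10_000
    prev_start = prev_end = None
    for i in range(n_genes):
        if overlapping[i] and prev_end is not None:
            # Start inside the previous gene's interval.
            lo = prev_start
            start = int(rng.integers(lo, prev_end))
        else:
            start = cursor + int(gaps[i])
        end = start + int(lengths[i])
        if i in pseudo_idx:
            biotype = str(rng.choice(["processed_pseudogene", "unprocessed_pseudogene"]))
        else:
            biotype = str(rng.choice(["protein_coding", "protein_coding", "lincRNA", "antisense"]))
        ensg = f"ENSG{i + 1:011d}"
        genes.append(
            GeneModel(
                ensg_id=ensg,
                gene_name=f"GENE{i + 1}",
                chromosome="1",
                start=start,
                end=end,
                biotype=biotype,
            )
        )
        prev_start, prev_end = start, end
        cursor = max(cursor, end)

    probe_map: dict[str, str] = {}
    counter = 1
    for i, g in enumerate(genes):
        n_probes = 2 if i == 0 else int(rng.integers(1, 3))
        for _ in range(n_probes):
            probe_map[f"probe_{counter:05d}"] = g.ensg_id
            counter += 1
    protein_map = {f"PROT{i + 1:05d}": g.ensg_id for i, g in enumerate(genes)}
    return Annotation(genes=genes, probe_map=probe_map, protein_map=protein_map)


# ---------------------------------------------------------------------------
# Expression cohorts with planted co-expression modules
# ---------------------------------------------------------------------------


def _pearson_target(spearman_rho: float) -> float:
    """Pearson correlation of bivariate normals whose Spearman equals ``rho``.

    For bivariate Gaussians rho_S = (6/pi) * asin(r/2); inverting gives the
    Pearson loading needed to hit a target Spearman.
    """
    return float(2.0 * np.sin(np.pi * spearman_rho / 6.0))


def gen_expression_cohorts(
    annotation: Annotation,
    n_datasets: int = 6,
    samples_per_dataset: int | list[int] = 40,
    modules: list[tuple[list[str], float]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate disease/healthy expression cohorts with planted modules.

    ``modules`` is a list of (gene id list, target Spearman rho).  Within a
    module, probe profiles share a latent per-sample factor:
    ``y = lam * f + base + noise`` with the loading ``lam`` calibrated so the
    expected pairwise Spearman correlation matches the target.  Genes outside
    any module are independent noise, so off-module pairs are uncorrelated in
    expectation.  Half the samples in each dataset are labelled AD, half HI.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    modules = modules or []
    known = set(annotation.ensg_ids)
    for genes, rho in modules:
        if len(genes) < 2:
            raise ValueError("each module must list >= 2 genes")
        if not -1.0 < rho < 1.0:
            raise ValueError("target correlation must be in (-1, 1)")
        missing = set(genes) - known
        if missing:
            raise ValueError(f"module genes not in annotation: {sorted(missing)}")

    if isinstance(samples_per_dataset, int):
        sample_counts = [samples_per_dataset] * n_datasets
    else:
        sample_counts = list(samples_per_dataset)
        if len(sample_counts) != n_datasets:
            raise ValueError("samples_per_dataset length must equal n_datasets")

    rng = np.random.default_rng(seed)
    gene_module: dict[str, int] = {}
    loadings: list[float] = []
    for m, (genes, rho) in enumerate(modules):
        r = _pearson_target(abs(rho))
        # corr between two module genes = lam^2 / (lam^2 + 1 + noise_sd^2)
        lam = np.sqrt(r / (1.0 - r) * (1.0 + noise_sd**2)) if r > 0 else 0.0
        loadings.append(float(lam))
        for g in genes:
            gene_module[g] = m

    probe_items = sorted(annotation.probe_map.items())
    datasets: list[ExpressionDataset] = []
    for d in range(n_datasets):
        n = sample_counts[d]
        sample_ids = [f"DS{d + 1}_S{j + 1:03d}" for j in range(n)]
        factors = rng.normal(size=(len(modules), n))
        rows = np.empty((len(probe_items), n))
        for i, (_probe, ensg) in enumerate(probe_items):
            base = rng.normal(scale=1.0, size=n)
            noise = rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else 0.0
            m = gene_module.get(ensg)
            signal = loadings[m] * factors[m] if m is not None else 0.0
            rows[i] = 7.0 + signal + base + noise
        condition = np.array(["AD"] * (n // 2) + ["HI"] * (n - n // 2))
        ann = pd.DataFrame(
            {"condition": condition, "donor": [f"D{d + 1}_{j}" for j in range(n)]},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        datasets.append(
            ExpressionDataset(
                dataset_id=f"COHORT{d + 1}",
                values=pd.DataFrame(
                    rows, index=[p for p, _ in probe_items], columns=sample_ids
                ),
                sample_annotations=ann,
            )
        )
    truth = GroundTruth(coexpressed_modules=[(list(g), rho) for g, rho in modules])
    return datasets, truth


# ---------------------------------------------------------------------------
# Region-annotated expression (Allen-atlas style)
# ---------------------------------------------------------------------------


def gen_region_expression(
    annotation: Annotation,
    regions: list[str] | None = None,
    disease_regions: list[str] | None = None,
    upregulated_genes: list[str] | None = None,
    effect: float = 1.0,
    samples_per_region: int = 2,
    n_datasets: int = 1,
    seed: int = 0,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Region-annotated whole-brain expression with planted upregulation.

    Defaults to the 231-region ontology with the 7 hippocampal-circuit
    disease regions.  ``upregulated_genes`` gain ``effect`` mean expression
    units in disease-region samples.  One dataset is emitted per synthetic
    donor brain (``n_datasets``).
    """
    regions = list(regions) if regions is not None else default_regions()
    disease_regions = (
        list(disease_regions) if disease_regions is not None else list(DISEASE_REGIONS)
    )
    upregulated_genes = list(upregulated_genes or [])
    missing = set(disease_regions) - set(regions)
    if missing:
        raise ValueError(f"disease regions not in region list: {sorted(missing)}")
    bad = set(upregulated_genes) - set(annotation.ensg_ids)
    if bad:
        raise ValueError(f"upregulated genes not in annotation: {sorted(bad)}")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if samples_per_region < 1:
        raise ValueError("samples_per_region must be >= 1")

    rng = np.random.default_rng(seed)
    probe_items = sorted(annotation.probe_map.items())
    up = set(upregulated_genes)
    disease = set(disease_regions)
    datasets = []
    for d in range(n_datasets):
        sample_ids, region_labels = [], []
        for r in regions:
            for j in range(samples_per_region):
                sample_ids.append(f"BRAIN{d + 1}_{r}_{j + 1}")
                region_labels.append(r)
        n = len(sample_ids)
        is_disease = np.array([r in disease for r in region_labels])
        rows = np.empty((len(probe_items), n))
        for i, (_probe, ensg) in enumerate(probe_items):
            mu = rng.normal(5.0, 1.0)
            x = rng.normal(mu, 1.0, size=n)
            if ensg in up:
                x = x + effect * is_disease
            rows[i] = x
        ann = pd.DataFrame(
            {"region": region_labels, "donor": f"BRAIN{d + 1}"},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        datasets.append(
            ExpressionDataset(
                dataset_id=f"BRAIN{d + 1}",
                values=pd.DataFrame(
                    rows, index=[p for p, _ in probe_items], columns=sample_ids
                ),
                sample_annotations=ann,
            )
        )
    truth = GroundTruth(disease_region_genes=upregulated_genes)
    return datasets, truth


# ---------------------------------------------------------------------------
# Genotypes, phenotypes and planted epistasis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPair:
    """A planted epistatic SNP pair: y gains bA*gA + bB*gB + bAB*gA*gB."""

    snp_a: str
    snp_b: str
    beta_ab: float
    beta_a: float = 0.5
    beta_b: float = 0.5


@dataclass
class SyntheticCohort:
    """Everything the epistasis stage consumes, plus its ground truth."""

    genotypes: GenotypeMatrix
    phenotype: pd.Series  # quantitative scan phenotype, indexed by individual
    trait_series: list[TraitSeries]
    braak_scores: pd.Series
    ages: pd.Series
    ventricle_series: dict[str, list[tuple[float, float]]]
    covariates: pd.DataFrame  # age, sex, baseline_status per individual
    ground_truth: GroundTruth = field(default_factory=GroundTruth)


def gen_genotypes_and_traits(
    annotation: Annotation,
    n_individuals: int = 500,
    n_snps: int = 50,
    epistatic_pairs: list[PlantedPair] | None = None,
    trait_registry: tuple[str, ...] = TRAIT_REGISTRY,
    missing_rate: float = 0.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticCohort:
    """Cohort genotypes under Hardy-Weinberg sampling plus phenotypes.

    SNP positions are drawn uniformly over the chromosome span so that some
    fall inside gene bodies (within the 5 kb margin) and some in intergenic
    stretches.  The quantitative scan phenotype follows
    ``y = b0 + sum(bA*gA + bB*gB + bAB*gA*gB) + N(0, noise_sd)`` over the
    planted pairs.  Longitudinal trait series, age-trending Braak-like scores
    and covariate-confounded ventricular-volume series are generated for the
    phenotype-derivation operations.
    """
    if n_individuals < 10:
        raise ValueError("n_individuals must be >= 10 (degenerate regression below)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    epistatic_pairs = list(epistatic_pairs or [])

    rng = np.random.default_rng(seed)
    span_end = max(g.end for g in annotation.genes) + 30_000
    positions = np.sort(rng.integers(1, span_end, size=n_snps))
    mafs = rng.uniform(0.1, 0.5, size=n_snps)
    snps = [
        SnpRecord(
            snp_id=f"rs{i + 1:06d}",
            chromosome="1",
            position=int(positions[i]),
            maf=float(mafs[i]),
        )
        for i in range(n_snps)
    ]
    snp_ids = [s.snp_id for s in snps]
    known = set(snp_ids)
    for p in epistatic_pairs:
        if p.snp_a not in known or p.snp_b not in known:
            raise ValueError("planted pair references unknown SNP")
        if not (np.isfinite(p.beta_ab) and np.isfinite(p.beta_a) and np.isfinite(p.beta_b)):
            raise ValueError("planted effect sizes must be finite")

    individuals = [f"IND{i + 1:04d}" for i in range(n_individuals)]
    dos = rng.binomial(2, mafs[None, :], size=(n_individuals, n_snps)).astype(float)
    if missing_rate > 0:
        mask = rng.random(size=dos.shape) < missing_rate
        dos[mask] = np.nan
    dosages = pd.DataFrame(dos, index=individuals, columns=snp_ids)
    genotypes = GenotypeMatrix(individuals=individuals, snps=snps, dosages=dosages)

    # Quantitative scan phenotype (missing dosages treated as 0 contribution
    # for generation; the scan itself does pairwise complete-case analysis).
    y = rng.normal(0.0, noise_sd, size=n_individuals)
    filled = np.nan_to_num(dos, nan=0.0)
    col = {s: j for j, s in enumerate(snp_ids)}
    for p in epistatic_pairs:
        ga, gb = filled[:, col[p.snp_a]], filled[:, col[p.snp_b]]
        y = y + p.beta_a * ga + p.beta_b * gb + p.beta_ab * ga * gb
    phenotype = pd.Series(y, index=individuals, name="composite")

    # Longitudinal cognitive trait series: per-individual random baseline and
    # trend, 1-6 visits at irregular times.
    trait_series: list[TraitSeries] = []
    for trait in trait_registry:
        base_mu = rng.normal(20.0, 5.0)
        for ind in individuals:
            k = int(rng.integers(1, 7))
            times = np.sort(rng.uniform(0.0, 5.0, size=k))
            times = np.unique(np.round(times, 3))
            b = rng.normal(base_mu, 3.0)
            s = rng.normal(0.0, 1.0)
            values = b + s * times + rng.normal(0.0, 0.5, size=len(times))
            trait_series.append(
                TraitSeries(
                    individual=ind,
                    trait=trait,
                    observations=list(zip(times.tolist(), values.tolist())),
                )
            )

    # Braak-like ordinal score with a smooth age trend.
    ages = pd.Series(rng.uniform(60.0, 95.0, size=n_individuals), index=individuals, name="age")
    braak_raw = 1.0 + 0.12 * (ages - 60.0) + rng.normal(0.0, 0.8, size=n_individuals)
    braak = pd.Series(
        np.clip(np.round(braak_raw), 1, 6).astype(int), index=individuals, name="braak"
    )

    # Ventricular-volume series confounded by age, sex and baseline status.
    sex = rng.integers(0, 2, size=n_individuals)
    status = rng.integers(0, 2, size=n_individuals)
    covariates = pd.DataFrame(
        {"age": ages.to_numpy(), "sex": sex, "baseline_status": status},
        index=individuals,
    )
    ventricle: dict[str, list[tuple[float, float]]] = {}
    slopes = (
        0.08 * (ages.to_numpy() - 75.0)
        + 2.0 * sex
        + 4.0 * status
        + rng.normal(0.0, 1.0, size=n_individuals)
    )
    for i, ind in enumerate(individuals):
        k = int(rng.integers(1, 5))
        times = np.sort(rng.uniform(0.0, 3.0, size=k))
        times = np.unique(np.round(times, 3))
        vols = 40.0 + slopes[i] * times + rng.normal(0.0, 0.3, size=len(times))
        ventricle[ind] = list(zip(times.tolist(), vols.tolist()))

    truth = GroundTruth(
        epistatic_pairs=[(p.snp_a, p.snp_b, p.beta_ab) for p in epistatic_pairs]
    )
    return SyntheticCohort(
        genotypes=genotypes,
        phenotype=phenotype,
        trait_series=trait_series,
        braak_scores=braak,
        ages=ages,
        ventricle_series=ventricle,
        covariates=covariates,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# PPI lists, GWAS and positive-selection tables
# ---------------------------------------------------------------------------


@dataclass
class OmicsTables:
    """PPI edge lists plus the two node-attribute input tables."""

    ppi: pd.DataFrame  # protein_a, protein_b, score, score_kind (pbs|mi), source
    gwas: pd.DataFrame  # snp_id, ensg, p
    positive_selection: pd.DataFrame  # ensg, p
    ground_truth: GroundTruth = field(default_factory=GroundTruth)


def gen_ppi_and_tables(
    annotation: Annotation,
    n_ppi: int = 60,
    pbs_fraction: float = 0.3,
    gwas_n_snps: int = 100,
    gwas_signal_fraction: float = 0.3,
    ps_n_genes: int = 10,
    seed: int = 0,
) -> OmicsTables:
    """Protein interaction lists and GWAS / positive-selection tables.

    ``pbs_fraction`` of PPI edges carry yeast two-hybrid PBS scores in
    [0, 10]; the rest carry curated-database MI confidence scores in [0, 1].
    Pseudogene-mapped proteins are eligible partners, exercising the
    pseudogene filter downstream.  GWAS "signal" SNPs (a
    ``gwas_signal_fraction`` share, recorded in the ground truth) get
    p-values below 0.05; background SNPs are uniform on (0, 1].
    """
    for frac in (pbs_fraction, gwas_signal_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = sorted(annotation.protein_map)
    if len(proteins) < 2:
        raise ValueError("annotation must map at least two proteins")

    rows = []
    n_pbs = int(round(pbs_fraction * n_ppi))
    for k in range(n_ppi):
        a, b = rng.choice(len(proteins), size=2, replace=False)
        if k < n_pbs:
            score, kind, source = float(rng.uniform(0.0, 10.0)), "pbs", "PBA"
        else:
            score = float(rng.uniform(0.0, 1.0))
            kind = "mi"
            source = str(rng.choice(["IAH", "ADIA", "SIA"]))
        rows.append((proteins[a], proteins[b], score, kind, source))
    ppi = pd.DataFrame(rows, columns=["protein_a", "protein_b", "score", "score_kind", "source"])

    ensgs = annotation.ensg_ids
    n_signal = int(round(gwas_signal_fraction * gwas_n_snps))
    signal = np.zeros(gwas_n_snps, dtype=bool)
    signal[:n_signal] = True
    p_vals = np.where(
        signal,
        rng.uniform(1e-8, 0.05, size=gwas_n_snps),
        rng.uniform(0.05, 1.0, size=gwas_n_snps),
    )
    gwas = pd.DataFrame(
        {
            "snp_id": [f"rsG{i + 1:06d}" for i in range(gwas_n_snps)],
            "ensg": rng.choice(ensgs, size=gwas_n_snps),
            "p": p_vals,
        }
    )
    ps_genes = rng.choice(ensgs, size=min(ps_n_genes, len(ensgs)), replace=False)
    ps = pd.DataFrame({"ensg": ps_genes, "p": rng.uniform(1e-6, 0.05, size=len(ps_genes))})
    truth = GroundTruth(gwas_signal_snps=gwas.loc[signal, "snp_id"].tolist())
    return OmicsTables(ppi=ppi, gwas=gwas, positive_selection=ps, ground_truth=truth)


# ---------------------------------------------------------------------------
# Prioritization scenario (use-case testbed)
# ---------------------------------------------------------------------------


def gen_prioritization_scenario(
    n_nodes: int = 300,
    n_positive: int = 60,
    n_negative: int = 60,
    edges_per_node: int = 4,
    assortativity: float = 0.8,
    n_regions: int = 231,
    bio_effect: float = 0.5,
    bio_signal_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Synthetic graph + region Z-table where disease genes cluster.

    Positive (disease-associated) nodes preferentially attach to other
    positives with probability ``assortativity``, so neighborhood label
    fractions are informative.  Only ``bio_signal_fraction`` of positives
    carry an elevated disease-region Z profile (strength ``bio_effect``),
    making the biological block deliberately weaker than the graph block.

    Returns (edge frame with interaction types, region Z-table, ground truth).
    """
    rng = np.random.default_rng(seed)
    nodes = [f"ENSG{i + 1:011d}" for i in range(n_nodes)]
    positives = list(rng.choice(nodes, size=n_positive, replace=False))
    rest = [n for n in nodes if n not in set(positives)]
    negatives = list(rng.choice(rest, size=n_negative, replace=False))
    pos_set = set(positives)

    edge_rows = []
    types = ("PPI", "co-expression", "epistasis")
    sources = {"PPI": "IAH", "co-expression": "ADN", "epistasis": "TGEN"}
    for node in nodes:
        for _ in range(edges_per_node):
            if node in pos_set and rng.random() < assortativity:
                partner = positives[int(rng.integers(len(positives)))]
            else:
                partner = nodes[int(rng.integers(n_nodes))]
            if partner == node:
                continue
            t = types[int(rng.integers(3))]
            score = float(rng.uniform(0.5, 1.0)) if t != "epistasis" else float(
                rng.uniform(1e-12, 1e-8)
            )
            a, b = sorted((node, partner))
            edge_rows.append((a, b, score, t, sources[t]))
    edges = pd.DataFrame(
        edge_rows, columns=["ensg_a", "ensg_b", "score", "interaction_type", "data_source"]
    ).drop_duplicates(subset=["ensg_a", "ensg_b", "interaction_type"])

    regions = default_regions(n_regions)
    z = rng.normal(size=(n_nodes, n_regions))
    n_bio = int(round(bio_signal_fraction * n_positive))
    bio_genes = positives[:n_bio]
    didx = [regions.index(r) for r in DISEASE_REGIONS]
    for g in bio_genes:
        z[nodes.index(g)][didx] += bio_effect
    ztable = pd.DataFrame(z, index=pd.Index(nodes, name="ensg"), columns=regions)
    truth = GroundTruth(
        positive_genes=positives,
        negative_genes=negatives,
        disease_region_genes=bio_genes,
    )
    return edges, ztable, truth
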