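"""Pairwise-SNP epistasis scan with genic/intergenic binning.

An epistatic interaction is a departure from additivity of two loci's
effects on a quantitative phenotype.  For SNPs with dosages gA, gB in
{0, 1, 2} the model is

    y = b0 + bA*gA + bB*gB + bAB*gA*gB + e

fitted by OLS; the interaction is assessed by the F test of bAB against the
null of no effect, with (1, n-4) degrees of freedom (equal to the squared t
of the coefficient).

SNPs are aggregated into *bins*: a genic bin is a gene extended by a 5 kb
margin on each side (a SNP inside several overlapping genes joins each); a
SNP outside all genic bins joins exactly one intergenic region (IGR)
delimited by its two flanking genes.  Multiple testing is controlled
region-wise: for a bin pair with m and n member SNPs the per-pair critical
level is alpha / (m*n).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .synthdata import Annotation
from .types import GeneModel, GenotypeMatrix, SnpRecord, TraitSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phenotype derivation and adjustment
# ---------------------------------------------------------------------------


def derive_trait_values(series: list[TraitSeries]) -> pd.DataFrame:
    """Latest value and regression slope per (individual, trait).

    For each longitudinal cognitive trait, two derived phenotypes: the last
    assessed value (``<trait>_latest``) and the OLS slope of value on time
    (``<trait>_slope``; missing for individuals with a single visit).
    Returns a frame indexed by individual with one column per derived
    phenotype.
    """
    records: dict[tuple[str, str], dict[str, float]] = {}
    for ts in series:
        times = np.array([t for t, _ in ts.observations])
        vals = np.array([v for _, v in ts.observations])
        latest = float(vals[-1])
        slope = float(np.polyfit(times, vals, 1)[0]) if len(times) >= 2 else np.nan
        records[(ts.individual, ts.trait)] = {"latest": latest, "slope": slope}

    individuals = sorted({i for i, _ in records})
    traits = sorted({t for _, t in records})
    data = {}
    for trait in traits:
        data[f"{trait}_latest"] = [
            records.get((ind, trait), {}).get("latest", np.nan) for ind in individuals
        ]
        data[f"{trait}_slope"] = [
            records.get((ind, trait), {}).get("slope", np.nan) for ind in individuals
        ]
    return pd.DataFrame(data, index=pd.Index(individuals, name="individual"))


def adjust_braak(
    scores: pd.Series, ages: pd.Series, span: float = 0.75
) -> pd.Series:
    """Age-adjusted Braak-stage phenotype.

    Braak staging (ordinal 1-6 severity of Alzheimer-type neuropathology)
    increases with age even in cognitively normal individuals; the age trend
    is estimated by loess regression (default span 0.75) and subtracted.
    Falls back to mean-centering when all ages coincide.
    """
    scores, ages = scores.align(ages, join="inner")
    if len(scores) < 10:
        raise ValueError("need n >= 10 for loess adjustment")
    s = scores.to_numpy(dtype=float)
    a = ages.to_numpy(dtype=float)
    if not ((s >= 1) & (s <= 6)).all():
        raise ValueError("Braak scores must lie in [1, 6]")
    if np.ptp(a) == 0:
        logger.warning("all ages identical; falling back to mean-centering")
        fitted = np.full_like(s, s.mean())
    else:
        fitted = lowess(s, a, frac=span, return_sorted=False)
    out = pd.Series(s - fitted, index=scores.index, name="braak_adjusted")
    return out


def adjust_ventricle(
    series: dict[str, list[tuple[float, float]]],
    covariates: pd.DataFrame,
) -> pd.Series:
    """Covariate-adjusted rate of ventricular-volume change.

    Stage 1: per-individual OLS slope of volume on time (individuals with
    fewer than two time points are excluded, logged).  Stage 2: the slopes
    are regressed on age, sex and baseline disease status; the residuals —
    ventricle variation unexplained by these covariates — are the phenotype.
    """
    slopes = {}
    n_excluded = 0
    for ind, obs in series.items():
        if len(obs) < 2:
            n_excluded += 1
            continue
        t = np.array([x for x, _ in obs])
        v = np.array([y for _, y in obs])
        slopes[ind] = float(np.polyfit(t, v, 1)[0])
    if n_excluded:
        logger.info("excluded %d individuals with <2 time points", n_excluded)
    if not slopes:
        raise ValueError("no individual has >= 2 time points")

    idx = [i for i in covariates.index if i in slopes]
    y = np.array([slopes[i] for i in idx])
    X = covariates.loc[idx, ["age", "sex", "baseline_status"]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(idx)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=pd.Index(idx, name="individual"), name="ventricle_slope_residual")


# ---------------------------------------------------------------------------
# Genotype quality control
# ---------------------------------------------------------------------------


def hwe_chisq_p(dosages: np.ndarray) -> float:
    """Hardy-Weinberg 1-df chi-square p-value from 0/1/2 genotype counts."""
    d = dosages[~np.isnan(dosages)]
    n = len(d)
    if n == 0:
        return 1.0
    n_aa = int((d == 0).sum())
    n_ab = int((d == 1).sum())
    n_bb = int((d == 2).sum())
    p = (2 * n_bb + n_ab) / (2 * n)
    q = 1.0 - p
    exp = np.array([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = exp > 0
    stat = float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    return float(stats.chi2.sf(stat, df=1))


def qc_filter(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.1,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-3,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Marker-level quality control.

    Excludes SNPs whose missing-genotype fraction exceeds ``max_missing``,
    whose empirical minor allele frequency falls below ``min_maf``, or whose
    genotype counts deviate from Hardy-Weinberg equilibrium at
    ``p <= hwe_alpha`` (1-df chi-square).  Returns the filtered matrix plus a
    report of exclusions with reasons.
    """
    reasons = []
    keep = []
    dos = genotypes.dosages
    for snp in genotypes.snps:
        col = dos[snp.snp_id].to_numpy(dtype=float)
        miss = float(np.isnan(col).mean())
        if miss > max_missing:
            reasons.append((snp.snp_id, "missing", miss))
            continue
        observed = col[~np.isnan(col)]
        if len(observed) == 0:
            reasons.append((snp.snp_id, "missing", 1.0))
            continue
        af = observed.mean() / 2.0
        maf = min(af, 1.0 - af)
        if maf < min_maf:
            reasons.append((snp.snp_id, "maf", maf))
            continue
        p_hwe = hwe_chisq_p(col)
        if p_hwe <= hwe_alpha:
            reasons.append((snp.snp_id, "hwe", p_hwe))
            continue
        keep.append(snp.snp_id)
    report = pd.DataFrame(reasons, columns=["snp_id", "reason", "value"])
    if not keep:
        raise ValueError("all SNPs removed by quality control")
    return genotypes.subset_snps(keep), report


def empirical_maf(dosages: np.ndarray) -> float:
    d = dosages[~np.isnan(dosages)]
    if len(d) == 0:
        return 0.0
    af = d.mean() / 2.0
    return float(min(af, 1.0 - af))


# ---------------------------------------------------------------------------
# The interaction test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpistasisResult:
    snp_a: str
    snp_b: str
    beta_interaction: float
    f_statistic: float
    p_value: float
    n: int
    bin_a: str | None = None
    bin_b: str | None = None


def epistasis_test(
    g_a: np.ndarray, g_b: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, int] | None:
    """Test the multiplicative term of ``y ~ 1 + gA + gB + gA*gB``.

    Missing dosages or phenotype values are removed pairwise (complete-case).
    Returns (beta_interaction, F, p, n) or None when the design is
    degenerate (fewer than 5 complete cases, a constant dosage vector, or a
    collinear interaction column).  F is the squared t statistic of the
    interaction coefficient with (1, n-4) df; p is its upper-tail
    probability.
    """
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(g_a) | np.isnan(g_b) | np.isnan(y))
    g_a, g_b, y = g_a[ok], g_b[ok], y[ok]
    n = len(y)
    if n < 5:
        return None
    if np.ptp(g_a) == 0 or np.ptp(g_b) == 0:
        return None
    X = np.column_stack([np.ones(n), g_a, g_b, g_a * g_b])
    XtX = X.T @ X
    # collinear design (e.g. interaction column in the span of main effects)
    if np.linalg.matrix_rank(XtX) < 4:
        return None
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - 4
    if dof <= 0:
        return None
    sigma2 = float(resid @ resid) / dof
    if sigma2 == 0:
        # perfect fit: infinitely significant interaction if beta3 != 0
        if beta[3] == 0:
            return None
        return float(beta[3]), float("inf"), 0.0, n
    se = np.sqrt(sigma2 * XtX_inv[3, 3])
    t = beta[3] / se
    f = float(t * t)
    p = float(stats.f.sf(f, 1, dof))
    return float(beta[3]), f, max(p, np.nextafter(0, 1)), n


def scan_pairs(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    maf_product_min: float = 0.01,
    p_threshold: float = 1e-5,
) -> list[EpistasisResult]:
    """Exhaustive pairwise interaction scan over a QC'd genotype panel.

    Pairs whose MAF product is not greater than ``maf_product_min`` are
    skipped before testing.  Results with p < ``p_threshold`` are returned
    sorted ascending by p-value.
    """
    y = phenotype.reindex(genotypes.individuals).to_numpy(dtype=float)
    dos = genotypes.dosages.to_numpy(dtype=float)
    snp_ids = genotypes.snp_ids
    mafs = np.array([empirical_maf(dos[:, j]) for j in range(dos.shape[1])])
    results: list[EpistasisResult] = []
    for i, j in itertools.combinations(range(len(snp_ids)), 2):
        if mafs[i] * mafs[j] <= maf_product_min:
            continue
        core = epistasis_test(dos[:, i], dos[:, j], y)
        if core is None:
            continue
        beta, f, p, n = core
        if p < p_threshold:
            results.append(
                EpistasisResult(
                    snp_a=snp_ids[i], snp_b=snp_ids[j],
                    beta_interaction=beta, f_statistic=f, p_value=p, n=n,
                )
            )
    results.sort(key=lambda r: (r.p_value, r.snp_a, r.snp_b))
    return results


# ---------------------------------------------------------------------------
# Genic / intergenic bin mapping
# ---------------------------------------------------------------------------

#: Sentinel flank for intergenic regions at chromosome ends.
TERMINAL = "TELOMERE"


@dataclass(frozen=True)
class BinAssignment:
    bin_id: str
    kind: str  # "genic" | "igr"


def map_snps_to_bins(
    snps: list[SnpRecord],
    annotation: Annotation | list[GeneModel],
    margin: int = 5000,
) -> dict[str, list[BinAssignment]]:
    """Assign each SNP to genic bins or one intergenic region.

    A SNP within ``[start - margin, end + margin]`` of a gene (boundaries
    inclusive) is assigned to that gene's ENSG bin — to every such gene when
    genes overlap.  A SNP outside all genic bins joins the unique IGR
    ``ENSGC-ENSGD`` named by its flanking genes in coordinate order;
    chromosome-terminal SNPs get a terminal IGR with a sentinel flank.
    SNPs on chromosomes without genes are left unassigned (logged).
    """
    genes = annotation.genes if isinstance(annotation, Annotation) else annotation
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.start, g.end))

    out: dict[str, list[BinAssignment]] = {}
    for snp in snps:
        chrom_genes = by_chrom.get(snp.chromosome)
        if not chrom_genes:
            logger.warning("SNP %s on chromosome without genes; unassigned", snp.snp_id)
            out[snp.snp_id] = []
            continue
        pos = snp.position
        genic = [
            g for g in chrom_genes if g.start - margin <= pos <= g.end + margin
        ]
        if genic:
            out[snp.snp_id] = [BinAssignment(g.ensg_id, "genic") for g in genic]
            continue
        # intergenic: flanking genes by extended-boundary position
        left = [g for g in chrom_genes if g.end + margin < pos]
        right = [g for g in chrom_genes if g.start - margin > pos]
        left_id = max(left, key=lambda g: g.end).ensg_id if left else TERMINAL
        right_id = min(right, key=lambda g: g.start).ensg_id if right else TERMINAL
        out[snp.snp_id] = [BinAssignment(f"{left_id}-{right_id}", "igr")]
    return out


def bin_members(
    assignments: dict[str, list[BinAssignment]]
) -> dict[str, set[str]]:
    """Invert SNP -> bin assignments into bin -> member SNP sets."""
    members: dict[str, set[str]] = {}
    for snp_id, bins in assignments.items():
        for b in bins:
            members.setdefault(b.bin_id, set()).add(snp_id)
    return members


def binwise_bonferroni(
    results: list[EpistasisResult],
    assignments: dict[str, list[BinAssignment]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region-wise Bonferroni reporting of bin-pair interactions.

    For a bin pair (A, B) with m and n member SNPs the critical level is
    ``alpha / (m * n)``.  A bin pair is reported when any of its member
    SNP-pair p-values falls below that threshold; the reported score is the
    minimum member p-value.  Gene-gene rows are typed ``epistasis``; rows
    touching an intergenic bin are typed ``IGRI``.
    """
    members = bin_members(assignments)
    kind_of = {
        b.bin_id: b.kind for bins in assignments.values() for b in bins
    }
    best: dict[tuple[str, str], float] = {}
    for res in results:
        bins_a = assignments.get(res.snp_a)
        bins_b = assignments.get(res.snp_b)
        if not bins_a or not bins_b:
            raise ValueError(
                f"result SNP pair ({res.snp_a}, {res.snp_b}) lacks bin assignments"
            )
        for ba in bins_a:
            for bb in bins_b:
                key = tuple(sorted((ba.bin_id, bb.bin_id)))
                if key[0] == key[1]:
                    continue  # within-bin pair is not a network edge
                best[key] = min(best.get(key, np.inf), res.p_value)

    rows = []
    for (bin_a, bin_b), p_min in sorted(best.items(), key=lambda kv: kv[1]):
        m = len(members[bin_a])
        n = len(members[bin_b])
        threshold = alpha / (m * n)
        if p_min < threshold:
            itype = (
                "epistasis"
                if kind_of[bin_a] == "genic" and kind_of[bin_b] == "genic"
                else "IGRI"
            )
            rows.append((bin_a, bin_b, p_min, threshold, m, n, itype))
    return pd.DataFrame(
        rows,
        columns=["bin_a", "bin_b", "p_value", "threshold", "m_snps", "n_snps", "interaction_type"],
    )


def results_frame(
    results: list[EpistasisResult],
    assignments: dict[str, list[BinAssignment]] | None = None,
) -> pd.DataFrame:
    """Flatten scan results to the TSV-ready schema."""
    rows = []
    for r in results:
        if assignments is not None:
            bins_a = ";".join(b.bin_id for b in assignments.get(r.snp_a, []))
            bins_b = ";".join(b.bin_id for b in assignments.get(r.snp_b, []))
        else:
            bins_a = bins_b = ""
        rows.append(
            (r.snp_a, r.snp_b, bins_a, bins_b, r.beta_interaction, r.f_statistic, r.p_value)
        )
    return pd.DataFrame(
        rows, columns=["snp_a", "snp_b", "bin_a", "bin_b", "beta", "F", "p"]
    )
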