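"""Phenotype derivation, QC, the interaction F-test and bin mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adnet import epistasis, synthdata
from adnet.epistasis import (
    BinAssignment,
    EpistasisResult,
    adjust_braak,
    adjust_ventricle,
    bin_members,
    binwise_bonferroni,
    derive_trait_values,
    epistasis_test,
    hwe_chisq_p,
    map_snps_to_bins,
    qc_filter,
    scan_pairs,
)
from adnet.types import GeneModel, GenotypeMatrix, SnpRecord, TraitSeries


def anova_f_oracle(g_a, g_b, y):
    """Full-vs-reduced sum-of-squares F test for the interaction term."""
    g_a, g_b, y = map(np.asarray, (g_a, g_b, y))
    n = len(y)
    X_red = np.column_stack([np.ones(n), g_a, g_b])
    X_full = np.column_stack([X_red, g_a * g_b])
    rss = []
    for X in (X_red, X_full):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(float(r @ r))
    df2 = n - 4
    f = (rss[0] - rss[1]) / (rss[1] / df2)
    return f, float(stats.f.sf(f, 1, df2))


class TestTraitDerivation:
    def test_exact_line(self):
        ts = TraitSeries("I1", "MMSE", [(0, 1), (1, 3), (2, 5)])
        out = derive_trait_values([ts])
        assert out.loc["I1", "MMSE_latest"] == 5
        assert out.loc["I1", "MMSE_slope"] == pytest.approx(2.0)

    def test_single_observation_slope_missing(self):
        out = derive_trait_values([TraitSeries("I1", "FAQ", [(4, 7.5)])])
        assert out.loc["I1", "FAQ_latest"] == 7.5
        assert np.isnan(out.loc["I1", "FAQ_slope"])

    def test_full_registry_yields_46_columns(self, genotype_cohort):
        out = derive_trait_values(genotype_cohort.trait_series)
        assert out.shape[1] == 46
        assert out.shape[1] == 2 * len(synthdata.TRAIT_REGISTRY)


class TestBraakAdjustment:
    def test_age_independent_scores_stay_centered(self):
        rng = np.random.default_rng(0)
        n = 200
        ages = pd.Series(rng.uniform(60, 95, n))
        # age-independent scores; the loess fit should be ~flat at the mean
        # (its local wiggle scales with the score sd, so use a moderate spread)
        scores = pd.Series(rng.integers(3, 5, n).astype(float))
        resid = adjust_braak(scores, ages)
        centered = scores - scores.mean()
        assert np.max(np.abs(resid.to_numpy() - centered.to_numpy())) < 0.2

    def test_exact_linear_trend_removed(self):
        rng = np.random.default_rng(1)
        ages = pd.Series(rng.uniform(60, 95, 150))
        scores = 1.0 + (ages - 60) / 7.0  # exactly linear, inside [1, 6]
        resid = adjust_braak(scores, ages)
        assert np.max(np.abs(resid)) < 0.05

    def test_constant_scores_zero_residuals(self):
        rng = np.random.default_rng(2)
        ages = pd.Series(rng.uniform(60, 95, 50))
        resid = adjust_braak(pd.Series(np.full(50, 3.0)), ages)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_identical_ages_fall_back_to_centering(self):
        scores = pd.Series([1.0, 2, 3, 4, 5, 6, 1, 2, 3, 4])
        resid = adjust_braak(scores, pd.Series(np.full(10, 70.0)))
        assert np.allclose(resid, scores - scores.mean())


class TestVentricleAdjustment:
    @staticmethod
    def _covariates(n, rng):
        return pd.DataFrame(
            {
                "age": rng.uniform(60, 90, n),
                "sex": rng.integers(0, 2, n),
                "baseline_status": rng.integers(0, 2, n),
            },
            index=[f"I{i}" for i in range(n)],
        )

    def test_orthogonal_covariates_give_centered_slopes(self):
        rng = np.random.default_rng(3)
        n = 40
        cov = self._covariates(n, rng)
        slopes = rng.normal(size=n)
        series = {
            f"I{i}": [(0.0, 10.0), (1.0, 10.0 + slopes[i])] for i in range(n)
        }
        resid = adjust_ventricle(series, cov)
        # residuals of y on covariates are y minus its projection; with
        # covariates independent of the slopes the fit reduces to ~ the mean
        assert abs(resid.mean()) < 1e-10
        r = np.corrcoef(resid, slopes - slopes.mean())[0, 1]
        assert r > 0.9

    def test_planted_age_effect_removed(self):
        rng = np.random.default_rng(4)
        n = 300
        cov = self._covariates(n, rng)
        slopes = 3.0 * cov["age"].to_numpy() + rng.normal(0, 1, n)
        series = {
            f"I{i}": [(0.0, 40.0), (2.0, 40.0 + 2 * slopes[i])] for i in range(n)
        }
        resid = adjust_ventricle(series, cov)
        assert abs(np.corrcoef(resid, cov["age"])[0, 1]) < 0.1

    def test_short_series_excluded(self):
        rng = np.random.default_rng(5)
        cov = self._covariates(3, rng)
        series = {"I0": [(0.0, 1.0)], "I1": [(0, 1.0), (1, 2.0)], "I2": [(0, 1.0), (1, 3.0)]}
        resid = adjust_ventricle(series, cov)
        assert "I0" not in resid.index and len(resid) == 2


def _matrix_from(dosages: dict[str, list[float]], mafs=None) -> GenotypeMatrix:
    n = len(next(iter(dosages.values())))
    individuals = [f"I{i}" for i in range(n)]
    snps = [
        SnpRecord(s, "1", 100 + k, 0.3 if mafs is None else mafs[k])
        for k, s in enumerate(dosages)
    ]
    return GenotypeMatrix(
        individuals=individuals,
        snps=snps,
        dosages=pd.DataFrame(dosages, index=individuals, dtype=float),
    )


class TestQcFilter:
    def test_exact_hwe_retained(self):
        counts = [0.0] * 25 + [1.0] * 50 + [2.0] * 25
        assert hwe_chisq_p(np.array(counts)) == pytest.approx(1.0)
        gm = _matrix_from({"s1": counts})
        kept, report = qc_filter(gm)
        assert kept.snp_ids == ["s1"] and report.empty

    def test_low_maf_excluded(self):
        # MAF 0.04 in 50 individuals: 4 heterozygotes
        low = [1.0] * 4 + [0.0] * 96
        ok = [0.0] * 25 + [1.0] * 50 + [2.0] * 25
        gm = _matrix_from({"s_low": low, "s_ok": ok})
        kept, report = qc_filter(gm)
        assert kept.snp_ids == ["s_ok"]
        assert report.set_index("snp_id").loc["s_low", "reason"] == "maf"

    def test_high_missingness_excluded(self):
        miss = [np.nan] * 20 + ([0.0] * 20 + [1.0] * 40 + [2.0] * 20)
        ok = [0.0] * 25 + [1.0] * 50 + [2.0] * 25
        gm = _matrix_from({"s_miss": miss, "s_ok": ok})
        kept, report = qc_filter(gm)
        assert kept.snp_ids == ["s_ok"]
        assert report.set_index("snp_id").loc["s_miss", "reason"] == "missing"

    def test_hwe_violation_excluded(self):
        # all heterozygotes: gross departure from HWE
        het = [1.0] * 100
        ok = [0.0] * 25 + [1.0] * 50 + [2.0] * 25
        gm = _matrix_from({"s_het": het, "s_ok": ok})
        kept, report = qc_filter(gm)
        assert kept.snp_ids == ["s_ok"]
        assert report.set_index("snp_id").loc["s_het", "reason"] == "hwe"

    def test_all_removed_raises(self):
        gm = _matrix_from({"s1": [1.0] * 50})
        with pytest.raises(ValueError, match="all SNPs removed"):
            qc_filter(gm)


class TestEpistasisTest:
    def _genotypes(self, rng, n, maf=0.3):
        return rng.binomial(2, maf, n).astype(float), rng.binomial(2, maf, n).astype(float)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            g_a, g_b = self._genotypes(rng, 80)
            y = 0.3 * g_a - 0.2 * g_b + 0.4 * g_a * g_b + rng.normal(size=80)
            beta, f, p, n = epistasis_test(g_a, g_b, y)
            f_o, p_o = anova_f_oracle(g_a, g_b, y)
            assert f == pytest.approx(f_o, rel=1e-10)
            assert p == pytest.approx(p_o, rel=1e-10)

    def test_affine_invariance_of_y(self):
        rng = np.random.default_rng(7)
        g_a, g_b = self._genotypes(rng, 100)
        y = g_a * g_b + rng.normal(size=100)
        b1, f1, p1, _ = epistasis_test(g_a, g_b, y)
        b2, f2, p2, _ = epistasis_test(g_a, g_b, 3.0 * y - 5.0)
        assert f2 == pytest.approx(f1, rel=1e-9)
        assert p2 == pytest.approx(p1, rel=1e-9)
        assert b2 == pytest.approx(3.0 * b1, rel=1e-9)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(8)
        g_a, g_b = self._genotypes(rng, 100)
        y = g_a + 0.5 * g_a * g_b + rng.normal(size=100)
        r1 = epistasis_test(g_a, g_b, y)
        r2 = epistasis_test(g_b, g_a, y)
        assert r1[1] == pytest.approx(r2[1], rel=1e-10)
        assert r1[2] == pytest.approx(r2[2], rel=1e-10)

    def test_null_pvalues_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(200):
            g_a, g_b = self._genotypes(rng, 1000)
            y = g_a + g_b + rng.normal(size=1000)
            _, _, p, _ = epistasis_test(g_a, g_b, y)
            rejections += p < 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_recovers_planted_multiplicative_effect(self):
        rng = np.random.default_rng(10)
        g_a, g_b = self._genotypes(rng, 200)
        y = g_a * g_b + rng.normal(0, 0.1, 200)
        beta, _, p, _ = epistasis_test(g_a, g_b, y)
        assert abs(beta - 1.0) < 0.1
        assert p < 1e-8

    def test_degenerate_inputs_return_none(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, 50).astype(float)
        y = rng.normal(size=50)
        assert epistasis_test(np.zeros(50), g, y) is None  # constant SNP
        assert epistasis_test(g[:4], g[:4], y[:4]) is None  # too few cases

    def test_missing_dosages_complete_case(self):
        rng = np.random.default_rng(12)
        g_a, g_b = self._genotypes(rng, 120)
        y = g_a * g_b + rng.normal(size=120)
        g_a_miss = g_a.copy()
        g_a_miss[:20] = np.nan
        res = epistasis_test(g_a_miss, g_b, y)
        ref = epistasis_test(g_a[20:], g_b[20:], y[20:])
        assert res[1] == pytest.approx(ref[1], rel=1e-12)
        assert res[3] == 100


class TestScanPairs:
    def test_maf_product_prefilter(self):
        rng = np.random.default_rng(13)
        n = 200
        # MAFs 0.05 and 0.1: product 0.005 <= 0.01 -> skipped
        d1 = rng.binomial(2, 0.05, n).astype(float)
        d2 = rng.binomial(2, 0.1, n).astype(float)
        d3 = rng.binomial(2, 0.4, n).astype(float)
        gm = _matrix_from({"a": list(d1), "b": list(d2), "c": list(d3)})
        pheno = pd.Series(rng.normal(size=n), index=gm.individuals)
        res = scan_pairs(gm, pheno, p_threshold=1.0)
        tested = {(r.snp_a, r.snp_b) for r in res}
        assert ("a", "b") not in tested

    def test_threshold_one_returns_all_tested(self, genotype_cohort):
        gm, _ = qc_filter(genotype_cohort.genotypes)
        res = scan_pairs(gm, genotype_cohort.phenotype, p_threshold=1.0)
        mafs = {s.snp_id: s for s in gm.snps}
        assert len(res) > 0
        assert all(r.p_value <= 1.0 for r in res)
        ps = [r.p_value for r in res]
        assert ps == sorted(ps)

    def test_planted_pair_ranked_first_across_seeds(self, annotation):
        hits = 0
        for seed in range(10):
            cohort = synthdata.gen_genotypes_and_traits(
                annotation, n_individuals=500, n_snps=50,
                epistatic_pairs=[synthdata.PlantedPair("rs000001", "rs000002", 1.0)],
                noise_sd=0.5, seed=seed,
            )
            gm, _ = qc_filter(cohort.genotypes)
            res = scan_pairs(gm, cohort.phenotype, p_threshold=1.0)
            top = {res[0].snp_a, res[0].snp_b}
            hits += top == {"rs000001", "rs000002"}
        assert hits >= 9


def _gene(ensg, start, end):
    return GeneModel(ensg, ensg.replace("ENSG", "G"), "1", start, end, "protein_coding")


class TestBinMapping:
    def test_margin_boundary_inclusive(self):
        genes = [_gene("ENSG1", 10_000, 20_000)]
        snp = SnpRecord("s1", "1", 5_000, 0.3)
        out = map_snps_to_bins([snp], genes, margin=5000)
        assert out["s1"] == [BinAssignment("ENSG1", "genic")]

    def test_just_outside_margin_is_intergenic(self):
        genes = [_gene("ENSGUP", 1_000, 2_000), _gene("ENSG1", 10_000, 20_000)]
        snp = SnpRecord("s1", "1", 4_999, 0.3)  # 1 bp outside the 5 kb margin
        out = map_snps_to_bins([snp], genes, margin=2000)
        assert out["s1"][0].kind == "igr"
        assert out["s1"][0].bin_id == "ENSGUP-ENSG1"

    def test_overlapping_genes_multi_assignment(self):
        genes = [_gene("ENSG1", 10_000, 30_000), _gene("ENSG2", 25_000, 40_000)]
        snp = SnpRecord("s1", "1", 27_000, 0.3)
        out = map_snps_to_bins([snp], genes, margin=5000)
        assert {b.bin_id for b in out["s1"]} == {"ENSG1", "ENSG2"}

    def test_terminal_igr_gets_sentinel(self):
        genes = [_gene("ENSG1", 50_000, 60_000)]
        out = map_snps_to_bins([SnpRecord("s1", "1", 100, 0.3)], genes, margin=5000)
        assert out["s1"][0].bin_id == f"{epistasis.TERMINAL}-ENSG1"

    def test_partition_property(self, annotation, genotype_cohort):
        out = map_snps_to_bins(genotype_cohort.genotypes.snps, annotation)
        for snp_id, bins in out.items():
            kinds = {b.kind for b in bins}
            assert kinds in ({"genic"}, {"igr"})
            if kinds == {"igr"}:
                assert len(bins) == 1  # IGR assignment unique per SNP

    def test_chromosome_without_genes_unassigned(self):
        genes = [_gene("ENSG1", 10_000, 20_000)]
        out = map_snps_to_bins([SnpRecord("s1", "2", 100, 0.3)], genes)
        assert out["s1"] == []


class TestBinwiseBonferroni:
    @staticmethod
    def _assignments(members: dict[str, list[str]], kinds: dict[str, str]):
        out: dict[str, list[BinAssignment]] = {}
        for bin_id, snps in members.items():
            for s in snps:
                out.setdefault(s, []).append(BinAssignment(bin_id, kinds[bin_id]))
        return out

    def test_threshold_arithmetic(self):
        members = {
            "A": [f"a{i}" for i in range(10)],
            "B": [f"b{i}" for i in range(20)],
        }
        asg = self._assignments(members, {"A": "genic", "B": "genic"})
        res = [EpistasisResult("a0", "b0", 1.0, 20.0, 2.0e-4, 100)]
        out = binwise_bonferroni(res, asg, alpha=0.05)
        assert len(out) == 1
        assert out["threshold"].iloc[0] == pytest.approx(0.05 / 200)

    def test_single_snp_bins_no_correction(self):
        asg = self._assignments(
            {"A": ["a0"], "B": ["b0"]}, {"A": "genic", "B": "genic"}
        )
        res = [EpistasisResult("a0", "b0", 1.0, 5.0, 0.04, 100)]
        out = binwise_bonferroni(res, asg, alpha=0.05)
        assert len(out) == 1 and out["threshold"].iloc[0] == 0.05

    def test_igr_rows_typed_igri(self):
        asg = self._assignments(
            {"G": ["a0"], "X-Y": ["b0"]}, {"G": "genic", "X-Y": "igr"}
        )
        res = [EpistasisResult("a0", "b0", 1.0, 50.0, 1e-9, 100)]
        out = binwise_bonferroni(res, asg, alpha=0.05)
        assert out["interaction_type"].iloc[0] == "IGRI"

    def test_never_reports_above_threshold(self, annotation, genotype_cohort):
        gm, _ = qc_filter(genotype_cohort.genotypes)
        res = scan_pairs(gm, genotype_cohort.phenotype, p_threshold=1.0)
        asg = map_snps_to_bins(gm.snps, annotation)
        out = binwise_bonferroni(res, asg, alpha=0.05)
        members = bin_members(asg)
        for row in out.itertuples(index=False):
            m, n = len(members[row.bin_a]), len(members[row.bin_b])
            assert row.p_value < 0.05 / (m * n)

    def test_end_to_end_only_planted_bins(self, annotation, genotype_cohort):
        gm, _ = qc_filter(genotype_cohort.genotypes)
        res = scan_pairs(gm, genotype_cohort.phenotype, p_threshold=1e-8)
        asg = map_snps_to_bins(gm.snps, annotation)
        out = binwise_bonferroni(res, asg, alpha=0.05)
        planted_bins = {b.bin_id for b in asg["rs000001"]} | {
            b.bin_id for b in asg["rs000002"]
        }
        assert len(out) >= 1
        assert set(out["bin_a"]) | set(out["bin_b"]) <= planted_bins
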