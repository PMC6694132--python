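"""Cross-study rank-aggregated co-expression and region-specific co-expression.

Two routes produce co-expression edges:

* the *global* route — Spearman correlation of all probe pairs in each of
  several disease/healthy cohorts, per-dataset rank normalization, Robust
  Rank Aggregation (RRA) of the normalized ranks across cohorts,
  Benjamini-Hochberg adjustment and a hard score threshold (default 1e-5);

* the *region* route — Spearman correlation restricted to samples from one
  brain region, FDR-adjusted p-value cut (default 0.01), then a quartile
  filter keeping only coefficients >= the 1st quartile of the positive part
  of the distribution or <= the 3rd quartile of the negative part.

Both routes end at the ENSG level: probes are mapped to genes, self-pairs
after mapping are dropped, and duplicate gene pairs collapse to the most
conservative (maximum) score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionDataset, canonical_pair

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spearman correlation of all probe pairs
# ---------------------------------------------------------------------------


def spearman_all_pairs(
    dataset: ExpressionDataset, with_pvalues: bool = False
) -> pd.DataFrame:
    """Spearman rho for every unordered probe pair of ``dataset``.

    Returns a frame with columns ``id_a, id_b, value`` (and ``p`` when
    ``with_pvalues``), pairs canonicalized so id_a < id_b.  Probes constant
    across samples have undefined rank correlation; they are excluded and
    logged.  P-values use the two-sided t approximation of Spearman's
    statistic.
    """
    values = dataset.values
    n_probes, n_samples = values.shape
    if n_samples < 3:
        raise ValueError("need >= 3 samples for rank correlation")
    if n_probes < 2:
        raise ValueError("need >= 2 probes")

    mat = values.to_numpy(dtype=float)
    sds = mat.std(axis=1)
    keep = sds > 0
    dropped = [p for p, k in zip(values.index, keep) if not k]
    if dropped:
        logger.warning("excluding %d constant probes: %s", len(dropped), dropped[:5])
    probes = [p for p, k in zip(values.index, keep) if k]
    mat = mat[keep]
    if len(probes) < 2:
        raise ValueError("fewer than 2 non-constant probes")

    rho = stats.spearmanr(mat, axis=1).statistic
    if np.isscalar(rho):  # spearmanr returns a scalar for exactly 2 variables
        rho = np.array([[1.0, rho], [rho, 1.0]])
    iu, ju = np.triu_indices(len(probes), k=1)
    rows = {
        "id_a": [probes[i] for i in iu],
        "id_b": [probes[j] for j in ju],
        "value": rho[iu, ju],
    }
    out = pd.DataFrame(rows)
    # canonicalize (probe index order need not be lexicographic)
    swap = out["id_a"] > out["id_b"]
    out.loc[swap, ["id_a", "id_b"]] = out.loc[swap, ["id_b", "id_a"]].to_numpy()
    if with_pvalues:
        r = out["value"].to_numpy()
        df = n_samples - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[np.isclose(np.abs(r), 1.0)] = 0.0
        out["p"] = p
    out.attrs["value_kind"] = "spearman_rho"
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Rank normalization
# ---------------------------------------------------------------------------


def rank_pairs(correlations: pd.DataFrame, by_abs: bool = True) -> pd.DataFrame:
    """Assign normalized ranks to a Spearman pair table.

    The pair with the strongest correlation gets rank 1; "strongest" is by
    default the largest |rho| (capturing negative co-regulation), optionally
    signed-descending.  Ties receive average ranks.  Normalized rank =
    rank / N_pairs, in (0, 1].
    """
    if correlations.attrs.get("value_kind", "spearman_rho") != "spearman_rho":
        raise ValueError("rank_pairs expects a spearman_rho table")
    out = correlations.copy()
    if out.empty:
        out["normalized_rank"] = pd.Series(dtype=float)
        return out
    key = out["value"].abs() if by_abs else out["value"]
    ranks = stats.rankdata(-key.to_numpy(), method="average")
    out["normalized_rank"] = ranks / len(out)
    return out


# ---------------------------------------------------------------------------
# Robust Rank Aggregation
# ---------------------------------------------------------------------------


def rra_score(normalized_ranks: np.ndarray | list[float]) -> float:
    """Robust Rank Aggregation score of one pair's normalized rank profile.

    With sorted normalized ranks r(1) <= ... <= r(k), the score is
    ``min(k * min_j P(Beta(j, k-j+1) <= r(j)), 1)``: the j-th smallest of k
    independent uniforms follows Beta(j, k-j+1), so each term asks how
    surprising the j-th best rank is under the null of random orderings; the
    Bonferroni factor k accounts for taking the minimum over j.
    """
    r = np.asarray(normalized_ranks, dtype=float)
    if r.ndim != 1 or len(r) == 0:
        raise ValueError("need a 1-D, non-empty rank profile")
    if np.any((r <= 0.0) | (r > 1.0)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    k = len(r)
    r = np.sort(r)
    j = np.arange(1, k + 1)
    rho = float(np.min(stats.beta.cdf(r, j, k - j + 1)))
    return min(k * rho, 1.0)


def aggregate_global_coexpression(
    datasets: list[ExpressionDataset],
    probe_map: dict[str, str],
    alpha: float = 1e-5,
    by_abs: bool = True,
) -> pd.DataFrame:
    """Full global co-expression pipeline across several cohorts.

    Per dataset: Spearman all pairs -> normalized ranks.  Pairs absent from
    a dataset (e.g. a probe excluded as constant there) contribute a
    normalized rank of 1, the least significant value.  Per pair: RRA score
    across the k datasets, then Benjamini-Hochberg adjustment over all pairs
    and retention of adjusted scores < ``alpha``.  Probe pairs are then
    mapped to ENSG pairs; unmapped probes are dropped with a log entry,
    self-pairs after mapping are dropped, and duplicate ENSG pairs keep the
    maximum (most conservative) score.

    Returns an ENSG-level frame ``id_a, id_b, value`` with
    ``value_kind == "rra_score"``.
    """
    if not datasets:
        raise ValueError("need >= 1 dataset")
    k = len(datasets)
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for d_idx, ds in enumerate(datasets):
        ranked = rank_pairs(spearman_all_pairs(ds), by_abs=by_abs)
        for id_a, id_b, nr in ranked[["id_a", "id_b", "normalized_rank"]].itertuples(
            index=False
        ):
            pair = (id_a, id_b)
            if pair not in profiles:
                profiles[pair] = np.ones(k)
            profiles[pair][d_idx] = nr

    if not profiles:
        return _empty_pair_table("rra_score")
    pairs = list(profiles)
    scores = np.array([rra_score(profiles[p]) for p in pairs])
    adjusted = multipletests(scores, method="fdr_bh")[1]
    keep = adjusted < alpha
    if not keep.any():
        logger.warning("no probe pair survives RRA threshold %.3g", alpha)
        return _empty_pair_table("rra_score")

    rows = []
    n_unmapped = 0
    for (pa, pb), score in zip(
        (p for p, k_ in zip(pairs, keep) if k_), adjusted[keep]
    ):
        ga, gb = probe_map.get(pa), probe_map.get(pb)
        if ga is None or gb is None:
            n_unmapped += 1
            continue
        if ga == gb:
            continue  # self-pair after probe->gene mapping
        a, b = canonical_pair(ga, gb)
        rows.append((a, b, score))
    if n_unmapped:
        logger.info("dropped %d pairs with unmapped probes", n_unmapped)
    if not rows:
        return _empty_pair_table("rra_score")
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "value"])
    out = out.groupby(["id_a", "id_b"], as_index=False)["value"].max()
    out.attrs["value_kind"] = "rra_score"
    return out


def _empty_pair_table(kind: str) -> pd.DataFrame:
    out = pd.DataFrame(columns=["id_a", "id_b", "value"])
    out.attrs["value_kind"] = kind
    return out


# ---------------------------------------------------------------------------
# Region-specific co-expression
# ---------------------------------------------------------------------------


def region_coexpression(
    dataset: ExpressionDataset,
    region: str,
    probe_map: dict[str, str],
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Quartile-filtered co-expression within one brain region.

    Restricts to the region's samples, computes Spearman rho with p-values,
    Benjamini-Hochberg-adjusts the p-values and keeps pairs with adjusted
    p <= ``p_threshold``; then applies the quartile filter: keep rho >= Q1 of
    the surviving positive coefficients or rho <= Q3 of the surviving
    negative coefficients (linear-interpolation quantiles).  Output is
    ENSG-level, tagged ``ABA_<region>`` in ``attrs["data_source"]``.
    """
    ann = dataset.sample_annotations
    if "region" not in ann.columns:
        raise ValueError("dataset lacks region annotations")
    samples = ann.index[ann["region"] == region]
    if region not in set(ann["region"]):
        raise ValueError(f"region {region!r} not present in annotations")
    if len(samples) < 3:
        raise ValueError(f"insufficient data: region {region!r} has <3 samples")

    sub = ExpressionDataset(
        dataset_id=f"{dataset.dataset_id}_{region}",
        values=dataset.values[list(samples)],
        sample_annotations=ann.loc[samples],
    )
    table = spearman_all_pairs(sub, with_pvalues=True)
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table[table["p_adj"] <= p_threshold]
    table = _quartile_filter(table)

    rows = []
    for id_a, id_b, value in table[["id_a", "id_b", "value"]].itertuples(index=False):
        ga, gb = probe_map.get(id_a), probe_map.get(id_b)
        if ga is None or gb is None or ga == gb:
            continue
        a, b = canonical_pair(ga, gb)
        rows.append((a, b, value))
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "value"])
    if not out.empty:
        # collapse duplicate gene pairs to the strongest coefficient
        out["absval"] = out["value"].abs()
        out = (
            out.sort_values("absval", ascending=False)
            .drop_duplicates(subset=["id_a", "id_b"])
            .drop(columns="absval")
            .reset_index(drop=True)
        )
    out.attrs["value_kind"] = "spearman_rho"
    out.attrs["data_source"] = f"ABA_{region}"
    return out


def _quartile_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Keep rho >= Q1(positive part) or rho <= Q3(negative part)."""
    if table.empty:
        return table
    v = table["value"].to_numpy()
    pos, neg = v[v > 0], v[v < 0]
    keep = np.zeros(len(v), dtype=bool)
    if len(pos):
        keep |= v >= np.quantile(pos, 0.25)
    if len(neg):
        keep |= v <= np.quantile(neg, 0.75)
    return table[keep]
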