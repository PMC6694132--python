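"""Disease-gene prioritization on the heterogeneous graph.

The use case: label genes as disease-associated (positive), essential
non-disease (negative) or unknown; derive per-node features from two
blocks — a *biological* block (regional expression Z-scores plus a
disease-region contrast statistic) and a *graph* block (positive-label
fractions in the exact 1-hop and 2-hop neighborhoods of each typed
subgraph) — and evaluate a classifier that scores unknown genes by their
probability of disease association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .synthdata import DISEASE_REGIONS

logger = logging.getLogger(__name__)

EDGE_TYPES = ("PPI", "co-expression", "epistasis")


# ---------------------------------------------------------------------------
# Graph container
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneousGraph:
    """Undirected multigraph over ENSG nodes with per-type subgraph views."""

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "HeterogeneousGraph":
        g = nx.MultiGraph()
        for row in edges.itertuples(index=False):
            g.add_edge(
                row.ensg_a,
                row.ensg_b,
                score=float(row.score),
                interaction_type=row.interaction_type,
                data_source=row.data_source,
            )
        return cls(graph=g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def subgraph(self, edge_type: str) -> nx.Graph:
        """Simple-graph view of one interaction type's edges."""
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type!r}")
        sub = nx.Graph()
        sub.add_nodes_from(self.graph.nodes)
        for a, b, data in self.graph.edges(data=True):
            if data["interaction_type"] == edge_type:
                sub.add_edge(a, b)
        return sub


def prepare_case_study_graph(edges: pd.DataFrame, coexpr_cutoff: float = 0.5) -> HeterogeneousGraph:
    """Case-study graph: drop IGRI and weak region co-expression edges.

    Intergenic-region interactions are excluded so every node maps directly
    to a gene; disease-region co-expression edges with |rho| below
    ``coexpr_cutoff`` are excluded as weak (the magnitude reading keeps
    strong negative correlations).  Edges whose scores are not correlations
    (RRA co-expression, PPI, epistasis p-values) are untouched by the cutoff.
    """
    keep = edges["interaction_type"] != "IGRI"
    is_region_coexpr = (edges["interaction_type"] == "co-expression") & edges[
        "data_source"
    ].str.startswith("ABA_")
    keep &= ~is_region_coexpr | (edges["score"].abs() >= coexpr_cutoff)
    return HeterogeneousGraph.from_edges(edges[keep])


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


@dataclass
class LabelSet:
    positive: set[str]
    negative: set[str]
    unknown: set[str]

    def __post_init__(self) -> None:
        if self.positive & self.negative or self.positive & self.unknown or self.negative & self.unknown:
            raise ValueError("label classes must be pairwise disjoint")


def assemble_labels(
    gwas_genes: set[str] | list[str],
    ad_ppi_genes: set[str] | list[str],
    negative_list: set[str] | list[str],
    all_nodes: set[str] | list[str],
) -> LabelSet:
    """Partition the node set into positive / negative / unknown.

    Positives are the GWAS-supported and disease-PPI genes present in the
    graph; the externally supplied negative list fills the negative class.
    Genes claimed by both resolve positive-over-negative with a logged
    warning.  The remainder is unknown.
    """
    nodes = set(all_nodes)
    positive = (set(gwas_genes) | set(ad_ppi_genes)) & nodes
    conflicts = positive & set(negative_list)
    if conflicts:
        logger.warning(
            "%d genes in both positive and negative lists; kept positive", len(conflicts)
        )
    negative = (set(negative_list) & nodes) - positive
    if not positive or not negative:
        raise ValueError("degenerate labelling: empty positive or negative class")
    unknown = nodes - positive - negative
    return LabelSet(positive=positive, negative=negative, unknown=unknown)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def neighborhood_label_fraction(
    graph: HeterogeneousGraph,
    node: str,
    labels: LabelSet,
    hop: int,
    edge_type: str,
) -> float:
    """Fraction of positive-labelled genes at exact hop distance 1 or 2.

    The hop-2 neighborhood contains nodes at shortest-path distance exactly
    2 within the typed subgraph (the node itself and its direct neighbors
    are excluded).  Empty neighborhoods yield 0 by convention.
    """
    if hop not in (1, 2):
        raise ValueError("hop must be 1 or 2")
    sub = graph.subgraph(edge_type)
    if node not in sub:
        raise ValueError(f"node {node!r} not in graph")
    return _hood_fraction(sub, node, labels.positive, hop)


def _hood_fraction(sub: nx.Graph, node: str, positive: set[str], hop: int) -> float:
    first = set(sub.neighbors(node))
    first.discard(node)  # self-loop guard
    if hop == 1:
        hood = first
    else:
        hood = set()
        for nb in first:
            hood.update(sub.neighbors(nb))
        hood -= first
        hood.discard(node)
    if not hood:
        return 0.0
    return len(hood & positive) / len(hood)


def disease_region_contrast(
    zrow: pd.Series, disease_regions: list[str] | tuple[str, ...] = DISEASE_REGIONS
) -> tuple[float, float]:
    """Wilcoxon rank-sum contrast of disease-region vs remaining regions.

    Compares a gene's aggregated expression in the disease-associated
    regions against the rest of the brain, using the normal approximation
    with tie correction.  Returns (statistic, two-sided p); the statistic is
    positive when disease regions rank higher.  All-missing rows yield
    (nan, nan).
    """
    in_disease = zrow.index.isin(disease_regions)
    x = zrow[in_disease].dropna().to_numpy(dtype=float)
    y = zrow[~in_disease].dropna().to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    n1, n2 = len(x), len(y)
    # signed standardized statistic: U centered at its null mean
    z = (res.statistic - n1 * n2 / 2.0) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (float(z), float(res.pvalue))


def build_feature_table(
    graph: HeterogeneousGraph,
    labels: LabelSet,
    zscores: pd.DataFrame,
    disease_regions: list[str] | tuple[str, ...] = DISEASE_REGIONS,
) -> pd.DataFrame:
    """Per-node feature vectors: biological block + graph block.

    Biological block: the gene's regional Z-score profile plus the
    disease-region contrast statistic.  Graph block: positive-label
    fractions at hops 1 and 2 in each typed subgraph (6 features).  Genes
    absent from the Z-table get zero-filled biological features.
    """
    nodes = graph.nodes
    region_cols = list(zscores.columns)
    bio = zscores.reindex(nodes).fillna(0.0)
    contrast = [
        0.0 if np.isnan(c := disease_region_contrast(bio.loc[n], disease_regions)[0]) else c
        for n in nodes
    ]
    feat = bio.copy()
    feat["disease_region_contrast"] = contrast
    for etype in EDGE_TYPES:
        sub = graph.subgraph(etype)
        for hop in (1, 2):
            col = f"frac_pos_{etype.replace('-', '_')}_hop{hop}"
            feat[col] = [_hood_fraction(sub, n, labels.positive, hop) for n in nodes]
    feat.index = pd.Index(nodes, name="ensg")
    feat.attrs["biological_columns"] = region_cols + ["disease_region_contrast"]
    feat.attrs["graph_columns"] = [
        c for c in feat.columns if c.startswith("frac_pos_")
    ]
    return feat


# ---------------------------------------------------------------------------
# Classifier harness
# ---------------------------------------------------------------------------


@dataclass
class ReferenceScorer:
    """Random-forest probability scorer over a feature table."""

    n_estimators: int = 200
    seed: int = 0

    def fit(self, features: pd.DataFrame, labels: LabelSet) -> "ReferenceScorer":
        train_nodes = [n for n in features.index if n in labels.positive | labels.negative]
        X = features.loc[train_nodes].to_numpy(dtype=float)
        y = np.array([1 if n in labels.positive else 0 for n in train_nodes])
        self._model = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed
        ).fit(X, y)
        return self

    def score(self, features: pd.DataFrame) -> pd.Series:
        proba = self._model.predict_proba(features.to_numpy(dtype=float))[:, 1]
        return pd.Series(proba, index=features.index, name="probability")


def evaluate_classifier(
    scores: pd.Series, labels: LabelSet, threshold: float = 0.5
) -> dict[str, float]:
    """Precision, recall, F1 and ROC AUC on the labelled nodes only."""
    labelled = [n for n in scores.index if n in labels.positive | labels.negative]
    if not labelled:
        raise ValueError("no labelled nodes among the scored genes")
    y_true = np.array([1 if n in labels.positive else 0 for n in labelled])
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    y_score = scores.loc[labelled].to_numpy(dtype=float)
    y_pred = (y_score >= threshold).astype(int)
    return {
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "roc_auc": float(roc_auc_score(y_true, y_score)),
    }


def fit_and_evaluate(
    features: pd.DataFrame,
    labels: LabelSet,
    seed: int = 0,
    test_fraction: float = 0.3,
    columns: list[str] | None = None,
) -> tuple[dict[str, float], pd.Series]:
    """Train the reference scorer with a held-out split and score all nodes.

    Labelled nodes are split into train/test (stratified by label); metrics
    are computed on the held-out nodes only, so they estimate generalization
    rather than training fit.  ``columns`` restricts the feature block (e.g.
    biological-only vs graph-only comparisons).  Returns
    ``(held-out metrics, scores for every node)``.
    """
    feats = features[columns] if columns is not None else features
    rng = np.random.default_rng(seed)
    pos = sorted(n for n in feats.index if n in labels.positive)
    neg = sorted(n for n in feats.index if n in labels.negative)
    test: set[str] = set()
    for group in (pos, neg):
        n_test = max(1, int(round(test_fraction * len(group))))
        test.update(rng.choice(group, size=n_test, replace=False))
    train_labels = LabelSet(
        positive=labels.positive - test,
        negative=labels.negative - test,
        unknown=labels.unknown | test,
    )
    scorer = ReferenceScorer(seed=seed).fit(feats, train_labels)
    scores = scorer.score(feats)
    test_scores = scores.loc[sorted(test)]
    metrics = evaluate_classifier(test_scores, labels)
    return metrics, scores


def rank_unknowns(scores: pd.Series, labels: LabelSet) -> pd.DataFrame:
    """Unknown genes sorted by descending score; ties break by ENSG id."""
    unk = [n for n in scores.index if n in labels.unknown]
    frame = pd.DataFrame({"ensg": unk, "probability": scores.loc[unk].to_numpy()})
    frame = frame.sort_values(
        ["probability", "ensg"], ascending=[False, True]
    ).reset_index(drop=True)
    frame.index = frame.index + 1
    frame.index.name = "rank"
    return frame
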