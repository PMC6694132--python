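"""Assembly of the integrated heterogeneous network and node attributes.

Every stage output is mapped onto the ENSG namespace, typed, tagged with a
registered data-source id and stacked into a single edge list; node-level
information (GWAS association, positive selection, regional expression)
merges into a fixed-width attribute table: 6 scalar attributes plus one
aggregated-expression column per brain region (237 fields at the default
231 regions).  Pseudogene nodes and their incident edges are removed from
the final tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .synthdata import DISEASE_REGIONS, TRAIT_REGISTRY
from .types import (
    EDGE_COLUMNS,
    PSEUDOGENE_BIOTYPES,
    GeneModel,
    canonical_pair,
)

logger = logging.getLogger(__name__)

SCALAR_NODE_COLUMNS = ["ensg", "gene_name", "biotype", "snp_id", "gwas_p", "ps_p"]


# ---------------------------------------------------------------------------
# Dataset registry
# ---------------------------------------------------------------------------

DATA_TYPES = (
    "PPI",
    "co-expression",
    "epistasis",
    "GWAS",
    "gene expression",
    "positive selection",
)


@dataclass(frozen=True)
class RegistryEntry:
    data_source_id: str
    data_type: str
    data_source_name: str


def default_registry() -> pd.DataFrame:
    """The packaged 64-dataset registry spanning the six data types.

    Co-expression: the cross-cohort aggregate (ADN) and seven disease-region
    datasets (ABA_CA1..ABA_SptN).  Epistasis: ventricular volume (ADNI_VER),
    Braak staging in two cohorts (TGEN, HBTRC) and 46 cognitive-trait
    phenotypes (23 traits x latest/slope).  PPI: brain-ageing yeast
    two-hybrid (PBA) and three curated collections (IAH, ADIA, SIA).  Plus
    the GWAS table, the positive-selection table and the aggregated regional
    expression dataset.
    """
    entries: list[RegistryEntry] = [
        RegistryEntry("ADN", "co-expression", "AD/normal cross-cohort co-expression"),
    ]
    for r in DISEASE_REGIONS:
        entries.append(
            RegistryEntry(f"ABA_{r}", "co-expression", f"co-expression in brain region {r}")
        )
    entries += [
        RegistryEntry("ADNI_VER", "epistasis", "epistasis on ventricular volume change"),
        RegistryEntry("TGEN", "epistasis", "epistasis on Braak staging (TGEN cohort)"),
        RegistryEntry("HBTRC", "epistasis", "epistasis on Braak staging (HBTRC cohort)"),
    ]
    for trait in TRAIT_REGISTRY:
        for deriv in ("latest", "slope"):
            entries.append(
                RegistryEntry(
                    f"ADNI_CT_{trait}_{deriv}",
                    "epistasis",
                    f"epistasis on cognitive trait {trait} ({deriv})",
                )
            )
    entries += [
        RegistryEntry("PBA", "PPI", "brain-ageing yeast two-hybrid PPI"),
        RegistryEntry("IAH", "PPI", "curated human PPI"),
        RegistryEntry("ADIA", "PPI", "curated Alzheimer's disease PPI"),
        RegistryEntry("SIA", "PPI", "curated synaptic PPI"),
        RegistryEntry("GWAS", "GWAS", "Alzheimer's disease GWAS associations"),
        RegistryEntry("PS", "positive selection", "positive Darwinian selection"),
        RegistryEntry("ABA_EXPR", "gene expression", "aggregated regional expression"),
    ]
    frame = pd.DataFrame(
        [(e.data_source_id, e.data_type, e.data_source_name) for e in entries],
        columns=["data_source_id", "data_type", "data_source_name"],
    )
    if frame["data_source_id"].duplicated().any():
        raise AssertionError("registry ids must be unique")
    return frame


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------


def map_identifiers(
    records: pd.DataFrame,
    mapping: dict[str, str] | dict[str, list[str]] | pd.DataFrame,
    id_columns: list[str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map identifier columns onto the ENSG namespace.

    ``mapping`` may be a dict (source id -> ENSG or list of ENSGs) or a
    two-column frame.  One-to-many maps expand into one output row per
    mapped combination; rows with any unmapped id are dropped and counted in
    the report ``{"input": ..., "mapped": ..., "dropped": ...}``.
    """
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] != 2:
            raise ValueError("mapping frame must have exactly two columns")
        lookup: dict[str, list[str]] = {}
        for src, ensg in mapping.itertuples(index=False):
            lookup.setdefault(str(src), []).append(str(ensg))
    else:
        lookup = {
            k: (v if isinstance(v, list) else [v]) for k, v in mapping.items()
        }
    if not lookup:
        logger.warning("empty identifier mapping: all %d rows dropped", len(records))

    out_rows = []
    dropped = 0
    for _, row in records.iterrows():
        targets = []
        ok = True
        for col in id_columns:
            mapped = lookup.get(str(row[col]))
            if not mapped:
                ok = False
                break
            targets.append(mapped)
        if not ok:
            dropped += 1
            continue
        # cartesian expansion over one-to-many maps
        def expand(i: int, acc: list[str]) -> None:
            if i == len(id_columns):
                new = row.copy()
                for col, val in zip(id_columns, acc):
                    new[col] = val
                out_rows.append(new)
                return
            for val in targets[i]:
                expand(i + 1, acc + [val])

        expand(0, [])
    out = pd.DataFrame(out_rows, columns=records.columns).reset_index(drop=True)
    report = {"input": len(records), "mapped": len(out), "dropped": dropped}
    return out, report


def filter_ppi_by_score(edges: pd.DataFrame, min_mi: float = 0.45) -> pd.DataFrame:
    """Keep curated PPI rows with MI confidence >= ``min_mi`` (inclusive)."""
    return edges[edges["score"] >= min_mi].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Edge assembly
# ---------------------------------------------------------------------------


def assemble_edges(
    stage_outputs: list[tuple[pd.DataFrame, str, str]],
    registry: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack stage outputs into the integrated edge list.

    ``stage_outputs`` holds (frame, interaction_type, data_source_id)
    triples; each frame needs node-id columns (first two columns or
    ``ensg_a``/``ensg_b``/``id_a``/``id_b``) and a score column.  Multi-edges
    between the same node pair from different sources are preserved.
    Unknown data-source ids raise against the registry.
    """
    registry = default_registry() if registry is None else registry
    known = set(registry["data_source_id"])
    frames = []
    for frame, itype, source in stage_outputs:
        if source not in known:
            raise ValueError(f"unknown data_source_id {source!r}")
        if frame.empty:
            continue
        cols = list(frame.columns)
        a_col = "ensg_a" if "ensg_a" in cols else ("id_a" if "id_a" in cols else cols[0])
        b_col = "ensg_b" if "ensg_b" in cols else ("id_b" if "id_b" in cols else cols[1])
        score_col = (
            "score" if "score" in cols else ("value" if "value" in cols else "p_value")
        )
        part = pd.DataFrame(
            {
                "ensg_a": frame[a_col].astype(str),
                "ensg_b": frame[b_col].astype(str),
                "score": frame[score_col].astype(float),
                "interaction_type": itype,
                "data_source": source,
            }
        )
        frames.append(part)
    if not frames:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    pairs = [canonical_pair(a, b) for a, b in zip(out["ensg_a"], out["ensg_b"])]
    out["ensg_a"] = [p[0] for p in pairs]
    out["ensg_b"] = [p[1] for p in pairs]
    return out[EDGE_COLUMNS]


# ---------------------------------------------------------------------------
# Node attributes
# ---------------------------------------------------------------------------


def assemble_node_attributes(
    gwas: pd.DataFrame,
    positive_selection: pd.DataFrame,
    zscores: pd.DataFrame,
    annotation: list[GeneModel],
    gwas_alpha: float = 0.05,
    n_regions: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge node-level evidence into the fixed-width attribute table.

    GWAS rows are filtered to ``p <= gwas_alpha`` before merging.  Returns
    ``(long, wide)``: the long form keeps one row per qualifying (gene, SNP)
    pair; the wide form keeps one row per ENSG (minimum GWAS p and its SNP
    id) with exactly ``6 + n_regions`` fields.  Missing attributes are left
    empty (NaN).
    """
    region_cols = list(zscores.columns)
    if n_regions is not None and len(region_cols) != n_regions:
        raise ValueError(
            f"schema error: region table has {len(region_cols)} columns, expected {n_regions}"
        )
    genes = pd.DataFrame(
        [(g.ensg_id, g.gene_name, g.biotype) for g in annotation],
        columns=["ensg", "gene_name", "biotype"],
    )
    gw = gwas[gwas["p"] <= gwas_alpha].rename(columns={"p": "gwas_p"})
    ps = positive_selection.rename(columns={"p": "ps_p"})

    long = genes.merge(gw[["ensg", "snp_id", "gwas_p"]], on="ensg", how="left")
    long = long.merge(ps[["ensg", "ps_p"]], on="ensg", how="left")
    long = long.merge(zscores, left_on="ensg", right_index=True, how="left")
    long = long[SCALAR_NODE_COLUMNS + region_cols]

    flat = long.sort_values(["ensg", "gwas_p"], na_position="last").drop_duplicates(
        subset="ensg", keep="first"
    )
    wide = flat.reset_index(drop=True)
    return long.reset_index(drop=True), wide


def filter_pseudogenes(
    edges: pd.DataFrame, nodes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Remove pseudogene nodes and every interaction touching them."""
    pseudo = set(nodes.loc[nodes["biotype"].isin(PSEUDOGENE_BIOTYPES), "ensg"])
    nodes_out = nodes[~nodes["ensg"].isin(pseudo)].reset_index(drop=True)
    touch = edges["ensg_a"].isin(pseudo) | edges["ensg_b"].isin(pseudo)
    edges_out = edges[~touch].reset_index(drop=True)
    report = {"nodes_removed": len(pseudo), "edges_removed": int(touch.sum())}
    if report["nodes_removed"]:
        logger.info(
            "pseudogene filter removed %d nodes and %d edges",
            report["nodes_removed"], report["edges_removed"],
        )
    return edges_out, nodes_out, report


# ---------------------------------------------------------------------------
# Summaries and comparisons
# ---------------------------------------------------------------------------


def summarize(edges: pd.DataFrame, nodes: pd.DataFrame | None = None) -> dict:
    """Per-dataset counts, per-type subgraph sizes, reduced-version counts.

    The reduced version applies the |rho| >= 0.8 rule to disease-region
    co-expression edges only (their scores are Spearman coefficients); all
    other edges pass unchanged.
    """
    per_source = edges.groupby("data_source").size().to_dict()
    per_type: dict[str, dict[str, int]] = {}
    for itype, sub in edges.groupby("interaction_type"):
        node_ids = set(sub["ensg_a"]) | set(sub["ensg_b"])
        per_type[itype] = {"edges": len(sub), "nodes": len(node_ids)}
    full_nodes = set(edges["ensg_a"]) | set(edges["ensg_b"])
    reduced = reduced_version(edges)
    return {
        "per_source_edge_counts": per_source,
        "per_type_subgraph": per_type,
        "full_graph": {"edges": len(edges), "nodes": len(full_nodes)},
        "reduced": {
            "edges": len(reduced),
            "nodes": len(set(reduced["ensg_a"]) | set(reduced["ensg_b"])),
        },
        "node_table_rows": None if nodes is None else len(nodes),
    }


def reduced_version(edges: pd.DataFrame, cutoff: float = 0.8) -> pd.DataFrame:
    """Restrictive release: region co-expression needs |rho| >= ``cutoff``."""
    is_region_coexpr = (edges["interaction_type"] == "co-expression") & edges[
        "data_source"
    ].str.startswith("ABA_")
    keep = ~is_region_coexpr | (edges["score"].abs() >= cutoff)
    return edges[keep].reset_index(drop=True)


def compare_edge_sets(**named_sets: set[tuple[str, str]]) -> pd.DataFrame:
    """Exclusive intersection sizes over k edge sets (UpSet-style).

    Input edges are canonicalized to unordered pairs first, so A-B and B-A
    count as the same interaction.  For every non-empty subset of the named
    sets, reports the number of pairs belonging to exactly those sets.
    """
    canon = {
        name: {canonical_pair(a, b) for a, b in pairs}
        for name, pairs in named_sets.items()
    }
    names = sorted(canon)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(canon[n] for n in combo))
            for other in names:
                if other not in combo:
                    inside -= canon[other]
            rows.append(("&".join(combo), len(inside)))
    return pd.DataFrame(rows, columns=["sets", "exclusive_count"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

EDGE_HEADER = ["ENSG.A", "ENSG.B", "score", "interaction_type", "data_source"]


def write_edges(edges: pd.DataFrame, path: str, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        out = edges.rename(
            columns=dict(zip(EDGE_COLUMNS, EDGE_HEADER))
        )
        out.to_csv(fh, sep="\t", index=False)


def read_edges(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame.rename(columns=dict(zip(EDGE_HEADER, EDGE_COLUMNS)))


def write_nodes(nodes: pd.DataFrame, path: str, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        nodes.to_csv(fh, sep="\t", index=False)


def read_nodes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def to_graphml(edges: pd.DataFrame, path: str) -> None:
    """Export the heterogeneous multigraph with typed, scored edges."""
    g = nx.MultiGraph()
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.ensg_a,
            row.ensg_b,
            score=float(row.score),
            interaction_type=row.interaction_type,
            data_source=row.data_source,
        )
    nx.write_graphml(g, path)
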