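"""Identifier mapping, edge/node assembly, filters, summaries, round-trips."""

import numpy as np
import pandas as pd
import pytest

from adnet import integration, synthdata
from adnet.integration import (
    assemble_edges,
    assemble_node_attributes,
    compare_edge_sets,
    default_registry,
    filter_ppi_by_score,
    filter_pseudogenes,
    map_identifiers,
    read_edges,
    read_nodes,
    reduced_version,
    summarize,
    write_edges,
    write_nodes,
)


class TestRegistry:
    def test_sixty_four_datasets_of_six_types(self):
        reg = default_registry()
        assert len(reg) == 64
        assert reg["data_source_id"].is_unique
        assert set(reg["data_type"]) == set(integration.DATA_TYPES)
        assert len(set(reg["data_type"])) == 6

    def test_cognitive_trait_entries(self):
        reg = default_registry()
        ct = reg[reg["data_source_id"].str.startswith("ADNI_CT_")]
        assert len(ct) == 46  # 23 traits x latest/slope


class TestMapIdentifiers:
    def test_one_to_one(self):
        frame = pd.DataFrame({"protein": ["P1"], "score": [0.5]})
        out, report = map_identifiers(frame, {"P1": "ENSG1"}, ["protein"])
        assert list(out["protein"]) == ["ENSG1"]
        assert report == {"input": 1, "mapped": 1, "dropped": 0}

    def test_one_to_many_expands(self):
        frame = pd.DataFrame({"probe": ["pr1"], "score": [0.5]})
        out, _ = map_identifiers(frame, {"pr1": ["ENSG1", "ENSG2"]}, ["probe"])
        assert len(out) == 2
        assert set(out["probe"]) == {"ENSG1", "ENSG2"}

    def test_drop_report_conservation(self):
        frame = pd.DataFrame({"id": ["a", "b", "c"], "x": [1, 2, 3]})
        out, report = map_identifiers(frame, {"a": "E1", "c": "E3"}, ["id"])
        assert report["dropped"] == report["input"] - len(out) == 1


class TestPpiFilter:
    def test_boundary_inclusive(self):
        edges = pd.DataFrame({"score": [0.44, 0.45, 0.9]})
        assert len(filter_ppi_by_score(edges)) == 2

    def test_zero_threshold_identity(self):
        edges = pd.DataFrame({"score": [0.1, 0.2]})
        assert len(filter_ppi_by_score(edges, min_mi=0.0)) == 2

    def test_above_max_empty(self):
        edges = pd.DataFrame({"score": [0.9, 1.0]})
        assert filter_ppi_by_score(edges, min_mi=1.01).empty


class TestAssembleEdges:
    def test_printed_example_row_round_trip(self, tmp_path):
        frame = pd.DataFrame(
            {"ensg_a": ["ENSG00000129484"], "ensg_b": ["ENSG00000167972"], "score": [0.0001]}
        )
        edges = assemble_edges([(frame, "PPI", "PBA")])
        path = tmp_path / "edges.tsv"
        write_edges(edges, str(path))
        back = read_edges(str(path))
        row = back.iloc[0]
        assert (
            row["ensg_a"], row["ensg_b"], row["score"], row["interaction_type"], row["data_source"]
        ) == ("ENSG00000129484", "ENSG00000167972", 0.0001, "PPI", "PBA")

    def test_multi_edges_preserved(self):
        pair = pd.DataFrame({"ensg_a": ["E1"], "ensg_b": ["E2"], "score": [0.5]})
        edges = assemble_edges([(pair, "PPI", "IAH"), (pair, "co-expression", "ADN")])
        assert len(edges) == 2
        assert set(edges["interaction_type"]) == {"PPI", "co-expression"}

    def test_empty_stage_contributes_nothing(self):
        empty = pd.DataFrame(columns=["ensg_a", "ensg_b", "score"])
        assert assemble_edges([(empty, "PPI", "PBA")]).empty

    def test_unknown_source_rejected(self):
        frame = pd.DataFrame({"ensg_a": ["E1"], "ensg_b": ["E2"], "score": [0.5]})
        with pytest.raises(ValueError, match="unknown data_source_id"):
            assemble_edges([(frame, "PPI", "NOT_A_SOURCE")])


@pytest.fixture(scope="module")
def node_inputs(annotation):
    omics = synthdata.gen_ppi_and_tables(annotation, seed=31)
    regions = synthdata.default_regions()
    rng = np.random.default_rng(31)
    z = pd.DataFrame(
        rng.normal(size=(len(annotation.genes), len(regions))),
        index=pd.Index(annotation.ensg_ids, name="ensg"),
        columns=regions,
    )
    return omics, z


class TestNodeAttributes:
    def test_vector_width_237(self, annotation, node_inputs):
        omics, z = node_inputs
        _long, wide = assemble_node_attributes(
            omics.gwas, omics.positive_selection, z, annotation.genes, n_regions=231
        )
        assert wide.shape[1] == 237
        assert list(wide.columns[:6]) == ["ensg", "gene_name", "biotype", "snp_id", "gwas_p", "ps_p"]

    def test_gwas_filter_excludes_p_above_alpha(self, annotation, node_inputs):
        omics, z = node_inputs
        gwas = pd.DataFrame(
            {"snp_id": ["s1", "s2"], "ensg": [annotation.ensg_ids[0]] * 2, "p": [0.06, 0.04]}
        )
        long, wide = assemble_node_attributes(
            gwas, omics.positive_selection, z, annotation.genes
        )
        kept = long.dropna(subset=["gwas_p"])
        assert set(kept["snp_id"]) == {"s2"}

    def test_min_p_kept_in_flat_view(self, annotation, node_inputs):
        omics, z = node_inputs
        gene = annotation.ensg_ids[0]
        gwas = pd.DataFrame(
            {"snp_id": ["s1", "s2"], "ensg": [gene] * 2, "p": [0.03, 0.01]}
        )
        long, wide = assemble_node_attributes(
            gwas, omics.positive_selection, z, annotation.genes
        )
        assert len(long[long["ensg"] == gene]) == 2
        row = wide[wide["ensg"] == gene].iloc[0]
        assert row["gwas_p"] == 0.01 and row["snp_id"] == "s2"

    def test_gene_without_evidence_keeps_full_width(self, annotation, node_inputs):
        omics, z = node_inputs
        empty_gwas = pd.DataFrame(columns=["snp_id", "ensg", "p"])
        empty_ps = pd.DataFrame(columns=["ensg", "p"])
        _long, wide = assemble_node_attributes(
            empty_gwas, empty_ps, z, annotation.genes
        )
        assert wide.shape == (len(annotation.genes), 237)
        assert wide["gwas_p"].isna().all()

    def test_region_count_mismatch_rejected(self, annotation, node_inputs):
        omics, z = node_inputs
        with pytest.raises(ValueError, match="schema error"):
            assemble_node_attributes(
                omics.gwas, omics.positive_selection,
                z.iloc[:, :10], annotation.genes, n_regions=231,
            )


class TestPseudogeneFilter:
    @staticmethod
    def _tables():
        nodes = pd.DataFrame(
            {
                "ensg": ["E1", "E2", "E3", "E4"],
                "biotype": ["protein_coding", "processed_pseudogene", "lincRNA",
                            "unprocessed_pseudogene"],
            }
        )
        edges = pd.DataFrame(
            {
                "ensg_a": ["E1", "E2", "E2", "E2", "E2"],
                "ensg_b": ["E3", "E1", "E3", "E3", "E4"],
                "score": [0.5] * 5,
                "interaction_type": ["PPI"] * 5,
                "data_source": ["IAH"] * 5,
            }
        )
        return edges, nodes

    def test_node_and_incident_edges_removed(self):
        edges, nodes = self._tables()
        e_out, n_out, report = filter_pseudogenes(edges, nodes)
        assert set(n_out["ensg"]) == {"E1", "E3"}
        assert len(e_out) == 1  # only E1-E3 survives
        assert report == {"nodes_removed": 2, "edges_removed": 4}

    def test_pseudogene_pseudogene_edge_counted_once(self):
        edges, nodes = self._tables()
        e_out, _n, report = filter_pseudogenes(edges, nodes)
        # the E2-E4 row (both pseudogenes) appears once in the removal count
        assert report["edges_removed"] == len(edges) - len(e_out)

    def test_idempotent_and_identity_without_pseudogenes(self):
        edges, nodes = self._tables()
        e1, n1, _ = filter_pseudogenes(edges, nodes)
        e2, n2, report2 = filter_pseudogenes(e1, n1)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(n1, n2)
        assert report2 == {"nodes_removed": 0, "edges_removed": 0}


class TestSummaries:
    @staticmethod
    def _toy_edges():
        return pd.DataFrame(
            {
                "ensg_a": ["E1", "E1", "E2", "E3"],
                "ensg_b": ["E2", "E3", "E3", "E4"],
                "score": [0.7, 0.5, 0.9, 1e-9],
                "interaction_type": ["PPI", "PPI", "co-expression", "epistasis"],
                "data_source": ["IAH", "PBA", "ABA_CA1", "TGEN"],
            }
        )

    def test_per_type_counts(self):
        s = summarize(self._toy_edges())
        per_type = {t: v["edges"] for t, v in s["per_type_subgraph"].items()}
        assert per_type == {"PPI": 2, "co-expression": 1, "epistasis": 1}

    def test_reduced_filter_keeps_strong_correlations(self):
        edges = pd.DataFrame(
            {
                "ensg_a": ["E1"] * 3,
                "ensg_b": ["E2", "E3", "E4"],
                "score": [0.9, 0.5, -0.85],
                "interaction_type": ["co-expression"] * 3,
                "data_source": ["ABA_CA1"] * 3,
            }
        )
        out = reduced_version(edges)
        assert sorted(out["score"]) == [-0.85, 0.9]

    def test_reduced_filter_scoped_to_region_coexpression(self):
        # a weak region co-expression edge is dropped; low PPI / RRA /
        # epistasis scores are out of the rule's scope and survive
        edges = pd.DataFrame(
            {
                "ensg_a": ["E1"] * 4,
                "ensg_b": ["E2", "E3", "E4", "E5"],
                "score": [0.5, 0.5, 1e-6, 1e-9],
                "interaction_type": ["co-expression", "PPI", "co-expression", "epistasis"],
                "data_source": ["ABA_CA1", "IAH", "ADN", "TGEN"],
            }
        )
        out = reduced_version(edges)
        assert "ABA_CA1" not in set(out["data_source"])
        assert len(out) == 3

    def test_subgraph_node_count_distinct_endpoints(self):
        s = summarize(self._toy_edges())
        assert s["per_type_subgraph"]["PPI"]["nodes"] == 3  # E1, E2, E3


class TestCompareEdgeSets:
    def test_orientation_insensitive(self):
        out = compare_edge_sets(
            x={("A", "B"), ("B", "C")}, y={("B", "A"), ("C", "D")}
        )
        sizes = dict(zip(out["sets"], out["exclusive_count"]))
        assert sizes == {"x": 1, "y": 1, "x&y": 1}

    def test_identical_sets_single_region(self):
        out = compare_edge_sets(a={("A", "B")}, b={("A", "B")})
        sizes = dict(zip(out["sets"], out["exclusive_count"]))
        assert sizes == {"a": 0, "b": 0, "a&b": 1}

    def test_region_sizes_sum_to_union(self):
        rng = np.random.default_rng(7)
        def rand_set():
            return {
                tuple(sorted((f"E{rng.integers(10)}", f"E{rng.integers(10, 20)}")))
                for _ in range(15)
            }
        sets = {"a": rand_set(), "b": rand_set(), "c": rand_set()}
        out = compare_edge_sets(**sets)
        union = set().union(*sets.values())
        assert out["exclusive_count"].sum() == len(union)


class TestRoundTrip:
    def test_edges_and_nodes_lossless(self, tmp_path, annotation, node_inputs):
        omics, z = node_inputs
        frame = pd.DataFrame(
            {"ensg_a": ["E2", "E1"], "ensg_b": ["E1", "E3"], "score": [0.7, 0.9]}
        )
        edges = assemble_edges([(frame, "co-expression", "ABA_DG")])
        _long, nodes = assemble_node_attributes(
            omics.gwas, omics.positive_selection, z, annotation.genes
        )
        ep, np_ = tmp_path / "e.tsv", tmp_path / "n.tsv"
        write_edges(edges, str(ep), comment="seed=0")
        write_nodes(nodes, str(np_), comment="seed=0")
        pd.testing.assert_frame_equal(read_edges(str(ep)), edges)
        back = read_nodes(str(np_))
        pd.testing.assert_frame_equal(back, nodes, check_dtype=False)
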