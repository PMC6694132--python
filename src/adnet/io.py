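"""Tab-separated writers/readers for generated inputs.

All pipeline inputs and outputs are plain TSV so that runs are inspectable
and diffable.  The genotype map mirrors PLINK ``.map`` columns
(chromosome, snp id, genetic distance placeholder, position).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthdata import Annotation
from .types import ExpressionDataset, GeneModel, GenotypeMatrix, SnpRecord


def write_expression(dataset: ExpressionDataset, prefix: str | Path) -> None:
    prefix = Path(prefix)
    dataset.values.to_csv(f"{prefix}_matrix.tsv", sep="\t", index_label="probe_id")
    dataset.sample_annotations.to_csv(f"{prefix}_samples.tsv", sep="\t")


def read_expression(prefix: str | Path, dataset_id: str) -> ExpressionDataset:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}_matrix.tsv", sep="\t", index_col="probe_id")
    ann = pd.read_csv(f"{prefix}_samples.tsv", sep="\t", index_col="sample_id")
    return ExpressionDataset(dataset_id=dataset_id, values=values, sample_annotations=ann)


def write_genotypes(gm: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    gm.dosages.to_csv(f"{prefix}_dosages.tsv", sep="\t", index_label="individual")
    snp_map = pd.DataFrame(
        [(s.chromosome, s.snp_id, 0, s.position, s.maf) for s in gm.snps],
        columns=["chromosome", "snp_id", "cm", "position", "maf"],
    )
    snp_map.to_csv(f"{prefix}_snps.tsv", sep="\t", index=False)


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    dosages = pd.read_csv(f"{prefix}_dosages.tsv", sep="\t", index_col="individual")
    snp_map = pd.read_csv(f"{prefix}_snps.tsv", sep="\t")
    snps = [
        SnpRecord(
            snp_id=str(r.snp_id), chromosome=str(r.chromosome),
            position=int(r.position), maf=float(r.maf),
        )
        for r in snp_map.itertuples(index=False)
    ]
    return GenotypeMatrix(
        individuals=list(dosages.index), snps=snps, dosages=dosages
    )


def write_annotation(annotation: Annotation, prefix: str | Path) -> None:
    prefix = Path(prefix)
    annotation.frame().to_csv(f"{prefix}_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(annotation.probe_map.items()), columns=["probe_id", "ensg_id"]
    ).to_csv(f"{prefix}_probes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(annotation.protein_map.items()), columns=["protein_id", "ensg_id"]
    ).to_csv(f"{prefix}_proteins.tsv", sep="\t", index=False)


def read_annotation(prefix: str | Path) -> Annotation:
    prefix = Path(prefix)
    genes_frame = pd.read_csv(f"{prefix}_genes.tsv", sep="\t")
    genes = [
        GeneModel(
            ensg_id=str(r.ensg_id), gene_name=str(r.gene_name),
            chromosome=str(r.chromosome), start=int(r.start), end=int(r.end),
            biotype=str(r.biotype),
        )
        for r in genes_frame.itertuples(index=False)
    ]
    probes = pd.read_csv(f"{prefix}_probes.tsv", sep="\t")
    proteins = pd.read_csv(f"{prefix}_proteins.tsv", sep="\t")
    return Annotation(
        genes=genes,
        probe_map=dict(zip(probes["probe_id"].astype(str), probes["ensg_id"].astype(str))),
        protein_map=dict(
            zip(proteins["protein_id"].astype(str), proteins["ensg_id"].astype(str))
        ),
    )


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
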