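"""Core domain containers shared by every stage of the pipeline.

The unifying namespace is the Ensembl gene id (ENSG).  Probes, proteins and
SNPs are all eventually mapped onto ENSG ids; intergenic regions get composite
``ENSGC-ENSGD`` ids naming their two flanking genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Gene biotypes the synthetic annotation draws from (Ensembl vocabulary).
BIOTYPES = (
    "protein_coding",
    "lincRNA",
    "antisense",
    "processed_pseudogene",
    "unprocessed_pseudogene",
)

#: Biotype categories treated as pseudogenes and excluded from the final network.
PSEUDOGENE_BIOTYPES = frozenset(
    b for b in BIOTYPES if b.endswith("pseudogene")
)


@dataclass(frozen=True)
class GeneModel:
    """One gene of the annotation: 1-based inclusive coordinates."""

    ensg_id: str
    gene_name: str
    chromosome: str
    start: int
    end: int
    biotype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.ensg_id}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.ensg_id}: coordinates are 1-based")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def is_pseudogene(self) -> bool:
        return self.biotype in PSEUDOGENE_BIOTYPES


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chromosome: str
    position: int
    maf: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf outside [0, 0.5]")


@dataclass
class ExpressionDataset:
    """Probes x samples intensity matrix with per-sample annotations.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns.
    ``sample_annotations`` is indexed by sample id and may carry ``condition``
    (AD / HI), ``region`` and ``donor`` columns.
    """

    dataset_id: str
    values: pd.DataFrame
    sample_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if not self.values.columns.equals(self.sample_annotations.index):
            raise ValueError("sample annotation index does not match columns")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix, entries in {0, 1, 2} with NaN = missing."""

    individuals: list[str]
    snps: list[SnpRecord]
    dosages: pd.DataFrame  # index: individuals, columns: snp ids

    def __post_init__(self) -> None:
        if list(self.dosages.index) != list(self.individuals):
            raise ValueError("dosage rows do not match individuals")
        if list(self.dosages.columns) != [s.snp_id for s in self.snps]:
            raise ValueError("dosage columns do not match SNP records")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages restricted to {0, 1, 2, missing}")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset_snps(self, keep: Sequence[str]) -> "GenotypeMatrix":
        keep = list(keep)
        keep_set = set(keep)
        snps = [s for s in self.snps if s.snp_id in keep_set]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snps=snps,
            dosages=self.dosages[[s.snp_id for s in snps]],
        )


@dataclass
class TraitSeries:
    """Longitudinal observations of one cognitive trait for one individual."""

    individual: str
    trait: str
    observations: list[tuple[float, float]]  # (time, value), time increasing

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("trait series requires >= 1 observation")
        times = [t for t, _ in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("observation times must strictly increase")


@dataclass
class GroundTruth:
    """Planted signals recorded by the generators, for recovery tests."""

    coexpressed_modules: list[tuple[list[str], float]] = field(default_factory=list)
    epistatic_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    disease_region_genes: list[str] = field(default_factory=list)
    positive_genes: list[str] = field(default_factory=list)
    negative_genes: list[str] = field(default_factory=list)
    gwas_signal_snps: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Integrated-network records
# ---------------------------------------------------------------------------

INTERACTION_TYPES = ("PPI", "co-expression", "epistasis", "IGRI")

EDGE_COLUMNS = ["ensg_a", "ensg_b", "score", "interaction_type", "data_source"]


@dataclass(frozen=True)
class EdgeRecord:
    """One typed, scored interaction between two ENSG-identified nodes.

    IGRI rows may carry composite ``ENSGC-ENSGD`` endpoint ids.  Score
    semantics depend on the source: RRA scores and p-values are
    lower-is-stronger, Spearman coefficients live in [-1, 1], PBS in [0, 10]
    (lower = more specific) and MI confidence in [0, 1].
    """

    ensg_a: str
    ensg_b: str
    score: float
    interaction_type: str
    data_source: str

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered node pair lexicographically (A-B == B-A)."""
    return (a, b) if a <= b else (b, a)


def edges_to_frame(edges: Sequence[EdgeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.ensg_a, e.ensg_b, e.score, e.interaction_type, e.data_source) for e in edges],
        columns=EDGE_COLUMNS,
    )
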