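import numpy as np
import pandas as pd
import pytest

from adnet import synthdata
from adnet.types import ExpressionDataset


@pytest.fixture(scope="session")
def annotation():
    return synthdata.gen_gene_annotation(
        n_genes=30, n_pseudogenes=3, overlap_fraction=0.1, seed=11
    )


@pytest.fixture(scope="session")
def cohorts(annotation):
    module = [g.ensg_id for g in annotation.genes if not g.is_pseudogene][:5]
    datasets, truth = synthdata.gen_expression_cohorts(
        annotation,
        n_datasets=6,
        samples_per_dataset=40,
        modules=[(module, 0.9)],
        noise_sd=0.3,
        seed=12,
    )
    return datasets, truth


@pytest.fixture(scope="session")
def genotype_cohort(annotation):
    return synthdata.gen_genotypes_and_traits(
        annotation,
        n_individuals=400,
        n_snps=30,
        epistatic_pairs=[synthdata.PlantedPair("rs000001", "rs000002", beta_ab=1.0)],
        missing_rate=0.02,
        seed=13,
    )


def make_expression(values: np.ndarray, probe_ids=None, dataset_id="TOY", **ann_cols):
    """Small helper to build an ExpressionDataset from a raw matrix."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    ann = pd.DataFrame(
        ann_cols or {"condition": ["AD"] * n_samples},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        sample_annotations=ann,
    )
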