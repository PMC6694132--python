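"""Aggregated gene expression per brain region, as node attributes.

Region-annotated whole-brain expression (six donor brains in the original
atlas design) is reduced to one Z-score per gene per region: per-dataset
probe x region means, per-region standardization across probes, averaging
across datasets, and a probe -> gene collapse keeping the probe whose
maximum |Z| over regions is largest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionDataset

logger = logging.getLogger(__name__)


def region_means(dataset: ExpressionDataset) -> pd.DataFrame:
    """Mean expression of each probe across the samples of each region.

    Returns a probe x region frame; regions with no samples in this dataset
    simply do not appear as columns (marked absent).
    """
    ann = dataset.sample_annotations
    if "region" not in ann.columns or ann["region"].isna().any():
        raise ValueError("every sample must carry a region label")
    groups = dataset.values.T.groupby(ann["region"], observed=True)
    return groups.mean().T


def zscore_and_collapse(
    mean_tables: list[pd.DataFrame],
    probe_map: dict[str, str],
    axis: str = "region",
    ddof: int = 1,
) -> pd.DataFrame:
    """Z-score per-dataset region means, average, and collapse probes to genes.

    ``axis="region"`` (default) standardizes across probes within each
    region column — each region's Z column has mean 0 and sd 1 in each
    dataset; ``axis="probe"`` standardizes each probe's profile across
    regions instead.  Per-probe Z-scores are averaged (unweighted) across
    the datasets in which the probe/region cell is present.  For genes with
    several probes, the entire regional profile of the probe with the
    largest maximum |Z| is kept.

    Returns an ENSG x region frame; ``attrs["zscore_axis"]`` records the
    convention used.
    """
    if axis not in ("region", "probe"):
        raise ValueError("axis must be 'region' or 'probe'")
    if not mean_tables:
        raise ValueError("need >= 1 mean table")

    z_tables = []
    for mt in mean_tables:
        if axis == "region":
            if len(mt.index) < 2:
                raise ValueError("need >= 2 probes per region to standardize")
            mu = mt.mean(axis=0)
            sd = mt.std(axis=0, ddof=ddof)
            degenerate = sd[sd == 0].index
            if len(degenerate):
                logger.warning(
                    "dropping %d zero-dispersion regions: %s",
                    len(degenerate), list(degenerate)[:5],
                )
                mt = mt.drop(columns=degenerate)
                mu = mu.drop(degenerate)
                sd = sd.drop(degenerate)
            z = (mt - mu) / sd
        else:
            mu = mt.mean(axis=1)
            sd = mt.std(axis=1, ddof=ddof)
            z = mt.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
        z_tables.append(z)

    combined = pd.concat(z_tables).groupby(level=0).mean()

    # probe -> gene collapse: keep the whole profile of the max-|Z| probe
    rows = []
    gene_probes: dict[str, list[str]] = {}
    for probe in combined.index:
        ensg = probe_map.get(probe, probe)  # gene-level input passes through
        gene_probes.setdefault(ensg, []).append(probe)
    for ensg, probes in gene_probes.items():
        peak = max(
            probes, key=lambda p: np.nanmax(np.abs(combined.loc[p].to_numpy()))
        )
        rows.append(combined.loc[peak].rename(ensg))
    out = pd.DataFrame(rows).sort_index()
    out.index.name = "ensg"
    out.attrs["zscore_axis"] = axis
    return out


def write_region_ztable(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="ensg")


def read_region_ztable(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="ensg")
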