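"""Expression preprocessing: sample de-duplication, quantile normalisation,
and median collapse of probes onto gene symbols.

The input is a probe-level log2 matrix that is assumed to be background
corrected upstream; quantile normalisation here equalises the per-sample
distributions, and probes mapping to zero or to multiple genes are dropped
before the per-gene median collapse.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .data import ExpressionData


def dedupe_samples(
    data: ExpressionData, duplicate_map: list[list[str]]
) -> ExpressionData:
    """Keep the first member of each known replicate group, drop the rest.

    ``duplicate_map`` is a list of sample-id groups known to be technical
    replicates of one biological sample; order within a group decides the
    survivor.
    """
    known = set(data.values.columns)
    drop: set[str] = set()
    for group in duplicate_map:
        unknown = [s for s in group if s not in known]
        if unknown:
            raise KeyError(f"unknown sample ids in duplicate map: {unknown}")
        drop.update(group[1:])
    keep = [s for s in data.values.columns if s not in drop]
    return data.subset_samples(keep)


def quantile_normalize(data: ExpressionData) -> ExpressionData:
    """Force every sample onto the common mean distribution of order statistics.

    After normalisation, sample j's sorted values all equal the across-sample
    mean of the sorted columns; tied values within a sample share the mean of
    their rank values. Idempotent.
    """
    vals = data.values
    if vals.isna().any().any():
        raise ValueError("quantile normalisation requires a complete matrix")
    x = vals.to_numpy(dtype=float)
    order = np.sort(x, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        # average ranks so ties share the mean reference value
        ranks = pd.Series(x[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    values = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return replace(data, values=values)


def collapse_probes_median(data: ExpressionData) -> ExpressionData:
    """Collapse a probe-level matrix to gene level by per-gene medians.

    Probes mapping to no gene or to more than one gene are discarded; each
    remaining gene's per-sample value is the median over its probes.
    """
    if data.level != "probe":
        raise ValueError("collapse expects a probe-level matrix")
    if data.probe_to_gene is None:
        raise ValueError("probe_to_gene mapping required")
    mapping = data.probe_to_gene
    counts = mapping.groupby("probe_id")["gene_symbol"].nunique()
    unique_probes = counts.index[counts == 1]
    usable = mapping[mapping["probe_id"].isin(unique_probes)].drop_duplicates()
    usable = usable[usable["probe_id"].isin(data.values.index)]
    if usable.empty:
        raise ValueError("no probe maps uniquely to a gene")
    sub = data.values.loc[usable["probe_id"]]
    gene_index = pd.Index(usable["gene_symbol"].to_numpy(), name="gene")
    collapsed = sub.groupby(gene_index, sort=True).median()
    return replace(data, values=collapsed, level="gene", probe_to_gene=None)


def preprocess(
    data: ExpressionData, duplicate_map: list[list[str]] | None = None
) -> ExpressionData:
    """De-duplicate, quantile-normalise, and collapse probes to genes."""
    out = dedupe_samples(data, duplicate_map or [])
    out = quantile_normalize(out)
    return collapse_probes_median(out)
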