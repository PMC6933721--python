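"""Methylation preprocessing.

The preparation chain for 450K-style promoter methylation analysis:

1. :func:`beta_to_m` — variance-stabilising logit2 transform,
   ``M = log2(beta / (1 - beta))``, with epsilon clipping at the boundary.
2. :func:`filter_missing` — drop CpG probes, then samples, whose missing
   fraction exceeds a threshold (default 20% for both).
3. :func:`impute_knn` — k-nearest-probe mean imputation of the remaining
   missing entries.
4. :func:`filter_blacklist` — remove sex-chromosome, SNP-overlapping and
   cross-hybridising probes.
5. :func:`restrict_promoter` — keep probes annotated to promoter-proximal
   region classes (TSS1500, TSS200, 5'UTR, first exon).

All functions return new :class:`~epihub.data.MethylationData` objects and
never mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import PROMOTER_CLASSES, MethylationData, ScaleError


@dataclass
class FilterReport:
    """Ids removed by a preprocessing step, for the run report."""

    dropped_probes: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_dropped_probes": len(self.dropped_probes),
            "n_dropped_samples": len(self.dropped_samples),
            "dropped_probes": list(self.dropped_probes),
            "dropped_samples": list(self.dropped_samples),
        }


def beta_to_m(data: MethylationData, epsilon: float = 1e-6) -> MethylationData:
    """Convert beta values to M-values, ``M = log2(beta / (1 - beta))``.

    Betas are clipped to ``[epsilon, 1 - epsilon]`` first so that fully
    (un)methylated probes map to large finite M rather than +/-inf. Missing
    entries stay missing.
    """
    if data.scale != "beta":
        raise ScaleError(f"beta_to_m expects beta-scale data, got {data.scale!r}")
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    beta = data.values.to_numpy(dtype=float)
    clipped = np.clip(beta, epsilon, 1 - epsilon)
    m = np.log2(clipped / (1 - clipped))
    m[~np.isfinite(beta)] = np.nan
    values = pd.DataFrame(m, index=data.values.index, columns=data.values.columns)
    return replace(data, values=values, scale="M")


def filter_missing(
    data: MethylationData,
    max_probe_missing: float = 0.2,
    max_sample_missing: float = 0.2,
) -> tuple[MethylationData, FilterReport]:
    """Drop probes, then samples, with too many missing values.

    Probe missingness is evaluated on the full sample set first; sample
    missingness is then evaluated on the surviving probes only. The order
    matters on edge cases and is fixed here.
    """
    for frac in (max_probe_missing, max_sample_missing):
        if not 0 < frac <= 1:
            raise ValueError("missingness thresholds must be in (0, 1]")
    vals = data.values
    probe_frac = vals.isna().mean(axis=1)
    keep_probes = probe_frac.index[probe_frac <= max_probe_missing]
    dropped_probes = probe_frac.index.difference(keep_probes)
    surviving = vals.loc[keep_probes]
    if surviving.empty:
        raise ValueError("all probes filtered out by missingness threshold")
    sample_frac = surviving.isna().mean(axis=0)
    keep_samples = sample_frac.index[sample_frac <= max_sample_missing]
    dropped_samples = sample_frac.index.difference(keep_samples)
    if not len(keep_samples):
        raise ValueError("all samples filtered out by missingness threshold")
    out = replace(
        data,
        values=surviving[keep_samples],
        probes=data.probes.loc[keep_probes],
        samples=data.samples.loc[keep_samples],
    )
    return out, FilterReport(list(dropped_probes), list(dropped_samples))


def _knn_impute_matrix(x: np.ndarray, k: int) -> np.ndarray:
    """Impute NaNs in a probes-by-samples matrix by k-nearest-probe means.

    Distance between probes is the Euclidean distance over samples observed
    in both. For a missing cell (i, s) the imputed value is the mean of the
    k nearest probes that are observed in sample s. Ties in distance break
    by row order, which keeps the procedure deterministic.
    """
    n_probes = x.shape[0]
    observed = np.isfinite(x)
    if not observed.any(axis=1).all():
        raise ValueError("probe with all entries missing; run filter_missing first")
    xz = np.where(observed, x, 0.0)
    mask = observed.astype(float)
    sq = xz**2
    out = x.copy()
    rows_missing = np.where(~observed.all(axis=1))[0]
    # Blockwise masked squared distances: sum over shared coords of
    # xi^2 + xj^2 - 2 xi xj.
    block = 512
    for start in range(0, len(rows_missing), block):
        rows = rows_missing[start : start + block]
        d2 = (
            sq[rows] @ mask.T
            + mask[rows] @ sq.T
            - 2.0 * (xz[rows] @ xz.T)
        )
        d2 = np.maximum(d2, 0.0)
        for bi, i in enumerate(rows):
            dist = d2[bi].copy()
            dist[i] = np.inf
            order = None
            for s in np.where(~observed[i])[0]:
                cand_ok = observed[:, s]
                # cheap top-(k+pad) pass; widen to a full sort only if the
                # short list lacks k observed candidates
                pad = min(n_probes - 1, k + 16)
                short = np.argpartition(dist, pad - 1)[:pad]
                short = short[np.argsort(dist[short], kind="stable")]
                picked = [j for j in short if cand_ok[j]][:k]
                if len(picked) < k:
                    if order is None:
                        order = np.argsort(dist, kind="stable")
                    picked = [j for j in order if cand_ok[j]][:k]
                if not picked:
                    raise ValueError(
                        f"no observed neighbours available for cell ({i}, {s})"
                    )
                out[i, s] = x[picked, s].mean()
    return out


def impute_knn(data: MethylationData, k: int = 10) -> MethylationData:
    """Replace missing entries by the mean over the k nearest probes.

    Deterministic; observed entries are preserved bit-exactly. ``k=10``
    matches the customary default for nearest-neighbour imputation of
    array data.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= data.values.shape[0]:
        raise ValueError("k must be smaller than the number of probes")
    x = data.values.to_numpy(dtype=float)
    if np.isfinite(x).all():
        return replace(data, values=data.values.copy())
    imputed = _knn_impute_matrix(x, k)
    values = pd.DataFrame(
        imputed, index=data.values.index, columns=data.values.columns
    )
    return replace(data, values=values)


def filter_blacklist(data: MethylationData) -> tuple[MethylationData, FilterReport]:
    """Remove sex-chromosome, SNP-targeting and cross-hybridising probes."""
    probes = data.probes
    bad = (
        probes["chromosome"].isin(["chrX", "chrY"])
        | probes["flag_snp"].astype(bool)
        | probes["flag_crosshyb"].astype(bool)
    )
    keep = probes.index[~bad.to_numpy()]
    dropped = probes.index[bad.to_numpy()]
    return data.subset_probes(keep), FilterReport(dropped_probes=list(dropped))


def restrict_promoter(data: MethylationData) -> tuple[MethylationData, FilterReport]:
    """Keep probes annotated to promoter-proximal region classes."""
    region = data.probes["region_class"]
    keep = region.index[region.isin(PROMOTER_CLASSES).to_numpy()]
    dropped = region.index.difference(keep)
    return data.subset_probes(keep), FilterReport(dropped_probes=list(dropped))


def preprocess(
    data: MethylationData,
    max_probe_missing: float = 0.2,
    max_sample_missing: float = 0.2,
    knn_k: int = 10,
    epsilon: float = 1e-6,
) -> tuple[MethylationData, dict]:
    """Full preprocessing chain: M transform, filters, imputation, promoter cut."""
    m = beta_to_m(data, epsilon=epsilon)
    m, miss_rep = filter_missing(m, max_probe_missing, max_sample_missing)
    m = impute_knn(m, k=knn_k)
    m, black_rep = filter_blacklist(m)
    m, prom_rep = restrict_promoter(m)
    report = {
        "missingness": miss_rep.to_dict(),
        "blacklist": black_rep.to_dict(),
        "promoter": prom_rep.to_dict(),
        "n_probes_final": int(m.values.shape[0]),
        "n_samples_final": int(m.values.shape[1]),
    }
    return m, report
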