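"""Shared data containers and TSV I/O.

Two array-backed containers travel through the whole analysis:

* :class:`MethylationData` — a CpG-by-sample matrix of beta values
  (methylation fractions in [0, 1]) or M-values (logit2 of beta), plus a
  probe annotation table mapping each CpG to a gene symbol, an Illumina
  region class, a chromosome and quality flags.
* :class:`ExpressionData` — a feature-by-sample log2 expression matrix at
  probe or gene level, plus sample metadata carrying the case/control
  condition label and any clinical covariates.

Both are thin dataclasses around :class:`pandas.DataFrame` so that all
downstream statistics stay label-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

PROMOTER_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon")
REGION_CLASSES = PROMOTER_CLASSES + ("Body", "3UTR")
CONDITIONS = ("GDM", "control")

PROBE_COLUMNS = [
    "gene_symbol",
    "region_class",
    "chromosome",
    "flag_snp",
    "flag_crosshyb",
]


class ScaleError(ValueError):
    """Raised when an operation receives methylation data on the wrong scale."""


@dataclass
class MethylationData:
    """CpG-by-sample methylation matrix with probe and sample annotation.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample ids. Entries are
        beta values in [0, 1] (``scale="beta"``) or M-values (``scale="M"``);
        NaN marks a missing measurement.
    probes
        DataFrame indexed by probe id with columns ``gene_symbol``,
        ``region_class``, ``chromosome``, ``flag_snp``, ``flag_crosshyb``.
    samples
        DataFrame indexed by sample id with at least a ``condition`` column
        (``GDM`` or ``control``).
    scale
        ``"beta"`` or ``"M"``.
    """

    values: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ScaleError(f"unknown methylation scale {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing_ann = self.values.index.difference(self.probes.index)
        if len(missing_ann):
            raise ValueError(
                f"{len(missing_ann)} matrix rows lack probe annotation "
                f"(e.g. {list(missing_ann[:3])})"
            )
        if self.scale == "beta":
            vals = self.values.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids) -> "MethylationData":
        probe_ids = pd.Index(probe_ids)
        return replace(
            self,
            values=self.values.loc[probe_ids],
            probes=self.probes.loc[probe_ids],
        )

    def subset_samples(self, sample_ids) -> "MethylationData":
        sample_ids = pd.Index(sample_ids)
        return replace(
            self,
            values=self.values[sample_ids],
            samples=self.samples.loc[sample_ids],
        )


@dataclass
class ExpressionData:
    """Feature-by-sample log2 expression matrix with sample metadata.

    ``level`` is ``"probe"`` before annotation collapse and ``"gene"``
    afterwards. ``probe_to_gene`` is a two-column frame (``probe_id``,
    ``gene_symbol``); a probe annotated to several genes appears on several
    rows, a probe with no gene does not appear at all.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    level: str = "gene"
    probe_to_gene: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"unknown feature level {self.level!r}")
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        extra = self.values.columns.difference(self.samples.index)
        if len(extra):
            raise ValueError(f"samples without metadata: {list(extra[:3])}")
        if "condition" in self.samples.columns:
            bad = set(self.samples["condition"]) - set(CONDITIONS)
            if bad:
                raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def condition_of(self, sample_ids=None) -> pd.Series:
        ids = self.values.columns if sample_ids is None else pd.Index(sample_ids)
        return self.samples.loc[ids, "condition"]

    def subset_samples(self, sample_ids) -> "ExpressionData":
        sample_ids = pd.Index(sample_ids)
        return replace(
            self,
            values=self.values[sample_ids],
            samples=self.samples.loc[sample_ids],
        )

    def group_samples(self) -> dict[str, list[str]]:
        cond = self.condition_of()
        return {c: list(cond.index[cond == c]) for c in CONDITIONS}


# ---------------------------------------------------------------------------
# TSV I/O


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t")


def read_probe_annotation_tsv(path) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("flag_snp", "flag_crosshyb"):
        if col in probes.columns:
            probes[col] = probes[col].astype(bool)
    return probes


def read_sample_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
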