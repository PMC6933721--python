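import numpy as np
import pandas as pd
import pytest

from epihub import syndata
from epihub.data import ExpressionData, MethylationData


@pytest.fixture(scope="session")
def default_study():
    """One default-shape synthetic study (seed 1) shared across tests."""
    cfg = syndata.SynthConfig(seed=1)
    meth, expr, truth = syndata.generate_cohort(cfg)
    docs, edges = syndata.generate_kgml(
        cfg, list(expr.values.index), hub_genes=truth.hub_genes
    )
    truth.true_edges = edges
    return cfg, meth, expr, truth, docs


@pytest.fixture()
def toy_expr():
    """4 genes x 6 samples, 3 GDM / 3 control, hand-checkable."""
    values = pd.DataFrame(
        {
            "s1": [3.0, 1.0, 5.0, 2.0],
            "s2": [5.0, 1.0, 5.0, 2.0],
            "s3": [4.0, 1.0, 5.0, 2.0],
            "s4": [1.0, 1.0, 5.0, 4.0],
            "s5": [3.0, 1.0, 5.0, 4.0],
            "s6": [2.0, 1.0, 5.0, 4.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    samples = pd.DataFrame(
        {"condition": ["GDM"] * 3 + ["control"] * 3},
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionData(values=values, samples=samples, level="gene")


def make_meth(values: pd.DataFrame, scale: str = "beta",
              probes: pd.DataFrame | None = None) -> MethylationData:
    if probes is None:
        probes = pd.DataFrame(
            {
                "gene_symbol": [f"g{i}" for i in range(len(values))],
                "region_class": "TSS200",
                "chromosome": "chr1",
                "flag_snp": False,
                "flag_crosshyb": False,
            },
            index=values.index,
        )
    samples = pd.DataFrame(
        {"condition": ["GDM"] * len(values.columns)},
        index=pd.Index(values.columns, name="sample_id"),
    )
    return MethylationData(values=values, probes=probes, samples=samples,
                           scale=scale)
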