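"""Baseline-characteristics statistics (Table-1 style).

Continuous covariates are compared between groups with a pooled-variance
(Student) two-sample t-test, computable either from raw data or from the
published mean/SD/n summaries alone; categorical covariates with a Pearson
chi-square on the contingency table, with the Yates continuity correction
for 2x2 tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SummaryStat:
    """Mean, standard deviation and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_data(cls, x) -> "SummaryStat":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


def t_test_summary(a: SummaryStat, b: SummaryStat) -> tuple[float, int, float]:
    """Pooled two-sample t-test from group summaries.

    Returns (t, df, p) with sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2),
    t = (m1-m2)/sqrt(sp^2 (1/n1 + 1/n2)), df = n1+n2-2, two-sided p.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        if a.mean == b.mean:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = (a.mean - b.mean) / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, min(p, 1.0)


def t_test_raw(x, y) -> tuple[float, int, float]:
    """Pooled two-sample t-test on raw per-group vectors."""
    return t_test_summary(SummaryStat.from_data(x), SummaryStat.from_data(y))


def welch_t_test(a: SummaryStat, b: SummaryStat) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summaries (optional variant)."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ValueError("zero variance with unequal means")
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, min(p, 1.0)


def chi_square(table, yates: bool = True) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table.

    The Yates correction (|O-E| reduced by 0.5, floored at 0) applies only
    to 2x2 tables; for larger tables the flag is ignored. Zero row or
    column margins are rejected.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    diff = np.abs(obs - expected)
    if yates and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, min(p, 1.0)


def build_table1(
    metadata: pd.DataFrame,
    continuous: list[str],
    categorical: list[str] | None = None,
    group_col: str = "condition",
) -> pd.DataFrame:
    """Per-variable group summaries and tests from sample metadata.

    For each continuous variable: per-group mean (sd) and a pooled t-test p.
    For each categorical variable: per-group counts and a chi-square p
    (Yates-corrected when 2x2). Variables absent from the metadata are
    reported as not computable.
    """
    groups = metadata[group_col].unique()
    if len(groups) != 2:
        raise ValueError("table-1 comparison needs exactly 2 groups")
    g1, g2 = sorted(groups)
    rows = []
    for var in continuous:
        if var not in metadata.columns:
            rows.append({"variable": var, "type": "continuous", "p": np.nan,
                         "note": "not computable: missing column"})
            continue
        a = metadata.loc[metadata[group_col] == g1, var].dropna()
        b = metadata.loc[metadata[group_col] == g2, var].dropna()
        t, df, p = t_test_raw(a, b)
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                f"{g1}_summary": f"{a.mean():.3f} ({a.std(ddof=1):.3f})",
                f"{g2}_summary": f"{b.mean():.3f} ({b.std(ddof=1):.3f})",
                "statistic": t,
                "p": p,
                "note": "",
            }
        )
    for var in categorical or []:
        if var not in metadata.columns:
            rows.append({"variable": var, "type": "categorical", "p": np.nan,
                         "note": "not computable: missing column"})
            continue
        ct = pd.crosstab(metadata[var], metadata[group_col])
        if ct.shape[0] < 2:
            rows.append({"variable": var, "type": "categorical", "p": np.nan,
                         "note": "not computable: single level"})
            continue
        statistic, df, p = chi_square(ct.to_numpy(), yates=ct.shape == (2, 2))
        rows.append(
            {
                "variable": var,
                "type": "categorical",
                f"{g1}_summary": "/".join(str(v) for v in ct[g1]),
                f"{g2}_summary": "/".join(str(v) for v in ct[g2]),
                "statistic": statistic,
                "p": p,
                "note": "",
            }
        )
    return pd.DataFrame(rows)
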