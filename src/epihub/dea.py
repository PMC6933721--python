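"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene g with case mean difference fc_g, pooled residual variance s2_g on
d = n1 + n2 - 2 degrees of freedom, the moderated analysis borrows strength
across genes by shrinking each s2_g toward a prior variance s0^2 with prior
degrees of freedom d0:

    s2_post = (d0 * s0^2 + d * s2_g) / (d0 + d)
    t_mod   = fc_g / sqrt(s2_post * (1/n1 + 1/n2))

and refers t_mod to a t distribution with d0 + d degrees of freedom (a
normal reference in the d0 -> inf limit). (d0, s0^2) are estimated by moment
matching on log s2: because d * s2_g / sigma_g^2 is chi-square with d df and
sigma_g^2 is scaled inverse chi-square (s0^2, d0) under the hierarchical
model, log s2_g has a known mean/variance decomposition in terms of digamma
and trigamma functions, leaving a single monotone trigamma equation for d0
solved by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data import ExpressionData

UP_IN_GDM = "up_in_GDM"
UP_IN_CONTROL = "up_in_control"


@dataclass(frozen=True)
class EBayesParams:
    """Prior degrees of freedom and prior variance of the variance hierarchy."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def fit_gene_models(expr: ExpressionData) -> pd.DataFrame:
    """Ordinary two-group linear fits for every gene.

    Returns a frame indexed by gene with columns ``log2_fc`` (GDM - control),
    ``s2`` (pooled residual variance), ``se``, ``df_residual``, ``n1``, ``n2``.
    """
    groups = expr.group_samples()
    case_ids, control_ids = groups["GDM"], groups["control"]
    n1, n2 = len(case_ids), len(control_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    case = expr.values[case_ids].to_numpy(dtype=float)
    control = expr.values[control_ids].to_numpy(dtype=float)
    fc = case.mean(axis=1) - control.mean(axis=1)
    rss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    rss += ((control - control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = rss / df
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return pd.DataFrame(
        {
            "log2_fc": fc,
            "s2": s2,
            "se": se,
            "df_residual": df,
            "n1": n1,
            "n2": n2,
        },
        index=expr.values.index,
    )


def _solve_trigamma(target: float) -> float:
    """Solve trigamma(y) = target for y > 0 by monotone bisection."""
    lo, hi = 1e-12, 1e12
    # trigamma is strictly decreasing from +inf to 0 on (0, inf)
    for _ in range(400):
        mid = math.sqrt(lo * hi)
        if special.polygamma(1, mid) > target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-14:
            break
    return math.sqrt(lo * hi)


def estimate_ebayes(s2, df_residual: int) -> EBayesParams:
    """Moment-matching estimate of (d0, s0_sq) from the gene-wise variances.

    Genes with non-positive sample variance carry no information about the
    hierarchy and are excluded from the moment fit. When the dispersion of
    log s2 does not exceed what sampling noise alone predicts, d0 = +inf and
    s0_sq is the common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError("need at least 2 genes with positive variance")
    d = float(df_residual)
    z = np.log(pos)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    n = pos.size
    e_mean = e.mean()
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    excess = e_var - special.polygamma(1, d / 2.0)
    if excess <= 0:
        # no excess dispersion: all true variances equal; plain mean is the
        # natural common-variance estimate in this limit
        return EBayesParams(d0=math.inf, s0_sq=float(pos.mean()))
    y = _solve_trigamma(float(excess))
    d0 = 2.0 * y
    s0_sq = float(np.exp(e_mean + special.digamma(y) - math.log(y)))
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def moderated_t(fit: pd.DataFrame, params: EBayesParams) -> pd.DataFrame:
    """Moderated t-statistics, two-sided p-values and direction calls."""
    s2 = fit["s2"].to_numpy(dtype=float)
    fc = fit["log2_fc"].to_numpy(dtype=float)
    df = fit["df_residual"].to_numpy(dtype=float)
    n1 = fit["n1"].to_numpy(dtype=float)
    n2 = fit["n2"].to_numpy(dtype=float)
    if math.isinf(params.d0):
        s2_post = np.full_like(s2, params.s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
        df_total = params.d0 + df
    se_mod = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se_mod > 0, fc / se_mod, 0.0)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t_mod)),
        2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    direction = np.where(fc > 0, UP_IN_GDM, UP_IN_CONTROL)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p"] = p
    out["direction"] = direction
    return out


def run_dea(expr: ExpressionData, alpha: float = 0.05) -> pd.DataFrame:
    """Fit, shrink, test; adds a boolean ``significant`` column at raw p < alpha.

    No multiple-testing correction is applied to the screen: the declared
    threshold for calling a differentially expressed gene is the raw p-value.
    """
    fit = fit_gene_models(expr)
    params = estimate_ebayes(fit["s2"], int(fit["df_residual"].iloc[0]))
    table = moderated_t(fit, params)
    table["significant"] = table["p"] < alpha
    return table


def deg_summary(table: pd.DataFrame) -> dict:
    sig = table[table["significant"]]
    return {
        "n_deg": int(len(sig)),
        "n_up_in_GDM": int((sig["direction"] == UP_IN_GDM).sum()),
        "n_up_in_control": int((sig["direction"] == UP_IN_CONTROL).sum()),
    }
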