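"""Over-representation analysis of a gene list against GMT gene-set collections.

Significance of the overlap k between a DEG list of size n and a gene set of
size K inside a universe of N genes is the hypergeometric upper tail

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

accumulated in log space for numerical safety. Benjamini-Hochberg q-values
are reported per category alongside the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    name: str
    genes: frozenset
    category: str = "pathway"
    description: str = ""


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("gene set names must be unique")
        for s in self.sets:
            if not s.genes:
                raise ValueError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path, category: str = "pathway") -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene1 TAB gene2 ...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(
                GeneSet(
                    name=name,
                    description=desc,
                    genes=frozenset(genes),
                    category=category,
                )
            )
    return GeneSetCollection(sets)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value, computed in log space."""
    if min(k, K, n, N) < 0 or K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich(
    deg_genes,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ORA of ``deg_genes`` against every set, restricted to ``universe``.

    Returns one row per set: overlap k, set size K and DEG count n within
    the universe, universe size N, raw p, BH q within category, and a
    ``significant`` flag at raw p < alpha.
    """
    universe = set(universe)
    deg = set(deg_genes) & universe
    if not set(deg_genes) <= universe:
        raise ValueError("DEG list must be contained in the universe")
    N, n = len(universe), len(deg)
    rows = []
    for s in collection:
        members = s.genes & universe
        K = len(members)
        k = len(members & deg)
        p = hypergeom_test(k, K, n, N) if (K and n) else 1.0
        rows.append(
            {
                "set": s.name,
                "category": s.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table["q"] = []
        table["significant"] = []
        return table
    q = np.full(len(table), np.nan)
    for cat, idx in table.groupby("category").groups.items():
        q[np.asarray(idx)] = multipletests(
            table.loc[idx, "p"].to_numpy(), method="fdr_bh"
        )[1]
    table["q"] = q
    table["significant"] = table["p"] < alpha
    return table.sort_values("p", kind="stable").reset_index(drop=True)
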