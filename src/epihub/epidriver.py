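"""Epigenetically driven gene screen and gene-gene-CpG network analysis.

A pathway-network gene is called *epigenetically driven* when the
methylation M-value of at least one of its promoter CpGs is significantly
negatively Pearson-correlated with the gene's expression across matched
samples (r < 0, two-sided p below alpha). Driver genes, their retained
CpGs, and the pathway edges among driver genes form a mixed
gene-gene-CpG network; hub genes are the intersection of the top-k gene
lists by degree, harmonic closeness, and betweenness centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionData, MethylationData, ScaleError

logger = logging.getLogger(__name__)

GENE_NODE = "gene"
CPG_NODE = "cpg"


def match_samples(expr: ExpressionData, meth: MethylationData) -> list[str]:
    """Sample ids present in both datasets, in expression order."""
    meth_ids = set(meth.sample_ids)
    matched = [s for s in expr.sample_ids if s in meth_ids]
    if not matched:
        raise ValueError("no samples shared between expression and methylation")
    return matched


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p from the t reference on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def screen_negative(
    expr: ExpressionData,
    meth: MethylationData,
    network_genes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Negative promoter-methylation/expression correlation screen.

    Tests every (gene in ``network_genes``, promoter CpG annotated to that
    gene) pair on the matched samples and keeps rows with r < 0 and
    p < alpha. The methylation input must already be M-scale and restricted
    to promoter probes. Returns the DriverTable with columns
    ``gene, cpg, r, p, n``.
    """
    if meth.scale != "M":
        raise ScaleError("screen_negative expects M-scale methylation data")
    matched = match_samples(expr, meth)
    n = len(matched)
    if n < 3:
        raise ValueError("need at least 3 matched samples")
    genes = [g for g in dict.fromkeys(network_genes) if g in expr.values.index]
    ann = meth.probes[meth.probes["gene_symbol"].isin(genes)]
    if ann.empty:
        return pd.DataFrame(columns=["gene", "cpg", "r", "p", "n"])
    cpgs = ann.index
    e = expr.values.loc[ann["gene_symbol"], matched].to_numpy(dtype=float)
    m = meth.values.loc[cpgs, matched].to_numpy(dtype=float)
    ec = e - e.mean(axis=1, keepdims=True)
    mc = m - m.mean(axis=1, keepdims=True)
    denom = np.sqrt((ec**2).sum(axis=1) * (mc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip((ec * mc).sum(axis=1) / denom, -1.0, 1.0)
    r = np.where(denom > 0, r, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, np.minimum(p, 1.0))
    table = pd.DataFrame(
        {
            "gene": ann["gene_symbol"].to_numpy(),
            "cpg": cpgs,
            "r": r,
            "p": p,
            "n": n,
        }
    )
    kept = table[(table["r"] < 0) & (table["p"] < alpha)]
    return kept.reset_index(drop=True)


def build_network(pathway: nx.Graph, drivers: pd.DataFrame) -> nx.Graph:
    """Assemble the mixed gene-gene-CpG network from the driver table.

    Gene nodes are the driver genes; gene-gene edges are the pathway edges
    among them; each retained CpG becomes a node tied to its gene.
    """
    if drivers.empty:
        raise ValueError("driver table is empty; nothing to build")
    net = nx.Graph()
    driver_genes = list(dict.fromkeys(drivers["gene"]))
    for g in driver_genes:
        net.add_node(g, node_type=GENE_NODE)
    for a, b in pathway.edges:
        if net.has_node(a) and net.has_node(b):
            net.add_edge(a, b, edge_type="gene-gene")
    for row in drivers.itertuples(index=False):
        net.add_node(row.cpg, node_type=CPG_NODE)
        net.add_edge(row.gene, row.cpg, edge_type="gene-cpg", r=row.r, p=row.p)
    return net


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, harmonic closeness, and betweenness for the gene nodes.

    Centralities are computed on the full mixed graph (CpG nodes contribute
    as path members) but reported for gene nodes only. Closeness is the
    harmonic form, sum over reachable vertices of 1/d(u, v), which stays
    well defined on disconnected networks; betweenness is unnormalised over
    unordered vertex pairs.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degree = dict(net.degree())
    closeness = nx.harmonic_centrality(net)
    betweenness = nx.betweenness_centrality(net, normalized=False)
    genes = [n for n, d in net.nodes(data=True) if d.get("node_type") == GENE_NODE]
    table = pd.DataFrame(
        {
            "degree": [degree[g] for g in genes],
            "closeness": [closeness[g] for g in genes],
            "betweenness": [betweenness[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    for metric in ("degree", "closeness", "betweenness"):
        table[f"{metric}_rank"] = (
            table[metric].rank(method="dense", ascending=False).astype(int)
        )
    return table.sort_index()


def select_hubs(table: pd.DataFrame, k: int = 10, frac: float | None = None):
    """Intersection of the top-k gene lists by the three centralities.

    ``k`` is an absolute cutoff applied with dense ranks, so value ties at
    the k-th rank are all included and the result is row-order invariant.
    Passing ``frac`` instead ranks by top fraction of genes (e.g. 0.10 for
    the top 10%), with k = ceil(frac * n_genes).
    """
    if frac is not None:
        if not 0 < frac <= 1:
            raise ValueError("frac must be in (0, 1]")
        k = int(np.ceil(frac * len(table)))
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) < k:
        raise ValueError("fewer gene nodes than k")
    tops = []
    for metric in ("degree", "closeness", "betweenness"):
        ranks = table[metric].rank(method="dense", ascending=False)
        tops.append(set(table.index[ranks <= k]))
    hubs = sorted(tops[0] & tops[1] & tops[2])
    if not hubs:
        logger.warning("hub selection produced an empty intersection")
    return hubs
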