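"""KGML pathway parsing and gene-interaction network construction.

KGML (KEGG Markup Language) encodes one pathway per XML document as
``entry`` elements (genes, or ``group`` containers of other entries) joined
by ``relation`` elements. Here each gene entry expands to the gene symbols
of all its listed aliases, each group expands to the union of its members'
genes, and each relation contributes the Cartesian set of gene-gene pairs
between the two expansions. Orientation and relation subtype do not affect
the topology: the result is a simple undirected graph whose edges carry the
contributing pathway ids and relation subtypes as provenance attributes.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)


def read_id_to_symbol_tsv(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def _entry_genes(entry, id_to_symbol) -> set[str]:
    genes = set()
    for alias in (entry.get("name") or "").split():
        symbol = id_to_symbol.get(alias)
        if symbol is None:
            logger.warning("no symbol mapping for gene id %s; skipped", alias)
        else:
            genes.add(symbol)
    return genes


def parse_kgml(source, id_to_symbol: dict[str, str]) -> nx.Graph:
    """Parse one KGML document into an undirected gene-gene graph.

    ``source`` is a path, file-like, or XML bytes/string. Entries whose ids
    cannot be mapped to a symbol are skipped with a warning, as are
    relations referencing unknown entry ids.
    """
    if isinstance(source, (bytes, str)) and str(source).lstrip().startswith("<"):
        root = etree.fromstring(
            source.encode() if isinstance(source, str) else source
        )
    else:
        root = etree.parse(str(source)).getroot()
    pathway_id = root.get("name", "unknown")

    expansion: dict[str, set[str]] = {}
    groups: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "gene":
            expansion[eid] = _entry_genes(entry, id_to_symbol)
        elif etype == "group":
            groups[eid] = [c.get("id") for c in entry.findall("component")]
        # other entry types (compound, map, ...) carry no gene edges
    for gid, members in groups.items():
        expansion[gid] = set().union(
            *(expansion.get(m, set()) for m in members)
        )

    graph = nx.Graph(pathway_ids={pathway_id})
    for genes in expansion.values():
        graph.add_nodes_from(genes)
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in expansion or e2 not in expansion:
            logger.warning(
                "relation %s-%s references unknown entry; skipped", e1, e2
            )
            continue
        subtype = ",".join(
            sorted(st.get("name", "") for st in rel.findall("subtype"))
        )
        for a, b in itertools.product(expansion[e1], expansion[e2]):
            if a == b:
                continue
            _add_edge(graph, a, b, pathway_id, subtype)
    return graph


def _add_edge(graph: nx.Graph, a: str, b: str, pathway_id: str, subtype: str):
    if graph.has_edge(a, b):
        data = graph.edges[a, b]
        data["pathways"] = sorted(set(data["pathways"]) | {pathway_id})
        if subtype:
            data["relation_types"] = sorted(
                set(data["relation_types"]) | {subtype}
            )
    else:
        graph.add_edge(
            a,
            b,
            pathways=[pathway_id],
            relation_types=[subtype] if subtype else [],
        )


def merge_graphs(graphs) -> nx.Graph:
    """Union of pathway graphs; shared edges accumulate their provenance."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("merge_graphs needs at least one graph")
    merged = nx.Graph(
        pathway_ids=set().union(*(g.graph.get("pathway_ids", set()) for g in graphs))
    )
    for g in graphs:
        merged.add_nodes_from(g.nodes)
        for a, b, data in g.edges(data=True):
            for pid in data.get("pathways", []):
                _add_edge(
                    merged, a, b, pid, ",".join(data.get("relation_types", []))
                )
            if not data.get("pathways"):
                _add_edge(merged, a, b, "unknown", "")
    return merged


def edge_set(graph: nx.Graph) -> set[tuple[str, str]]:
    """Canonical (sorted-pair) edge set, for comparisons."""
    return {tuple(sorted((a, b))) for a, b in graph.edges}


def degree_distribution(graph: nx.Graph) -> tuple[dict[int, int], float]:
    """Degree histogram plus the log-log least-squares slope.

    The slope of log10(frequency) against log10(degree) over degrees >= 1
    with nonzero counts is descriptive only; a clearly negative slope is the
    signature of a heavy-tailed, scale-free-like network.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("degree distribution of an empty graph")
    hist = Counter(d for _, d in graph.degree())
    pts = [(d, c) for d, c in hist.items() if d >= 1]
    if len(pts) >= 2:
        logd = np.log10([d for d, _ in pts])
        logc = np.log10([c for _, c in pts])
        slope = float(np.polyfit(logd, logc, 1)[0])
    else:
        slope = float("nan")
    return dict(sorted(hist.items())), slope


def write_sif(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edge_set(graph)):
            fh.write(f"{a}\tinteracts\t{b}\n")
    # isolated nodes get their own line so they survive a round trip
    isolated = [n for n in graph.nodes if graph.degree(n) == 0]
    if isolated:
        with open(path, "a") as fh:
            for n in sorted(isolated):
                fh.write(f"{n}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    out = nx.Graph()
    out.add_nodes_from(graph.nodes(data=True))
    for a, b, data in graph.edges(data=True):
        out.add_edge(
            a,
            b,
            pathways=";".join(data.get("pathways", [])),
            relation_types=";".join(data.get("relation_types", [])),
        )
    nx.write_graphml(out, path)
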