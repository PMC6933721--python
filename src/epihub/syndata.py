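"""Synthetic paired methylation/expression cohorts with known ground truth.

The generator emulates the structure of a placental GDM case/control study:

* a methylation cohort (default 41 GDM / 41 control samples) assayed on a
  450K-style array, delivered as a CpG-by-sample beta matrix plus probe
  annotation (gene, Illumina region class, chromosome, quality flags);
* a smaller expression cohort (default 30 / 25) whose sample ids are a
  subset of the methylation ids, delivered as a gene-by-sample log2 matrix
  already on the normalised scale;
* planted differentially expressed genes with signed log2 fold-changes;
* planted *driver* genes whose promoter-CpG M-values are linearly coupled
  to their expression with negative slope, noise-tuned so the expected
  Pearson correlation hits a target (default -0.6);
* a scale-free pathway network over all genes, grown by preferential
  attachment seeded on the planted hub drivers, serialised as KGML XML
  documents with entry/relation/group elements;
* an optional external validation cohort (default 6 GDM / 177 normal) that
  reuses the same gene baselines and effects.

Every random draw flows from ``SynthConfig.seed`` through fixed stream
keys, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionData, MethylationData

PROMOTER_CHOICES = ("TSS1500", "TSS200", "5UTR", "1stExon")
NONPROMOTER_CHOICES = ("Body", "3UTR")

# rng stream keys (second word of the seed sequence)
_STREAM_COHORT = 1
_STREAM_KGML = 2
_STREAM_EXTERNAL = 3


@dataclass(frozen=True)
class SynthConfig:
    """Study-shape parameters of the synthetic cohort.

    Cohort sizes, planted effect counts and coupling targets default to the
    shape of the emulated study: 41/41 methylation samples, 30/25
    expression samples drawn from the same individuals, 300 genes
    up-regulated in GDM and 165 in controls, 20 driver genes of which 10
    are network hubs.
    """

    n_cases_meth: int = 41
    n_controls_meth: int = 41
    n_cases_expr: int = 30
    n_controls_expr: int = 25
    n_genes: int = 1200
    n_pathways: int = 30
    n_deg_up_case: int = 300
    n_deg_up_control: int = 165
    n_drivers: int = 20
    n_hub_drivers: int = 10
    logfc_range: tuple[float, float] = (0.5, 2.0)
    driver_r_target: float = -0.6
    missing_rate: float = 0.02
    seed: int = 0
    # expression model
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.7
    hub_effect_sd: float = 1.5  # hub-driver case shift, in units of noise_sd
    # promoter CpG count model: geometric on {1..cpg_count_max} with success
    # probability calibrated so P(count < 20 | count >= 1) = cpg_frac_lt20
    cpg_frac_lt20: float = 0.825
    cpg_count_max: int = 30
    frac_gene_no_cpg: float = 0.071
    nonpromoter_frac: float = 0.10
    blacklist_frac: float = 0.05
    # external validation cohort
    n_cases_ext: int = 6
    n_controls_ext: int = 177
    ext_age_shift: float = 3.0
    ext_bmi_shift: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "n_cases_meth",
            "n_controls_meth",
            "n_cases_expr",
            "n_controls_expr",
            "n_genes",
            "n_pathways",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("n_deg_up_case", "n_deg_up_control", "n_drivers",
                     "n_hub_drivers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.n_hub_drivers <= self.n_drivers <= self.n_genes:
            raise ValueError("need n_hub_drivers <= n_drivers <= n_genes")
        if self.n_deg_up_case + self.n_deg_up_control > self.n_genes:
            raise ValueError("more planted DEGs than genes")
        if self.n_cases_expr > self.n_cases_meth:
            raise ValueError("expression cases must be a subset of methylation cases")
        if self.n_controls_expr > self.n_controls_meth:
            raise ValueError(
                "expression controls must be a subset of methylation controls"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not -1 < self.driver_r_target < 0:
            raise ValueError("driver_r_target must be a negative correlation")
        lo, hi = self.logfc_range
        if not 0 < lo <= hi:
            raise ValueError("logfc_range must be a positive interval")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    deg_genes: dict[str, str] = field(default_factory=dict)
    deg_lfc: dict[str, float] = field(default_factory=dict)
    driver_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    hub_genes: list[str] = field(default_factory=list)
    true_edges: set[tuple[str, str]] = field(default_factory=set)
    gene_means: pd.Series | None = None

    @property
    def driver_genes(self) -> list[str]:
        return list(dict.fromkeys(g for g, _, _ in self.driver_pairs))

    def to_json_dict(self) -> dict:
        return {
            "deg_genes": self.deg_genes,
            "deg_lfc": self.deg_lfc,
            "driver_pairs": [list(p) for p in self.driver_pairs],
            "hub_genes": self.hub_genes,
            "true_edges": sorted(list(e) for e in self.true_edges),
            "gene_means": (
                None
                if self.gene_means is None
                else {k: float(v) for k, v in self.gene_means.items()}
            ),
        }


def _geom_u(frac_lt20: float, cmax: int) -> float:
    """Failure probability of the truncated geometric CpG-count model.

    Solves P(X <= 19 | X <= cmax) = frac_lt20 for the geometric failure
    probability u = 1 - p, so the calibration target holds after
    truncation.
    """
    from scipy.optimize import brentq

    f = lambda u: (1 - u**19) - frac_lt20 * (1 - u**cmax)
    return brentq(f, 1e-9, 1 - 1e-9, xtol=1e-12)


def _draw_cpg_counts(rng: np.random.Generator, cfg: SynthConfig,
                     n: int) -> np.ndarray:
    """Truncated-geometric promoter CpG counts, with a zero-count fraction."""
    u = _geom_u(cfg.cpg_frac_lt20, cfg.cpg_count_max)
    j = np.arange(1, cfg.cpg_count_max + 1)
    pmf = u ** (j - 1) * (1 - u)
    pmf /= pmf.sum()
    counts = rng.choice(j, size=n, p=pmf)
    counts[rng.random(n) < cfg.frac_gene_no_cpg] = 0
    return counts


def _sample_ids(cfg: SynthConfig) -> tuple[list[str], list[str]]:
    cases = [f"CASE{i + 1:03d}" for i in range(cfg.n_cases_meth)]
    controls = [f"CTRL{i + 1:03d}" for i in range(cfg.n_controls_meth)]
    return cases, controls


def generate_cohort(
    cfg: SynthConfig,
) -> tuple[MethylationData, ExpressionData, GroundTruth]:
    """Generate the paired cohorts and the ground-truth record.

    Expression is drawn on the log2 scale as gene baseline Normal(8, 1.5)
    plus per-sample Normal(0, 0.7) noise; planted DEGs shift case means by
    a signed log2 fold-change from ``logfc_range`` (hub drivers by a fixed
    ``hub_effect_sd`` times the noise SD). Driver promoter CpGs follow
    ``M = m0 - (expr - baseline) + noise`` with the noise SD solved from the
    target correlation; all other CpG betas come from an equal-weight
    Beta(2, 8) / Beta(8, 2) mixture. Missing beta entries are injected at
    ``missing_rate``, and a small fraction of non-driver probes carry
    sex-chromosome/SNP/cross-hybridisation flags.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_COHORT])
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    cases, controls = _sample_ids(cfg)
    meth_samples = cases + controls
    expr_samples = sorted(
        rng.choice(cases, size=cfg.n_cases_expr, replace=False)
    ) + sorted(rng.choice(controls, size=cfg.n_controls_expr, replace=False))
    is_case = np.array([s in set(cases) for s in meth_samples])

    # --- planted gene sets -------------------------------------------------
    perm = list(rng.permutation(genes))
    hub_genes = perm[: cfg.n_hub_drivers]
    other_drivers = perm[cfg.n_hub_drivers : cfg.n_drivers]
    driver_genes = hub_genes + other_drivers
    rest = perm[cfg.n_drivers :]
    n_hub_deg = min(cfg.n_hub_drivers, cfg.n_deg_up_case)
    up_case = hub_genes[:n_hub_deg] + rest[: cfg.n_deg_up_case - n_hub_deg]
    rest = rest[cfg.n_deg_up_case - n_hub_deg :]
    up_control = rest[: cfg.n_deg_up_control]

    lfc = pd.Series(0.0, index=genes)
    lo, hi = cfg.logfc_range
    lfc[up_case] = rng.uniform(lo, hi, size=len(up_case))
    lfc[hub_genes[:n_hub_deg]] = cfg.hub_effect_sd * cfg.noise_sd
    lfc[up_control] = -rng.uniform(lo, hi, size=len(up_control))

    truth = GroundTruth(
        deg_genes={g: "up_in_GDM" for g in up_case}
        | {g: "up_in_control" for g in up_control},
        deg_lfc={g: float(lfc[g]) for g in (*up_case, *up_control)},
        hub_genes=list(hub_genes),
    )

    # --- expression (latent for every methylation sample) ------------------
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    truth.gene_means = pd.Series(baseline, index=genes)
    expr = (
        baseline[:, None]
        + lfc.to_numpy()[:, None] * is_case[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(meth_samples)))
    )
    expr_frame = pd.DataFrame(expr, index=genes, columns=meth_samples)

    # --- promoter CpG layout ------------------------------------------------
    counts = _draw_cpg_counts(rng, cfg, cfg.n_genes)
    driver_idx = {g: i for i, g in enumerate(genes)}
    for g in driver_genes:
        counts[driver_idx[g]] = max(counts[driver_idx[g]], 1)
    probe_gene, probe_region = [], []
    cpg_of_gene: dict[str, list[str]] = {}
    counter = itertools.count(1)
    for g, c in zip(genes, counts):
        ids = [f"cg{next(counter):08d}" for _ in range(c)]
        cpg_of_gene[g] = ids
        probe_gene += [g] * c
        probe_region += list(rng.choice(PROMOTER_CHOICES, size=c))
    # non-promoter probes to exercise the promoter restriction
    n_nonprom = int(round(cfg.nonpromoter_frac * len(probe_gene)))
    for _ in range(n_nonprom):
        g = genes[int(rng.integers(cfg.n_genes))]
        probe_gene.append(g)
        probe_region.append(str(rng.choice(NONPROMOTER_CHOICES)))
    probe_ids = [f"cg{next(counter):08d}" for _ in range(n_nonprom)]
    probe_ids = [pid for ids in cpg_of_gene.values() for pid in ids] + probe_ids

    n_probes = len(probe_ids)
    probes = pd.DataFrame(
        {
            "gene_symbol": probe_gene,
            "region_class": probe_region,
            "chromosome": [f"chr{(i % 22) + 1}" for i in range(n_probes)],
            "flag_snp": False,
            "flag_crosshyb": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # --- driver coupling ----------------------------------------------------
    pos = {pid: i for i, pid in enumerate(probe_ids)}
    driver_rows: set[str] = set()
    p_case_expr = cfg.n_cases_expr / (cfg.n_cases_expr + cfg.n_controls_expr)
    r = abs(cfg.driver_r_target)
    beta = np.empty((n_probes, len(meth_samples)))
    for g in driver_genes:
        avail = cpg_of_gene[g]
        n_cpg = 1 if len(avail) == 1 else (1 + int(rng.random() < 0.3))
        chosen = list(rng.choice(avail, size=n_cpg, replace=False))
        g_lfc = float(lfc[g])
        sd_x = math.sqrt(
            cfg.noise_sd**2 + g_lfc**2 * p_case_expr * (1 - p_case_expr)
        )
        sd_m = sd_x * math.sqrt(1.0 / r**2 - 1.0)
        centred = expr_frame.loc[g].to_numpy() - baseline[driver_idx[g]]
        for pid in chosen:
            m0 = rng.normal(0.0, 1.0)
            m = m0 - centred + rng.normal(0.0, sd_m, size=len(meth_samples))
            beta[pos[pid]] = 1.0 / (1.0 + 2.0 ** (-m))
            truth.driver_pairs.append((g, pid, -1.0))
            driver_rows.add(pid)

    # --- non-driver betas: bimodal Beta mixture -----------------------------
    nondriver = np.array([pid not in driver_rows for pid in probe_ids])
    n_nd = int(nondriver.sum())
    comp_hi = rng.random(n_nd) < 0.5
    a = np.where(comp_hi, 8.0, 2.0)
    b = np.where(comp_hi, 2.0, 8.0)
    beta[nondriver] = rng.beta(
        a[:, None], b[:, None], size=(n_nd, len(meth_samples))
    )

    # --- blacklist flags on non-driver probes -------------------------------
    nd_ids = np.array(probe_ids)[nondriver]
    n_black = int(round(cfg.blacklist_frac * n_probes))
    n_black = min(n_black, len(nd_ids))
    flagged = rng.choice(nd_ids, size=n_black, replace=False)
    kinds = rng.integers(0, 3, size=n_black)
    for pid, kind in zip(flagged, kinds):
        if kind == 0:
            probes.loc[pid, "chromosome"] = "chrX" if pid[-1] in "02468" else "chrY"
        elif kind == 1:
            probes.loc[pid, "flag_snp"] = True
        else:
            probes.loc[pid, "flag_crosshyb"] = True

    # --- missingness --------------------------------------------------------
    if cfg.missing_rate > 0:
        mask = rng.random(beta.shape) < cfg.missing_rate
        beta = np.where(mask, np.nan, beta)

    # --- sample metadata ----------------------------------------------------
    age = rng.normal(33.3, 4.75, size=len(meth_samples))
    bmi = rng.normal(26.5, 5.6, size=len(meth_samples))
    samples = pd.DataFrame(
        {
            "condition": np.where(is_case, "GDM", "control"),
            "age": np.round(age, 2),
            "bmi": np.round(bmi, 2),
        },
        index=pd.Index(meth_samples, name="sample_id"),
    )

    meth = MethylationData(
        values=pd.DataFrame(beta, index=probe_ids, columns=meth_samples),
        probes=probes,
        samples=samples,
        scale="beta",
    )
    expr_data = ExpressionData(
        values=expr_frame[expr_samples],
        samples=samples.loc[expr_samples],
        level="gene",
    )
    return meth, expr_data, truth


# ---------------------------------------------------------------------------
# Pathway network and KGML emission


def _preferential_attachment(
    rng: np.random.Generator, genes: list[str], hubs: list[str], m: int = 2
) -> set[tuple[str, str]]:
    """Scale-free network seeded on a hub clique.

    Hubs start as a fully connected seed, then remaining genes join in
    random order, each attaching ``m`` edges with probability proportional
    to current degree. Seeding the clique guarantees the hubs end up with
    the highest degrees.
    """
    edges: set[tuple[str, str]] = set()
    edge_order: list[tuple[str, str]] = []

    def add(a: str, b: str) -> None:
        if a == b:
            return
        e = tuple(sorted((a, b)))
        if e not in edges:
            edges.add(e)
            edge_order.append(e)

    seed_nodes = list(hubs) if len(hubs) >= 2 else list(genes[: max(2, m + 1)])
    for i, a in enumerate(seed_nodes):
        for b in seed_nodes[i + 1 :]:
            add(a, b)
    targets: list[str] = []
    for a, b in edge_order:
        targets += [a, b]
    if not targets:
        targets = list(seed_nodes)
    present = set(seed_nodes)
    newcomers = [g for g in genes if g not in present]
    order = list(rng.permutation(newcomers))
    for g in order:
        chosen: list[str] = []
        attempts = 0
        while len(chosen) < min(m, len(present)) and attempts < 50 * m:
            pick = targets[int(rng.integers(len(targets)))]
            if pick not in chosen:
                chosen.append(pick)
            attempts += 1
        for t in chosen:
            add(g, t)
            targets += [g, t]
        present.add(g)
    return edges


def make_id_to_symbol(gene_ids) -> dict[str, str]:
    """KGML alias -> symbol mapping used by all emitted documents."""
    return {f"syn:{g}": g for g in gene_ids}


def _kgml_document(
    name: str,
    edges: list[tuple[str, str]],
    with_features: bool,
) -> str:
    """Serialise one pathway's edges as a KGML document.

    When ``with_features`` is set (and the pathway is large enough), one
    relation is encoded through a multi-alias gene entry and another through
    a two-member group entry, exercising the parser's expansion rules.
    """
    from lxml import etree

    nodes = sorted({n for e in edges for n in e})
    remaining = list(edges)
    alias_feature = group_feature = None
    if with_features:
        nbrs: dict[str, list[str]] = {}
        for a, b in edges:
            nbrs.setdefault(a, []).append(b)
            nbrs.setdefault(b, []).append(a)
        hubs2 = [n for n in nodes if len(nbrs[n]) >= 2]
        used: set[tuple[str, str]] = set()
        for n in hubs2:
            pair = nbrs[n][:2]
            cand = {tuple(sorted((n, pair[0]))), tuple(sorted((n, pair[1])))}
            if cand & used:
                continue
            if alias_feature is None:
                alias_feature = (n, pair)
                used |= cand
            elif group_feature is None:
                group_feature = (n, pair)
                used |= cand
                break
        for feat in (alias_feature, group_feature):
            if feat is not None:
                n, pair = feat
                for b in pair:
                    e = tuple(sorted((n, b)))
                    if e in remaining:
                        remaining.remove(e)

    root = etree.Element(
        "pathway", name=name, org="syn", title=f"synthetic pathway {name}"
    )
    entry_id = {}
    next_id = itertools.count(1)
    for n in nodes:
        eid = str(next(next_id))
        entry_id[n] = eid
        etree.SubElement(
            root, "entry", id=eid, name=f"syn:{n}", type="gene"
        )
    relations = []
    if alias_feature is not None:
        n, (b, c) = alias_feature
        eid = str(next(next_id))
        etree.SubElement(
            root, "entry", id=eid, name=f"syn:{b} syn:{c}", type="gene"
        )
        relations.append((entry_id[n], eid))
    if group_feature is not None:
        n, (b, c) = group_feature
        gid = str(next(next_id))
        group = etree.SubElement(root, "entry", id=gid, type="group")
        etree.SubElement(group, "component", id=entry_id[b])
        etree.SubElement(group, "component", id=entry_id[c])
        relations.append((entry_id[n], gid))
    relations += [(entry_id[a], entry_id[b]) for a, b in remaining]
    for e1, e2 in relations:
        rel = etree.SubElement(root, "relation", entry1=e1, entry2=e2, type="PPrel")
        etree.SubElement(rel, "subtype", name="activation", value="--&gt;")
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def generate_kgml(
    cfg: SynthConfig,
    gene_ids: list[str],
    hub_genes: list[str] | None = None,
    out_dir=None,
) -> tuple[dict[str, str], set[tuple[str, str]]]:
    """Emit ``n_pathways`` KGML documents covering a scale-free network.

    Returns the documents (pathway name -> XML text) and the exact edge set
    the union of the documents encodes. With ``out_dir`` set, each document
    is also written to ``<out_dir>/<name>.xml``.
    """
    if not gene_ids:
        raise ValueError("gene_ids must be nonempty")
    rng = np.random.default_rng([cfg.seed, _STREAM_KGML])
    hubs = list(hub_genes or gene_ids[: cfg.n_hub_drivers])
    edges = _preferential_attachment(rng, list(gene_ids), hubs)
    edge_list = sorted(edges)
    assignment = rng.integers(0, cfg.n_pathways, size=len(edge_list))
    per_pathway: dict[int, list[tuple[str, str]]] = {
        i: [] for i in range(cfg.n_pathways)
    }
    for e, pw in zip(edge_list, assignment):
        per_pathway[pw].append(e)
    for i in range(cfg.n_pathways):
        if not per_pathway[i]:  # every pathway carries at least one edge
            per_pathway[i].append(edge_list[int(rng.integers(len(edge_list)))])
    docs = {}
    for i in range(cfg.n_pathways):
        name = f"path:syn{i + 1:05d}"
        docs[name] = _kgml_document(name, per_pathway[i], with_features=(i == 0))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, xml in docs.items():
            (out_dir / f"{name.replace(':', '_')}.xml").write_text(xml)
    return docs, edges


def pathway_gene_sets(docs: dict[str, str]) -> dict[str, set[str]]:
    """Gene membership of each emitted pathway (for GMT export)."""
    from . import kgml_net

    sets = {}
    for name, xml in docs.items():
        graph = kgml_net.parse_kgml(xml, make_id_to_symbol_from_xml(xml))
        sets[name] = set(graph.nodes)
    return sets


def make_id_to_symbol_from_xml(xml: str) -> dict[str, str]:
    from lxml import etree

    root = etree.fromstring(xml.encode())
    mapping = {}
    for entry in root.findall("entry"):
        for alias in (entry.get("name") or "").split():
            if alias.startswith("syn:"):
                mapping[alias] = alias.split(":", 1)[1]
    return mapping


def generate_external_cohort(
    cfg: SynthConfig, truth: GroundTruth
) -> ExpressionData:
    """External validation cohort reusing the internal gene model.

    Gene baselines and planted fold-changes carry over; cases additionally
    shift the age and BMI covariates (risk factors in the emulated
    population, unlike the matched internal cohort).
    """
    if truth.gene_means is None:
        raise ValueError("ground truth lacks gene baselines")
    rng = np.random.default_rng([cfg.seed, _STREAM_EXTERNAL])
    genes = list(truth.gene_means.index)
    n = cfg.n_cases_ext + cfg.n_controls_ext
    ids = [f"EXT{i + 1:03d}" for i in range(n)]
    is_case = np.array([i < cfg.n_cases_ext for i in range(n)])
    lfc = np.array([truth.deg_lfc.get(g, 0.0) for g in genes])
    values = (
        truth.gene_means.to_numpy()[:, None]
        + lfc[:, None] * is_case[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
    )
    age = rng.normal(30.0, 4.5, size=n) + cfg.ext_age_shift * is_case
    bmi = rng.normal(24.5, 4.0, size=n) + cfg.ext_bmi_shift * is_case
    samples = pd.DataFrame(
        {
            "condition": np.where(is_case, "GDM", "control"),
            "age": np.round(age, 2),
            "bmi": np.round(bmi, 2),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return ExpressionData(
        values=pd.DataFrame(values, index=genes, columns=ids),
        samples=samples,
        level="gene",
    )


def write_study(cfg: SynthConfig, out_dir) -> dict:
    """Generate everything and write the plain-text study bundle.

    Emits the beta matrix, probe annotation, expression matrix, sample
    metadata, KGML files, pathway GMT, id->symbol map, external cohort and
    ground-truth JSON under ``out_dir``; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meth, expr, truth = generate_cohort(cfg)
    docs, edges = generate_kgml(
        cfg, list(expr.values.index), hub_genes=truth.hub_genes,
        out_dir=out / "kgml",
    )
    truth.true_edges = edges
    external = generate_external_cohort(cfg, truth)

    meth.values.to_csv(out / "methylation_beta.tsv", sep="\t")
    meth.probes.to_csv(out / "probe_annotation.tsv", sep="\t")
    expr.values.to_csv(out / "expression.tsv", sep="\t")
    meth.samples.to_csv(out / "sample_metadata.tsv", sep="\t")
    external.values.to_csv(out / "external_expression.tsv", sep="\t")
    external.samples.to_csv(out / "external_metadata.tsv", sep="\t")
    with open(out / "id_to_symbol.tsv", "w") as fh:
        fh.write("kgml_id\tgene_symbol\n")
        for k, v in make_id_to_symbol(expr.values.index).items():
            fh.write(f"{k}\t{v}\n")
    with open(out / "pathways.gmt", "w") as fh:
        for name, xml in docs.items():
            genes = sorted(make_id_to_symbol_from_xml(xml).values())
            fh.write("\t".join([name, "synthetic pathway"] + genes) + "\n")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    return {
        "out_dir": str(out),
        "n_probes": int(meth.values.shape[0]),
        "n_genes": int(expr.values.shape[0]),
        "n_pathways": len(docs),
        "n_true_edges": len(edges),
    }
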