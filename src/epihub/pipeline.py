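"""Configuration-driven orchestration of the full analysis.

``run_all`` executes the whole chain on a synthetic study (or user-supplied
matrices): methylation preprocessing, differential expression, pathway
enrichment, KGML network construction, the negative promoter
methylation/expression screen, gene-gene-CpG centrality and hub selection,
SVM training with ten-fold cross-validation, internal validation, external
prediction with resampling stability, and the baseline-characteristics
table. Every stage's key numbers land in one JSON-serialisable run report;
all randomness flows from named seeds in the config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path


from . import clf, cohort_stats, dea, enrich, epidriver, kgml_net, meth_prep, syndata

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, seeds and input description for one pipeline run."""

    syn: syndata.SynthConfig = field(default_factory=syndata.SynthConfig)
    deg_alpha: float = 0.05
    enrich_alpha: float = 0.05
    corr_alpha: float = 0.05
    hub_k: int = 10
    cv_folds: int = 10
    train_counts: dict = field(
        default_factory=lambda: {"GDM": 15, "control": 12}
    )
    split_seed: int = 101
    cv_seed: int = 202
    stability_seed: int = 303
    stability_reps: int = 1000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("deg_alpha", "enrich_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 <= self.corr_alpha < 1:
            raise ValueError("corr_alpha must be in [0, 1)")


def _stage(report: dict, name: str):
    logger.info("stage %s", name)
    report["stages_completed"].append(name)


def run_all(config: RunConfig) -> dict:
    """Run every stage in order and return the machine-readable report.

    A stage failure aborts the run; the partial report names the failing
    stage. A driver screen that retains nothing ends the run gracefully
    before network construction.
    """
    report: dict = {
        "status": "ok",
        "stages_completed": [],
        "seeds": {
            "syndata": config.syn.seed,
            "split": config.split_seed,
            "cv": config.cv_seed,
            "stability": config.stability_seed,
        },
    }
    t0 = time.time()
    try:
        result = _run_stages(config, report)
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        failed_after = report["stages_completed"][-1] if report["stages_completed"] else None
        report["failed_after_stage"] = failed_after
        raise
    finally:
        report["runtime_s"] = round(time.time() - t0, 2)
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            with open(out / "run_report.json", "w") as fh:
                json.dump(report, fh, indent=1, default=str)
    return result


def _run_stages(config: RunConfig, report: dict) -> dict:
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # --- data ---------------------------------------------------------------
    meth_raw, expr, truth = syndata.generate_cohort(config.syn)
    docs, true_edges = syndata.generate_kgml(
        config.syn, list(expr.values.index), hub_genes=truth.hub_genes
    )
    truth.true_edges = true_edges
    external = syndata.generate_external_cohort(config.syn, truth)
    report["cohort"] = {
        "n_meth_samples": int(meth_raw.values.shape[1]),
        "n_expr_samples": int(expr.values.shape[1]),
        "n_genes": int(expr.values.shape[0]),
        "n_probes_raw": int(meth_raw.values.shape[0]),
    }
    _stage(report, "simulate")

    # --- methylation preprocessing -------------------------------------------
    meth, prep_report = meth_prep.preprocess(meth_raw)
    report["meth_prep"] = {
        k: v for k, v in prep_report.items() if k.startswith("n_")
    } | {
        "n_probes_dropped_missing": prep_report["missingness"]["n_dropped_probes"],
        "n_probes_dropped_blacklist": prep_report["blacklist"]["n_dropped_probes"],
        "n_probes_dropped_nonpromoter": prep_report["promoter"]["n_dropped_probes"],
    }
    _stage(report, "preprocess")

    # --- differential expression ---------------------------------------------
    deg_table = dea.run_dea(expr, alpha=config.deg_alpha)
    deg_genes = list(deg_table.index[deg_table["significant"]])
    report["dea"] = dea.deg_summary(deg_table)
    planted_strong = [g for g, f in truth.deg_lfc.items() if abs(f) >= 1.0]
    if planted_strong:
        detected = sum(g in set(deg_genes) for g in planted_strong)
        report["dea"]["planted_lfc_ge1_detected_frac"] = detected / len(
            planted_strong
        )
    _stage(report, "dea")

    # --- enrichment -----------------------------------------------------------
    gene_sets = enrich.GeneSetCollection(
        [
            enrich.GeneSet(name=name, genes=frozenset(genes), category="pathway")
            for name, genes in syndata.pathway_gene_sets(docs).items()
        ]
    )
    universe = set(expr.values.index)
    enr = enrich.enrich(deg_genes, gene_sets, universe, alpha=config.enrich_alpha)
    report["enrichment"] = {
        "n_sets": int(len(enr)),
        "n_significant": int(enr["significant"].sum()) if len(enr) else 0,
    }
    _stage(report, "enrich")

    # --- pathway network -------------------------------------------------------
    graphs = [
        kgml_net.parse_kgml(xml, syndata.make_id_to_symbol(expr.values.index))
        for xml in docs.values()
    ]
    network = kgml_net.merge_graphs(graphs)
    hist, slope = kgml_net.degree_distribution(network)
    # promoter CpG count profile over network genes
    per_gene = meth.probes.groupby("gene_symbol").size()
    with_cpg = per_gene[per_gene >= 1]
    report["network"] = {
        "n_genes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "degree_loglog_slope": slope,
        "frac_genes_with_promoter_cpg": float(
            len(with_cpg) / max(network.number_of_nodes(), 1)
        ),
        "frac_cpg_genes_below_20": float((with_cpg < 20).mean()),
    }
    _stage(report, "network")

    # --- driver screen ----------------------------------------------------------
    drivers = epidriver.screen_negative(
        expr, meth, list(network.nodes), alpha=config.corr_alpha
    )
    report["drivers"] = {
        "n_pairs": int(len(drivers)),
        "n_driver_genes": int(drivers["gene"].nunique()) if len(drivers) else 0,
        "n_cpgs": int(drivers["cpg"].nunique()) if len(drivers) else 0,
    }
    if truth.driver_pairs:
        found = {(g, c) for g, c in zip(drivers.get("gene", []), drivers.get("cpg", []))}
        retained = sum((g, c) in found for g, c, _ in truth.driver_pairs)
        report["drivers"]["planted_pairs_retained_frac"] = retained / len(
            truth.driver_pairs
        )
    _stage(report, "drivers")
    if drivers.empty:
        report["status"] = "halted"
        report["halt_reason"] = (
            "driver screen retained no gene-CpG pair; "
            "network construction and classification skipped"
        )
        return report

    # --- gene-gene-CpG network and hubs ------------------------------------------
    mixed = epidriver.build_network(network, drivers)
    cent = epidriver.centralities(mixed)
    hubs = epidriver.select_hubs(cent, k=config.hub_k)
    report["hubs"] = {
        "selected": hubs,
        "n_gene_nodes": int((cent.shape[0])),
        "planted_recovered": sorted(set(hubs) & set(truth.hub_genes)),
        "n_planted_recovered": len(set(hubs) & set(truth.hub_genes)),
    }
    _stage(report, "hubs")
    if not hubs:
        report["status"] = "halted"
        report["halt_reason"] = "hub intersection empty; classification skipped"
        return report

    # --- classifier ----------------------------------------------------------------
    split = clf.split_samples(expr.samples, config.train_counts, config.split_seed)
    model = clf.train_svm(
        expr, hubs, sample_ids=split.train, folds=config.cv_folds,
        seed=config.cv_seed,
    )
    eval_train = clf.evaluate(model, expr, split.train)
    eval_valid = clf.evaluate(model, expr, split.validation)
    eval_all = clf.evaluate(model, expr)
    report["classifier"] = {
        "n_train": len(split.train),
        "n_validation": len(split.validation),
        "C": model.C,
        "cv_accuracy": model.cv_accuracy,
        "train": eval_train.to_dict(),
        "validation": eval_valid.to_dict(),
        "all_samples": eval_all.to_dict(),
    }
    _stage(report, "train")

    # --- external validation ----------------------------------------------------------
    eval_ext = clf.evaluate(model, external)
    normals = external.subset_samples(
        external.samples.index[external.samples["condition"] == "control"]
    )
    hist_stab = clf.stability_resample(
        model, normals, frac=0.5, reps=config.stability_reps,
        seed=config.stability_seed,
    )
    modal = max(hist_stab, key=lambda k: hist_stab[k])
    predictions = model.predict(external)
    covar = clf.compare_covariates(
        predictions, external.samples[["age", "bmi"]]
    )
    report["external"] = {
        "n_samples": int(external.values.shape[1]),
        "evaluation": eval_ext.to_dict(),
        "stability_histogram": {str(k): v for k, v in hist_stab.items()},
        "stability_modal_misclassified": int(modal),
        "covariates": covar.to_dict(orient="records"),
    }
    _stage(report, "external")

    # --- table 1 -----------------------------------------------------------------------
    table1 = cohort_stats.build_table1(
        meth_raw.samples, continuous=["age", "bmi"], categorical=[]
    )
    report["table1"] = table1.to_dict(orient="records")
    _stage(report, "table1")

    if out:
        deg_table.to_csv(out / "deg_table.tsv", sep="\t")
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        drivers.to_csv(out / "driver_table.tsv", sep="\t", index=False)
        cent.to_csv(out / "centralities.tsv", sep="\t")
        kgml_net.write_sif(network, out / "pathway_network.sif")
        kgml_net.write_graphml(mixed, out / "gene_gene_cpg.graphml")
        clf.save_model_json(model, out / "svm_model.json")
        eval_valid.roc.to_csv(out / "roc_validation.tsv", sep="\t", index=False)
    return report
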