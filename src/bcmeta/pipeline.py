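"""End-to-end orchestration of the meta-analysis stages on one input bundle.

Stages run in dependency order: harmonization → differential expression →
PPI hubs → consensus co-expression → key hubs → biofluid screens →
prognostic / predictive signatures → diagnostic panel.  Every report is a
plain TSV/JSON file under the output directory, and a structured log records
the seed and every effective threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression as cx
from . import de as de_mod
from . import fluids as fl
from . import hubs as hb
from . import io as io_mod
from . import panel as pn
from . import survival as sv
from . import synthetic as syn
from .config import PipelineConfig
from .harmonize import merge_studies, qc_outlier_flags, zscore_transform

log = logging.getLogger("bcmeta")

ALL_STAGES = (
    "harmonize",
    "de",
    "hubs",
    "wgcna",
    "fluids",
    "prognostic",
    "predictive",
    "panel",
)


@dataclass
class PipelineReport:
    out_dir: Path
    artifacts: dict = field(default_factory=dict)

    def path(self, name: str) -> Path:
        return self.out_dir / name


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    sim: syn.SimConfig | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
    gene_list: list[str] | None = None,
) -> PipelineReport:
    """Run the enabled stages on a synthetic bundle generated from ``sim``.

    ``gene_list`` overrides the hub list for the survival stages (used when
    the network stages are disabled).  Raises if an enabled stage lacks its
    upstream artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if sim is None:
        sim = syn.SimConfig(seed=config.seed)
    log.info("pipeline config: %s", json.dumps(config.to_dict(), default=str))
    report = PipelineReport(out)

    studies, truth = syn.simulate_study_collection(sim)
    report.artifacts["truth"] = truth

    merged = None
    if "harmonize" in stages:
        kept = []
        for st in studies:
            qc = qc_outlier_flags(st)
            keep = [s for s in st.samples if not bool(qc.outliers.get(s, False))]
            if len(keep) < len(st.samples):
                log.info(
                    "%s: removed %d QC outliers",
                    st.study_id,
                    len(st.samples) - len(keep),
                )
                st = st.subset_samples(keep)
            kept.append(zscore_transform(st))
        merged = merge_studies(kept)
        io_mod.write_expression(merged.values, out / "merged_matrix.tsv")
        io_mod.write_phenotype(
            merged.samples.rename(columns={"study_id": "study",
                                           "phenotype": "group"}),
            out / "merged_phenotype.tsv",
        )
        report.artifacts["merged"] = merged

    de_res = scan = None
    if "de" in stages:
        if merged is None:
            raise ValueError("stage 'de' requires the harmonize stage")
        de_res = de_mod.differential_expression(merged)
        scan = de_mod.select_deg_threshold(
            de_res, merged, p_cut=config.de_p_adj_max,
            grid=config.fc_grid, seed=config.seed,
        )
        de_res.table.to_csv(out / "de_table.tsv", sep="\t")
        scan.table.to_csv(out / "threshold_scan.tsv", sep="\t")
        io_mod.write_gene_list(scan.selected_genes, out / "deg_list.txt")
        report.artifacts["de"] = de_res
        report.artifacts["scan"] = scan

    ppi_hubs = None
    if "hubs" in stages:
        degs = scan.selected_genes if scan is not None else None
        graph, gtruth = syn.simulate_ppi_graph(sim, node_names=degs)
        io_mod.write_edge_list(graph, out / "ppi_edges.tsv")
        ranking = hb.compute_centralities(graph, seed=config.seed)
        rra = hb.rra_aggregate(list(ranking.rankings.values()), sorted(graph))
        rra_hubs = ranking.hub_list(rra, p_max=config.rra_p_max)
        mcode = hb.mcode_cluster(
            graph,
            degree_cutoff=config.mcode_degree_cutoff,
            node_score_cutoff=config.mcode_node_score_cutoff,
            k_core=config.mcode_k_core,
            haircut=config.mcode_haircut,
            max_depth=config.mcode_max_depth,
            score_min=config.mcode_score_min,
        )
        cluster_genes = mcode.member_genes()
        ppi_hubs = hb.hub_intersection(rra_hubs, cluster_genes)
        io_mod.write_gene_list(rra_hubs, out / "rra_hubs.txt")
        io_mod.write_gene_list(cluster_genes, out / "mcode_genes.txt")
        io_mod.write_gene_list(ppi_hubs, out / "ppi_hubs.txt")
        rra.to_csv(out / "rra_scores.tsv", sep="\t")
        report.artifacts["graph"] = graph
        report.artifacts["graph_truth"] = gtruth
        report.artifacts["mcode"] = mcode
        report.artifacts["ppi_hubs"] = ppi_hubs

    key_hubs_flat = None
    if "wgcna" in stages:
        if merged is None:
            raise ValueError("stage 'wgcna' requires the harmonize stage")
        datasets, traits, ids = [], [], []
        for sid, sub in merged.samples.groupby("study_id", sort=False):
            if sid in config.wgcna_exclude_datasets:
                continue
            cols = list(sub.index)
            if len(cols) <= config.wgcna_min_samples:
                continue
            datasets.append(merged.values[cols])
            traits.append((sub["phenotype"] == "case").to_numpy().astype(float))
            ids.append(sid)
        if not datasets:
            raise ValueError("no dataset exceeds the sample-size rule for wgcna")
        partition = cx.detect_consensus_modules(
            datasets,
            power=config.wgcna_power,
            min_size=config.wgcna_min_module_size,
            merge_height=config.wgcna_merge_height,
        )
        trait_tab = cx.module_trait_table(partition, traits)
        stats = cx.gene_trait_meta_z(datasets, traits, partition)
        module_hubs = cx.select_module_hubs(stats)
        key_modules = list(
            trait_tab.index[trait_tab["consensus_p"] < config.module_trait_p_max]
        )
        key = cx.key_hub_genes(ppi_hubs or [], module_hubs, key_modules)
        key_hubs_flat = sorted({g for gs in key.values() for g in gs})
        trait_tab.to_csv(out / "module_trait.tsv", sep="\t")
        stats.table.to_csv(out / "module_gene_stats.tsv", sep="\t")
        with (out / "key_hubs.json").open("w") as fh:
            json.dump(key, fh, indent=2)
        report.artifacts["partition"] = partition
        report.artifacts["module_trait"] = trait_tab
        report.artifacts["key_hubs"] = key

    screen_genes = gene_list or key_hubs_flat or (ppi_hubs or None)

    if "fluids" in stages:
        (resp_expr, resp_labels), fluid_cohorts, ftruth = (
            syn.simulate_phenotype_cohorts(sim)
        )
        rows = []
        for name, (case, ctrl) in fluid_cohorts.items():
            genes = [g for g in (screen_genes or case.columns) if g in case.columns]
            rows.extend(
                fl.wilcoxon_screen(case, ctrl, genes=genes,
                                   alpha=config.fluid_alpha, cohort_id=name)
            )
        fl.screen_table(rows).to_csv(out / "fluid_screens.tsv", sep="\t",
                                     index=False)
        report.artifacts["fluid_screens"] = rows
        report.artifacts["response_data"] = (resp_expr, resp_labels)
        report.artifacts["fluid_truth"] = ftruth

    cohort = None
    if "prognostic" in stages or "predictive" in stages:
        cohort, struth = syn.simulate_survival_cohort(sim)
        report.artifacts["survival_truth"] = struth

    if "prognostic" in stages:
        genes = [
            g
            for g in (screen_genes or list(cohort.expression.columns))
            if g in cohort.expression.columns
        ]
        if not genes:
            # hub genes may be disjoint from the survival panel on synthetic
            # bundles; fall back to the cohort's own gene universe
            log.info("prognostic: hub list disjoint from cohort genes; "
                     "using all cohort genes")
            genes = list(cohort.expression.columns)
        uni_rows = {}
        for g in genes:
            try:
                uni_rows[g] = sv.cox_univariate(cohort, g).table.iloc[0]
            except ValueError:
                continue
        uni = pd.DataFrame(uni_rows).T
        sig = list(uni.index[uni["p"] < config.cox_p_max])
        selected, freq = sv.lasso_cox_select(
            cohort, sig or genes,
            folds=config.lasso_folds, iters=config.lasso_iters,
            freq_min=config.lasso_freq_min, seed=config.seed,
        )
        if not selected:
            selected = list(freq.sort_values(ascending=False).index[:3])
        fit, model = sv.cox_multivariate(cohort, selected)
        scores = sv.risk_index(model, cohort.expression)
        split = sv.median_split_km_logrank(scores, cohort)
        horizons = tuple(
            h for h in config.roc_horizons if h <= cohort.time.max()
        )
        roc = sv.time_dependent_roc(scores, cohort, horizons or (1.0,))
        uni.to_csv(out / "cox_univariate.tsv", sep="\t")
        (out / "prognostic_model.json").write_text(model.to_json())
        summary = {
            "selected_genes": selected,
            "logrank_p": split.p,
            "hr_high_vs_low": split.hr,
            "cindex": sv.harrell_cindex(scores, cohort),
            "roc_auc": roc.auc,
        }
        (out / "prognostic_summary.json").write_text(
            json.dumps(summary, indent=2)
        )
        report.artifacts["prognostic"] = (fit, model, split, roc)

    if "predictive" in stages:
        if "fluids" not in stages:
            raise ValueError("stage 'predictive' requires the fluids stage "
                             "(response cohort)")
        resp_expr, resp_labels = report.artifacts["response_data"]
        genes = [
            g
            for g in (screen_genes or list(resp_expr.columns))
            if g in resp_expr.columns
        ]
        tests = fl.response_group_tests(resp_expr, resp_labels, genes=genes,
                                        alpha=config.fluid_alpha)
        fl.screen_table(tests).to_csv(out / "response_tests.tsv", sep="\t",
                                      index=False)
        pred_genes = (
            [g for g in genes if g in cohort.expression.columns]
            or list(cohort.expression.columns)
        )[:3]
        if pred_genes:
            fit, model = sv.cox_multivariate(cohort, pred_genes,
                                             absolute_value=True)
            (out / "predictive_model.json").write_text(model.to_json())
            report.artifacts["predictive"] = (fit, model)
        report.artifacts["response_tests"] = tests

    if "panel" in stages:
        if merged is None:
            raise ValueError("stage 'panel' requires the harmonize stage")
        panel_genes = (screen_genes or merged.genes)[:9]
        panel_genes = [g for g in panel_genes if g in set(merged.genes)]
        if not panel_genes:
            raise ValueError("no panel genes present in the merged matrix")
        labels = merged.samples["phenotype"]
        rows = []
        for sid, sub in merged.samples.groupby("study_id", sort=False):
            cols = list(sub.index)
            counts = (sub["phenotype"] == "case").value_counts()
            if len(cols) <= 10 or counts.min() < config.panel_folds:
                continue
            rows.append(
                pn.evaluate_panel(
                    merged.values[cols], labels.loc[cols], panel_genes,
                    folds=config.panel_folds, repeats=config.panel_repeats,
                    dataset_id=str(sid), seed=config.seed,
                ).as_row()
            )
        rows.append(
            pn.evaluate_panel(
                merged.values, labels, panel_genes,
                folds=config.merged_panel_folds, repeats=1,
                dataset_id="merged", seed=config.seed,
            ).as_row()
        )
        pd.DataFrame(rows).to_csv(out / "panel_evaluation.tsv", sep="\t",
                                  index=False)
        report.artifacts["panel"] = rows

    (out / "run_log.json").write_text(
        json.dumps(
            {
                "seed": config.seed,
                "stages": list(stages),
                "config": config.to_dict(),
                "sim": str(sim),
            },
            indent=2,
            default=str,
        )
    )
    return report
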