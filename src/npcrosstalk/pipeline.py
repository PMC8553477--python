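"""End-to-end orchestration: synthetic demo generation, stage execution,
structured logging of filter in/out counts, and a results manifest.

The stage order follows the study design: merge datasets per disease →
batch-correct → differential expression (per-disease threshold presets) →
crosstalk intersection → pathway enrichment → correlation screen and DRL →
PPI direct/bridge extraction with topology → tripartite pathway network →
lasso screen, selection intersection, ROC and boxplot statistics.  All
stage outputs are plain-text tables under the output directory; identical
config + seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .bundle import ExpressionBundle, GROUP_CASE
from .diffexpr import DEGThresholds, classify_degs, fit_moderated_ttest, select_degs, volcano_table
from .drl import drl_table, join_disease_tables
from .enrich import hypergeometric_enrichment, intersect_degs
from .networks import assign_roles, bridge_pairs, direct_pairs, shared_pathway_network, topology_metrics
from .preprocess import batch_variance_fraction, combat_adjust, merge_datasets, pca_scores
from .screen import boxplot_table, intersect_selected, lasso_screen, roc_table
from .synthetic import SyntheticConfig, SyntheticStudy, generate_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class LassoSettings:
    folds: int = 10
    n_lambda: int = 50
    lambda_choice: str = "min"
    model: str = "logistic"
    cv_loss: str = "deviance"


@dataclass
class PipelineConfig:
    """Single-document pipeline configuration (YAML-serializable).

    ``datasets`` maps disease → list of (expression TSV, metadata TSV)
    pairs; each pair is one source dataset (batch).
    """

    seed: int = 0
    output_dir: str = "results"
    datasets: dict[str, list[list[str]]] = field(default_factory=dict)
    neuropeptides: str = ""
    pathways: str = ""
    ppi: str = ""
    thresholds: dict[str, dict] = field(
        default_factory=lambda: {
            "MDD": {"p_cut": 0.05, "lfc_cut": 0.0, "lfc_inclusive": False},
            "PD": {"p_cut": 0.05, "lfc_cut": 0.5, "lfc_inclusive": True},
        }
    )
    cc_cut: float = 0.5
    screen_on: str = "case"
    lasso: LassoSettings = field(default_factory=LassoSettings)
    topology_top: int = 20
    make_plots: bool = True

    def threshold_for(self, disease: str) -> DEGThresholds:
        spec = self.thresholds.get(disease, {"p_cut": 0.05, "lfc_cut": 0.0, "lfc_inclusive": False})
        return DEGThresholds(**spec)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        lasso = LassoSettings(**raw.pop("lasso", {}))
        return cls(lasso=lasso, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


# ---------------------------------------------------------------------------
# demo generation


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write all synthetic inputs as the plain-text formats the pipeline
    reads: per-batch expression/metadata TSVs, neuropeptide list, GMT,
    PPI edge list, and the truth ledger JSON.  Returns the dataset map for a
    PipelineConfig."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets: dict[str, list[list[str]]] = {}
    for disease, bundle in study.bundles.items():
        pairs = []
        for batch in sorted(bundle.metadata["batch"].unique()):
            samples = bundle.metadata.index[bundle.metadata["batch"] == batch]
            sub = bundle.subset_samples(samples)
            expr_path = outdir / f"expression_{disease}_{batch}.tsv"
            meta_path = outdir / f"metadata_{disease}_{batch}.tsv"
            io.write_expression_tsv(sub, expr_path)
            io.write_metadata_tsv(sub, meta_path)
            pairs.append([str(expr_path), str(meta_path)])
        datasets[disease] = pairs
    io.write_gene_list(study.panel.genes, outdir / "neuropeptides.txt")
    io.write_gmt(study.pathways, outdir / "pathways.gmt")
    io.write_edge_list(study.graph, outdir / "ppi_edges.tsv")
    io.write_json(study.ledger.to_dict(), outdir / "truth_ledger.json")
    return datasets


def make_demo(outdir, seed: int = 0, synthetic_config: SyntheticConfig | None = None) -> Path:
    """Write a ready-to-run synthetic study sized like the original cohorts
    (two diseases, 102 panel genes, 35 planted crosstalk genes, 4 shared
    predictive neuropeptides) plus a pipeline config.  Returns the config
    path."""
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    config = synthetic_config or SyntheticConfig(seed=seed)
    study = generate_study(config)
    datasets = write_study(study, inputs)
    pipe = PipelineConfig(
        seed=seed,
        output_dir=str(outdir / "results"),
        datasets=datasets,
        neuropeptides=str(inputs / "neuropeptides.txt"),
        pathways=str(inputs / "pathways.gmt"),
        ppi=str(inputs / "ppi_edges.tsv"),
    )
    config_path = outdir / "config.yaml"
    pipe.to_yaml(config_path)
    return config_path


# ---------------------------------------------------------------------------
# pipeline


def _register(manifest: dict, name: str, path: Path, rows: int) -> None:
    manifest["files"][name] = {"path": str(path), "rows": int(rows)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the results manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "cc_cut": config.cc_cut,
            "screen_on": config.screen_on,
            "thresholds": config.thresholds,
            "lasso": dataclasses.asdict(config.lasso),
        },
        "files": {},
        "counts": {},
    }

    neuropeptides = io.read_gene_list(config.neuropeptides)
    manifest["counts"]["neuropeptide_panel"] = len(neuropeptides)

    corrected: dict[str, ExpressionBundle] = {}
    deg_tables: dict[str, pd.DataFrame] = {}
    deg_sets: dict[str, dict[str, str]] = {}

    for disease in sorted(config.datasets):
        stage = f"preprocess[{disease}]"
        try:
            bundles = [
                io.read_expression_bundle(expr, meta, disease)
                for expr, meta in config.datasets[disease]
            ]
            merged = merge_datasets(bundles)
            scores_before, _ = pca_scores(merged, k=2)
            before = batch_variance_fraction(scores_before["PC1"], merged.metadata["batch"])
            adjusted = merged if merged.metadata["batch"].nunique() < 2 else combat_adjust(merged)
            scores_after, _ = pca_scores(adjusted, k=2)
            after = batch_variance_fraction(scores_after["PC1"], adjusted.metadata["batch"])
            logger.info(
                "%s: PC1 batch variance fraction %.3f -> %.3f", disease, before, after
            )
            corrected[disease] = adjusted
            manifest["counts"][f"{disease}_samples"] = adjusted.n_samples
            manifest["counts"][f"{disease}_case"] = int(adjusted.group_mask(GROUP_CASE).sum())
            manifest["counts"][f"{disease}_control"] = adjusted.n_samples - int(
                adjusted.group_mask(GROUP_CASE).sum()
            )
            manifest["counts"][f"{disease}_pc1_batch_fraction_before"] = before
            manifest["counts"][f"{disease}_pc1_batch_fraction_after"] = after

            path = out / f"corrected_{disease}.tsv"
            io.write_expression_tsv(adjusted, path)
            _register(manifest, f"corrected_{disease}", path, adjusted.n_genes)
            for tag, scores in (("before", scores_before), ("after", scores_after)):
                spath = out / f"pca_{tag}_{disease}.tsv"
                scores.to_csv(spath, sep="\t", index_label="sample_id")
                _register(manifest, f"pca_{tag}_{disease}", spath, len(scores))
            if config.make_plots:
                _plot_pca(scores_before, scores_after, adjusted.metadata, out / f"pca_{disease}.png")
        except Exception as err:
            raise PipelineError(stage, err) from err

        stage = f"diffexpr[{disease}]"
        try:
            table = fit_moderated_ttest(corrected[disease])
            thr = config.threshold_for(disease)
            table["direction"] = classify_degs(table, thr)
            up, down = select_degs(table, thr)
            deg_tables[disease] = table
            deg_sets[disease] = {g: "up" for g in up} | {g: "down" for g in down}
            manifest["counts"][f"{disease}_deg_up"] = len(up)
            manifest["counts"][f"{disease}_deg_down"] = len(down)
            manifest["counts"][f"{disease}_deg_total"] = len(up) + len(down)
            logger.info("%s: %d up, %d down DEGs", disease, len(up), len(down))
            path = out / f"deg_{disease}.tsv"
            table.to_csv(path, sep="\t", index_label="gene")
            _register(manifest, f"deg_{disease}", path, len(table))
            vpath = out / f"volcano_{disease}.tsv"
            volcano = volcano_table(table, thr)
            volcano.to_csv(vpath, sep="\t", index_label="gene")
            _register(manifest, f"volcano_{disease}", vpath, len(volcano))
            if config.make_plots:
                _plot_volcano(volcano, out / f"volcano_{disease}.png")
        except Exception as err:
            raise PipelineError(stage, err) from err

    diseases = sorted(corrected)
    if len(diseases) != 2:
        raise PipelineError("crosstalk", ValueError("pipeline expects exactly two diseases"))
    d_a, d_b = diseases

    try:
        crosstalk_table = intersect_degs(
            deg_sets[d_a], deg_sets[d_b], exclude=set(neuropeptides)
        )
        crosstalk = list(crosstalk_table.index)
        manifest["counts"]["crosstalk_genes"] = len(crosstalk)
        logger.info("crosstalk intersection: %d genes", len(crosstalk))
        path = out / "crosstalk.tsv"
        crosstalk_table.rename(
            columns={"direction_a": f"direction_{d_a}", "direction_b": f"direction_{d_b}"}
        ).to_csv(path, sep="\t", index_label="gene")
        _register(manifest, "crosstalk", path, len(crosstalk_table))
    except Exception as err:
        raise PipelineError("crosstalk", err) from err

    try:
        pathways = io.read_gmt(config.pathways)
        universe = set(corrected[d_a].genes) & set(corrected[d_b].genes)
        enrichment = hypergeometric_enrichment(set(crosstalk), pathways, universe)
        manifest["counts"]["enriched_sets"] = int(enrichment["significant"].sum())
        path = out / "enrichment.tsv"
        enrichment.to_csv(path, sep="\t")
        _register(manifest, "enrichment", path, len(enrichment))
    except Exception as err:
        raise PipelineError("enrichment", err) from err

    try:
        drl_tables = {}
        for disease in diseases:
            table = drl_table(
                corrected[disease], crosstalk, neuropeptides,
                cc_cut=config.cc_cut, screen_on=config.screen_on,
            )
            drl_tables[disease] = table
            manifest["counts"][f"{disease}_screened_pairs"] = len(table)
            path = out / f"drl_{disease}.tsv"
            table.to_csv(path, sep="\t", index=False)
            _register(manifest, f"drl_{disease}", path, len(table))
            sif = out / f"drl_{disease}.sif"
            io.write_sif(
                [(r.crosstalk, r.neuropeptide, f"{r.drl:.4f}") for r in table.itertuples()],
                sif, relation="drl",
            )
            _register(manifest, f"drl_sif_{disease}", sif, len(table))
        joined = join_disease_tables(drl_tables[d_a], drl_tables[d_b])
        manifest["counts"]["drl_pairs_both_diseases"] = len(joined)
        path = out / "drl_joined.tsv"
        joined.to_csv(path, sep="\t", index=False)
        _register(manifest, "drl_joined", path, len(joined))
    except Exception as err:
        raise PipelineError("drl", err) from err

    try:
        graph = io.read_edge_list(config.ppi)
        roles = assign_roles(graph, crosstalk, neuropeptides)
        direct = direct_pairs(graph, crosstalk, neuropeptides)
        triples, subnet = bridge_pairs(graph, crosstalk, neuropeptides)
        manifest["counts"]["ppi_direct_pairs"] = len(direct)
        manifest["counts"]["ppi_bridge_triples"] = len(triples)
        dpath = out / "ppi_direct_pairs.tsv"
        dpath.write_text("".join(f"{c}\t{n}\n" for c, n in direct))
        _register(manifest, "ppi_direct_pairs", dpath, len(direct))
        bpath = out / "ppi_bridge_triples.tsv"
        bpath.write_text("".join(f"{c}\t{b}\t{n}\n" for c, b, n in triples))
        _register(manifest, "ppi_bridge_triples", bpath, len(triples))
        spath = out / "ppi_bridge_subnetwork.sif"
        io.write_sif(sorted(tuple(sorted(e)) for e in subnet.edges()), spath)
        _register(manifest, "ppi_bridge_subnetwork", spath, subnet.number_of_edges())
        if subnet.number_of_nodes():
            topo = topology_metrics(subnet, roles, top=config.topology_top)
        else:
            topo = topology_metrics(graph, roles, top=config.topology_top)
        tpath = out / "topology.tsv"
        topo.to_csv(tpath, sep="\t", index=False)
        _register(manifest, "topology", tpath, len(topo))
    except Exception as err:
        raise PipelineError("networks", err) from err

    try:
        tri = shared_pathway_network(crosstalk, neuropeptides, pathways)
        pathway_nodes = {t for s, e, t in tri if e == "crosstalk-pathway"}
        manifest["counts"]["tripartite_pathways"] = len(pathway_nodes)
        path = out / "tripartite.sif"
        io.write_sif(tri, path, relation="shared")
        _register(manifest, "tripartite", path, len(tri))
    except Exception as err:
        raise PipelineError("tripartite", err) from err

    try:
        selections = {}
        for disease in diseases:
            panel_genes = [g for g in neuropeptides if g in corrected[disease].matrix.index]
            panel_bundle = corrected[disease].subset_genes(panel_genes)
            result = lasso_screen(
                panel_bundle,
                folds=config.lasso.folds,
                seed=config.seed,
                n_lambda=config.lasso.n_lambda,
                model=config.lasso.model,
                cv_loss=config.lasso.cv_loss,
                lambda_choice=config.lasso.lambda_choice,
            )
            selections[disease] = result.selected
            manifest["counts"][f"{disease}_lasso_selected"] = len(result.selected)
            path = out / f"lasso_{disease}.tsv"
            pd.DataFrame(
                {
                    "lambda": result.lambdas,
                    "cv_mean": result.cv_mean,
                    "cv_se": result.cv_se,
                }
            ).to_csv(path, sep="\t", index=False)
            _register(manifest, f"lasso_cv_{disease}", path, len(result.lambdas))
            gpath = out / f"lasso_selected_{disease}.txt"
            io.write_gene_list(result.selected, gpath)
            _register(manifest, f"lasso_selected_{disease}", gpath, len(result.selected))
        shared_np = intersect_selected(selections[d_a], selections[d_b])
        manifest["counts"]["lasso_intersection"] = len(shared_np)
        logger.info("lasso: %s selected in both diseases", shared_np)
        path = out / "lasso_intersection.txt"
        io.write_gene_list(shared_np, path)
        _register(manifest, "lasso_intersection", path, len(shared_np))
    except Exception as err:
        raise PipelineError("lasso", err) from err

    try:
        roc_rows, box_rows = [], []
        linked_crosstalk: set[str] = set()
        for disease in diseases:
            if shared_np:
                roc_rows.append(roc_table(corrected[disease], shared_np))
                box_rows.append(boxplot_table(corrected[disease], shared_np))
            table = drl_tables[disease]
            linked_crosstalk |= set(
                table.loc[table["neuropeptide"].isin(shared_np), "crosstalk"]
            )
        roc = pd.concat(roc_rows, ignore_index=True) if roc_rows else pd.DataFrame(
            columns=["gene", "disease", "auc"]
        )
        path = out / "roc_auc.tsv"
        roc.to_csv(path, sep="\t", index=False)
        _register(manifest, "roc_auc", path, len(roc))

        manifest["counts"]["crosstalk_linked_to_selected_np"] = len(linked_crosstalk)
        box_targets = sorted(linked_crosstalk)
        box_all = []
        for disease in diseases:
            genes = [g for g in box_targets if g in corrected[disease].matrix.index]
            if genes:
                box_all.append(boxplot_table(corrected[disease], genes))
        box = pd.concat(box_rows + box_all, ignore_index=True) if (box_rows or box_all) else (
            pd.DataFrame(
                columns=[
                    "gene", "disease", "case_median", "case_q1", "case_q3",
                    "control_median", "control_q1", "control_q3", "p", "stars",
                ]
            )
        )
        path = out / "boxplot_stats.tsv"
        box.to_csv(path, sep="\t", index=False)
        _register(manifest, "boxplot_stats", path, len(box))
    except Exception as err:
        raise PipelineError("roc_boxplot", err) from err

    manifest_path = out / "manifest.json"
    io.write_json(manifest, manifest_path)
    logger.info("pipeline complete: %d output files", len(manifest["files"]))
    return manifest


# ---------------------------------------------------------------------------
# basic plots (exports are tables first; these are convenience figures)


def _plot_pca(before: pd.DataFrame, after: pd.DataFrame, metadata: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, scores, title in ((axes[0], before, "before"), (axes[1], after, "after")):
        for batch, samples in metadata.groupby("batch").groups.items():
            sub = scores.loc[samples]
            ax.scatter(sub["PC1"], sub["PC2"], s=8, label=str(batch))
        ax.set_title(f"PCA {title} correction")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_volcano(volcano: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"up": "tab:red", "down": "tab:blue", "ns": "lightgray"}
    for cls, sub in volcano.groupby("class"):
        ax.scatter(sub["log2FC"], sub["neg_log10_p"], s=4, c=colors.get(cls, "k"), label=cls)
    ax.set_xlabel("log2FC")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
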