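"""End-to-end pipeline: counts + titers -> DE, pathways, predictor, graph.

Stage order mirrors the analysis design: normalize -> feature filter ->
responder classification -> differential expression (three contrasts)
-> per-sample pathway scores -> differential pathways -> nested-CV
LASSO on week-2 transcriptomes -> ROC / confusion / odds-titer
correlation -> MGM + FCI-MAX on the selected genes + covariates +
log week-12 IgG -> direct neighbors with edge stability.  Every run
writes a manifest with the seed and a config hash.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .data import ExpressionMatrix, GeneSetCollection
from .diffexpr import de_contrast
from .enrichment import differential_pathways, gsva_scores
from .fci import direct_neighbors, fci_max_orient, neighborhood
from .mgm import MgmParams, MixedDataset
from .prediction import lasso_logistic_cv, odds_titer_correlation, roc_auc
from .preprocess import classify_response, filter_features, normalize
from .simulate import OUTCOME_NODE
from .stability import edge_stability

log = logging.getLogger("vaxresp")


@dataclass
class PipelineConfig:
    expression_path: str = ""
    metadata_path: str = ""
    gmt_path: str = ""
    annotation_path: str = ""
    output_dir: str = "vaxresp_out"
    variance_top_k: int = 8000
    pseudocount: float = 0.5
    trend: bool = True
    p_threshold: float = 0.05
    hr_threshold: float = 0.4
    fold_threshold: float = 2.0
    k_folds: int = 5
    inner_folds: int = 5
    n_lambdas: int = 50
    prob_threshold: float = 0.5
    mgm: MgmParams = field(default_factory=MgmParams)
    alpha: float = 0.05
    max_cond_size: int = 3
    n_subsamples: int = 100
    subsample_frac: float = 0.9
    max_graph_genes: int = 20
    contrasts: tuple[str, ...] = ("baseline_RvsNR", "week2_RvsNR", "delta_RvsNR")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mgm = MgmParams(**raw.pop("mgm", {}))
        cfg = cls(**raw)
        cfg.mgm = mgm
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contrasts"] = list(self.contrasts)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    expression: ExpressionMatrix | None = None,
    samples: pd.DataFrame | None = None,
    gene_sets: GeneSetCollection | None = None,
    annotations: dict[str, str] | None = None,
) -> dict:
    """Execute every stage; in-memory inputs override configured paths."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"output_dir": str(outdir)}

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        name = stage("load")
        if expression is None:
            expression = vio.read_expression(config.expression_path)
        if samples is None:
            samples = vio.read_sample_table(config.metadata_path)
        if gene_sets is None and config.gmt_path:
            gene_sets = vio.read_gmt(config.gmt_path)
        if annotations is None and config.annotation_path:
            annotations = vio.read_annotations(config.annotation_path)
        log.info("loaded %d genes x %d samples", expression.n_genes,
                 expression.n_samples)

        name = stage("normalize")
        norm = normalize(expression, pseudocount=config.pseudocount)

        name = stage("filter")
        filtered = filter_features(norm, annotations, config.variance_top_k)
        report["n_genes_kept"] = filtered.n_genes
        log.info("kept %d genes", filtered.n_genes)

        name = stage("classify")
        labels = classify_response(samples, config.hr_threshold,
                                   config.fold_threshold)
        report["n_responders"] = sum(v == "R" for v in labels.response.values())
        report["n_subjects"] = len(labels.response)

        name = stage("diffexpr")
        de = {}
        for contrast in config.contrasts:
            out = de_contrast(filtered, samples, labels, contrast,
                              trend=config.trend, p_threshold=config.p_threshold)
            out.results.to_csv(outdir / f"de_{contrast}.tsv", sep="\t", index=False)
            de[contrast] = out
            report[f"de_{contrast}"] = {"n_up": out.n_up, "n_down": out.n_down}
            log.info("%s: %d up / %d down at p<=%.3g", contrast, out.n_up,
                     out.n_down, config.p_threshold)

        if gene_sets is not None:
            name = stage("enrichment")
            scores = gsva_scores(filtered, gene_sets)
            scores.to_csv(outdir / "enrichment_scores.tsv", sep="\t")
            dp = differential_pathways(scores, samples, labels,
                                       config.contrasts[0],
                                       p_threshold=config.p_threshold)
            dp.results.to_csv(outdir / "differential_pathways.tsv", sep="\t",
                              index=False)
            report["n_pathways"] = len(scores)
            report["n_significant_pathways"] = dp.n_significant

        name = stage("predict")
        wk2 = samples[samples["timepoint"] == "week2"]
        y = wk2["subject_id"].map(labels.response).map({"NR": 0, "R": 1})
        y.index = wk2["sample_id"].to_numpy()
        model = lasso_logistic_cv(
            filtered.subset_samples(y.index), y,
            k_folds=config.k_folds, inner_folds=config.inner_folds,
            n_lambdas=config.n_lambdas, seed=config.seed,
        )
        roc = roc_auc(model.heldout_probabilities, model.labels,
                      threshold=config.prob_threshold)
        wk2_idx = wk2.set_index("sample_id")
        corr = odds_titer_correlation(
            model.heldout_probabilities,
            wk2_idx.loc[model.labels.index, "igg_week12"],
            wk2_idx.loc[model.labels.index, "igg_week12"]
            / wk2_idx.loc[model.labels.index, "igg_week0"],
        )
        pd.DataFrame({
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }).to_csv(outdir / "roc_points.tsv", sep="\t", index=False)
        with open(outdir / "prediction_summary.json", "w") as fh:
            json.dump({"auroc": roc.auroc, "confusion": roc.confusion,
                       "odds_titer": corr,
                       "selected_features": model.selected_features,
                       "lambda": model.lambda_}, fh, indent=2)
        report["auroc"] = roc.auroc
        report["confusion"] = roc.confusion
        report["odds_titer"] = corr
        report["selected_features"] = model.selected_features
        log.info("held-out AUROC %.3f, %d features selected", roc.auroc,
                 len(model.selected_features))

        name = stage("graph")
        graph_genes = model.selected_features[: config.max_graph_genes]
        if not graph_genes:  # fall back to top DE genes so the stage runs
            graph_genes = de[config.contrasts[0]].top["gene_id"].head(10).tolist()
        frame = filtered.values.loc[graph_genes, y.index].T.copy()
        frame[OUTCOME_NODE] = np.log(
            wk2_idx.loc[y.index, "igg_week12"].to_numpy(dtype=float)
        )
        frame["sex"] = wk2_idx.loc[y.index, "sex"].to_numpy()
        frame["batch"] = wk2_idx.loc[y.index, "batch"].to_numpy()
        data = MixedDataset(frame.reset_index(drop=True), {})
        pag = edge_stability(
            data, config.mgm, n_subsamples=config.n_subsamples,
            subsample_frac=config.subsample_frac, seed=config.seed,
            alpha=config.alpha, max_cond_size=config.max_cond_size,
        )
        pag.write_graphml(outdir / "graph.graphml")
        pag.write_sif(outdir / "graph.sif")
        pag.write_edge_list(outdir / "graph_edges.tsv")
        direct = direct_neighbors(pag, OUTCOME_NODE)
        full_view = neighborhood(pag, OUTCOME_NODE, radius=2)
        with open(outdir / "direct_neighbors.json", "w") as fh:
            json.dump({"direct": direct, "full_model_nodes": full_view}, fh,
                      indent=2)
        report["n_edges"] = pag.n_edges()
        report["direct_neighbors"] = direct
        log.info("graph: %d edges, %d direct neighbors of %s", pag.n_edges(),
                 len(direct), OUTCOME_NODE)

        name = stage("manifest")
        vio.write_manifest(outdir, config.to_dict(), config.seed,
                           extra={"report_keys": sorted(report)})
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc
    return report
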