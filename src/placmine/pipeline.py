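"""Configuration-driven orchestration of the four analysis stages.

Stages: ``simulate`` (optional synthetic inputs) -> ``diff`` (dual-omics
screen + cross-omics overlap + sample clustering) -> ``textmine``
(tf-idf / LSA / k-means on the per-gene corpus) -> ``predict`` (trait
models + permutation importance) -> ``network`` (importance graph export).
Every stage reads and writes plain-text files, so each can be re-run in
isolation; all randomness derives from one master seed, and a JSON run
report records the derived sub-seeds and per-stage summary counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import network as net
from . import stats as ost
from .model import TRAITS, run_trait_models, select_features
from .simulate import SimConfig, simulate_omics_cohort, write_study
from .textmine import build_term_matrix, cluster_genes, fit_lsa, summarize_clusters

log = logging.getLogger(__name__)

STAGES = ("simulate", "diff", "textmine", "predict", "network")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; anything omitted keeps its default."""

    outdir: str = "placmine_out"
    # input paths (default to the simulate stage's own outputs)
    methylome: str | None = None
    transcriptome: str | None = None
    phenotypes: str | None = None
    feature_gene_map: str | None = None
    corpus: str | None = None
    # thresholds
    alpha_levene: float = 0.05
    q_threshold: float = 0.05
    include_threshold: float = 10.0
    label_threshold: float = 80.0
    supplementary_threshold: float = 50.0
    ga_subset_min: float = 37.0
    # text-mining parameters
    ngram_orders: tuple[int, ...] = (1, 2, 3)
    min_df: int = 2
    tfidf_norm: str = "l2"
    lsa_k: int = 1000
    k_clusters: int = 24
    top_m: int = 10
    # model parameters
    train_ratio: float = 2 / 3
    smote_k: int = 5
    cv_folds: int = 5
    n_repeats: int = 20
    # simulation + master seed
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {}) or {}
        cfg = cls(**raw)
        cfg.sim = SimConfig(**sim_raw)
        for key, val in overrides.items():
            if val is not None:
                setattr(cfg, key, val)
        return cfg

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic sub-seed per stage, derived from the master seed
        (kept below 2**31 for portability)."""
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGES))
        return {s: int(v & 0x7FFFFFFF) for s, v in zip(STAGES, state)}

    def path(self, name: str, default_name: str) -> Path:
        configured = getattr(self, name, None)
        return Path(configured) if configured else Path(self.outdir) / default_name


def _read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing input {path}; run the '{producer}' subcommand first or "
            f"point the config at an existing file"
        )
    return path


def _fmt(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def stage_simulate(cfg: PipelineConfig) -> dict:
    seed = cfg.stage_seeds()["simulate"]
    sim_cfg = cfg.sim
    sim_cfg.seed = seed
    study = simulate_omics_cohort(sim_cfg)
    paths = write_study(study, cfg.outdir)
    log.info(
        "simulate: %d meth x %d expr features, %d samples, %d genes",
        sim_cfg.n_meth_features, sim_cfg.n_expr_features,
        sim_cfg.n_control + sim_cfg.n_case, sim_cfg.n_genes,
    )
    return {
        "seed": seed,
        "n_samples": sim_cfg.n_control + sim_cfg.n_case,
        "n_meth_features": sim_cfg.n_meth_features,
        "n_expr_features": sim_cfg.n_expr_features,
        "files": {k: str(v) for k, v in paths.items()},
    }


def stage_diff(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meth = _read_matrix(_require(cfg.path("methylome", "methylome.tsv"), "simulate"))
    expr = _read_matrix(_require(cfg.path("transcriptome", "transcriptome.tsv"), "simulate"))
    pheno = _read_matrix(_require(cfg.path("phenotypes", "phenotypes.tsv"), "simulate"))
    fmap = pd.read_csv(
        _require(cfg.path("feature_gene_map", "feature_gene_map.tsv"), "simulate"),
        sep="\t", index_col=0,
    )["gene"]
    groups = pheno.loc[meth.columns, "group"]

    kw = dict(alpha_levene=cfg.alpha_levene, q_threshold=cfg.q_threshold)
    meth_stats = ost.run_differential(meth, groups, layer="methylation", **kw)
    expr_stats = ost.run_differential(expr, groups, layer="expression", **kw)
    _fmt(meth_stats, out / "meth_stats.tsv")
    _fmt(expr_stats, out / "expr_stats.tsv")

    overlap = ost.cross_omics_overlap(meth_stats, expr_stats, fmap)
    rs, ps, sigs = [], [], []
    for gene in overlap.index:
        corr = ost.meth_expr_correlation(gene, meth_stats, expr_stats, meth, expr, fmap)
        rs.append(corr.r)
        ps.append(corr.p)
        sigs.append(corr.significant)
    overlap["r"] = rs
    overlap["r_p"] = ps
    overlap["r_significant"] = sigs
    _fmt(overlap, out / "overlap_genes.tsv")

    # heatmap-style sample clustering on significant features per layer
    cluster_rows = []
    for layer, matrix, stats in (("methylation", meth, meth_stats), ("expression", expr, expr_stats)):
        sig = stats.index[stats["significant"]]
        if len(sig) == 0:
            continue
        hc = ost.hcluster_order(matrix.loc[sig])
        for rank, s in enumerate(hc["leaf_order"]):
            cluster_rows.append(
                {"layer": layer, "sample": s, "leaf_rank": rank,
                 "cluster": int(hc["two_cluster"][s])}
            )
    _fmt(pd.DataFrame(cluster_rows), out / "sample_clusters.tsv", index=False)

    # concordance with the high-gestational-age restricted subset
    keep = (pheno["group"] == "control") | (pheno["gestational_age"] >= cfg.ga_subset_min)
    kendall = {}
    subset = pheno.index[keep]
    if (pheno.loc[subset, "group"] == "case").sum() >= 2:
        for layer, matrix, stats in (("methylation", meth, meth_stats), ("expression", expr, expr_stats)):
            sub_stats = ost.run_differential(
                matrix[subset], pheno.loc[subset, "group"], layer=layer, **kw
            )
            tau, p = ost.kendall_concordance(stats, sub_stats)
            kendall[layer] = {"tau": tau, "p": p}

    n_meth_sig = int(meth_stats["significant"].sum())
    n_expr_sig = int(expr_stats["significant"].sum())
    log.info(
        "diff: %d significant methylation sites, %d transcripts, %d overlap genes",
        n_meth_sig, n_expr_sig, len(overlap),
    )
    return {
        "n_meth_tested": len(meth_stats),
        "n_expr_tested": len(expr_stats),
        "n_meth_significant": n_meth_sig,
        "n_expr_significant": n_expr_sig,
        "n_significant": n_meth_sig + n_expr_sig,
        "n_overlap_genes": len(overlap),
        "n_overlap_correlated": int(sum(sigs)),
        "kendall": kendall,
    }


def _load_corpus(path: Path) -> dict[str, list[str]]:
    docs: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            docs[rec["gene"]] = rec["abstracts"]
    return docs


def stage_textmine(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seeds()["textmine"]
    docs = _load_corpus(_require(cfg.path("corpus", "corpus.jsonl"), "simulate"))
    # restrict to genes carrying at least one significant feature when the
    # screen has run; otherwise mine the full corpus
    stats_paths = [out / "meth_stats.tsv", out / "expr_stats.tsv"]
    fmap_path = cfg.path("feature_gene_map", "feature_gene_map.tsv")
    if all(p.exists() for p in stats_paths) and fmap_path.exists():
        fmap = pd.read_csv(fmap_path, sep="\t", index_col=0)["gene"]
        sig_genes: set[str] = set()
        for p in stats_paths:
            stats = pd.read_csv(p, sep="\t", index_col=0)
            sig_genes |= set(fmap.reindex(stats.index[stats["significant"]]).dropna())
        selected = {g: d for g, d in docs.items() if g in sig_genes}
        if len(selected) >= 2:
            docs = selected
    tm = build_term_matrix(docs, ngram_orders=tuple(cfg.ngram_orders),
                           min_df=cfg.min_df, norm=cfg.tfidf_norm)
    model = fit_lsa(tm, cfg.lsa_k)
    k = min(cfg.k_clusters, len(model.genes))
    labels, wcss = cluster_genes(model, k, seed=seed)
    report = summarize_clusters(model, labels, top_m=cfg.top_m)

    _fmt(labels.to_frame().rename_axis("gene"), out / "gene_clusters.tsv")
    term_rows = [
        {"cluster": c, "rank": i, "term": term, "weight": w}
        for c, terms in sorted(report.top_terms.items())
        for i, (term, w) in enumerate(terms)
    ]
    _fmt(pd.DataFrame(term_rows), out / "cluster_terms.tsv", index=False)
    with open(out / "vocabulary.tsv", "w") as fh:
        fh.write("index\tterm\tdoc_freq\n")
        for i, (t, d) in enumerate(zip(tm.vocabulary, tm.doc_freq)):
            fh.write(f"{i}\t{t}\t{int(d)}\n")
    coo = tm.matrix.tocoo()
    with open(out / "term_matrix.tsv", "w") as fh:
        fh.write(f"# terms x genes sparse triplets, {tm.shape[0]} x {tm.shape[1]}\n")
        fh.write("term_index\tgene_index\tvalue\n")
        order = np.lexsort((coo.col, coo.row))
        for i in order:
            fh.write(f"{coo.row[i]}\t{coo.col[i]}\t{coo.data[i]:.10g}\n")
    log.info(
        "textmine: %d genes, %d terms, %d clusters (sizes %d-%d), retained var %.3f",
        len(model.genes), len(tm.vocabulary), k,
        report.sizes.min(), report.sizes.max(), model.retained_variance,
    )
    return {
        "seed": seed,
        "n_genes": len(model.genes),
        "n_terms": len(tm.vocabulary),
        "lsa_k": model.k,
        "retained_variance": model.retained_variance,
        "n_clusters": int(k),
        "cluster_sizes": {int(c): int(s) for c, s in report.sizes.items()},
        "wcss": wcss,
    }


def stage_predict(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seeds()["predict"]
    meth = _read_matrix(_require(cfg.path("methylome", "methylome.tsv"), "simulate"))
    expr = _read_matrix(_require(cfg.path("transcriptome", "transcriptome.tsv"), "simulate"))
    pheno = _read_matrix(_require(cfg.path("phenotypes", "phenotypes.tsv"), "simulate"))
    meth_stats = pd.read_csv(_require(out / "meth_stats.tsv", "diff"), sep="\t", index_col=0)
    expr_stats = pd.read_csv(_require(out / "expr_stats.tsv", "diff"), sep="\t", index_col=0)
    selected = select_features(meth_stats, expr_stats)
    features = pd.concat([meth, expr]).loc[selected]
    results = run_trait_models(
        features, pheno, ratio=cfg.train_ratio, smote_k=cfg.smote_k,
        cv_folds=cfg.cv_folds, n_repeats=cfg.n_repeats, seed=seed,
    )

    model_rows, pred_rows, imp_rows = [], [], []
    for name, res in results.items():
        model_rows.append(
            {
                "trait": name,
                "task": res.trait.task,
                "hyperparameters": json.dumps(res.best_params, sort_keys=True),
                "metric": res.trait.metric,
                "value": res.metric,
                "p_value": res.p_value,
                "defined": res.defined,
            }
        )
        for i in range(len(res.y_test)):
            pred_rows.append(
                {
                    "trait": name,
                    "actual": res.y_test[i],
                    "predicted": res.predictions[i],
                    "case_probability": (
                        res.probabilities[i] if res.probabilities is not None else np.nan
                    ),
                }
            )
        imp = res.importance.rename(columns={"raw": "raw", "percent": "percent"})
        for feat, row in imp.iterrows():
            imp_rows.append(
                {"feature": feat, "trait": name, "raw": row["raw"], "percent": row["percent"]}
            )
    _fmt(pd.DataFrame(model_rows), out / "trait_models.tsv", index=False)
    _fmt(pd.DataFrame(pred_rows), out / "predictions.tsv", index=False)
    _fmt(pd.DataFrame(imp_rows), out / "importance.tsv", index=False)
    metrics = {r["trait"]: {"metric": r["metric"], "value": r["value"], "p": r["p_value"]}
               for r in model_rows}
    log.info("predict: %d selected features; metrics %s", len(selected),
             {k: round(v["value"], 3) if np.isfinite(v["value"]) else None
              for k, v in metrics.items()})
    return {"seed": seed, "n_selected_features": len(selected), "metrics": metrics}


def stage_network(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    imp_path = _require(out / "importance.tsv", "predict")
    imp = pd.read_csv(imp_path, sep="\t")
    wide = imp.pivot_table(index="feature", columns="trait", values="percent", fill_value=0.0)
    wide = wide.reindex(columns=[t.name for t in TRAITS if t.name in wide.columns])
    g = net.build_importance_network(
        wide, include_threshold=cfg.include_threshold, label_threshold=cfg.label_threshold
    )
    net.write_sif(g, out / "network.sif")
    net.write_graphml(g, out / "network.graphml")
    supp = net.supplementary_table(wide, threshold=cfg.supplementary_threshold)
    _fmt(supp, out / "importance_ge50.tsv", index=False)
    n_features = sum(1 for _, d in g.nodes(data=True) if d["kind"] == "feature")
    n_labeled = sum(
        1 for _, d in g.nodes(data=True) if d["kind"] == "feature" and d["labeled"]
    )
    log.info("network: %d feature nodes (%d labeled), %d edges",
             n_features, n_labeled, g.number_of_edges())
    return {
        "n_feature_nodes": n_features,
        "n_labeled_features": n_labeled,
        "n_edges": g.number_of_edges(),
        "n_supplementary": len(supp),
    }


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in order and write the run report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "placmine_version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": cfg.stage_seeds(),
        "config": {k: v for k, v in asdict(cfg).items() if k != "sim"},
        "sim_config": asdict(cfg.sim),
        "stages": {},
    }
    runners = {
        "simulate": stage_simulate,
        "diff": stage_diff,
        "textmine": stage_textmine,
        "predict": stage_predict,
        "network": stage_network,
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("--- stage %s ---", stage)
        try:
            report["stages"][stage] = runners[stage](cfg)
        except Exception:
            log.error("stage %s failed", stage)
            raise
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str, sort_keys=True)
    return report
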