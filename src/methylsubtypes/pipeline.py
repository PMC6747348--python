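"""End-to-end orchestration: simulate → relevance → MCFS → SMOTE → IFS →
enrichment, with per-stage artifacts and a deterministic run manifest.

Every stage RNG is derived from one master seed, so two runs with the same
configuration produce byte-identical artifact files.  A ``--exclude-class``
mode drops one subtype up front and reruns the whole sweep on the remaining
classes (e.g. to probe how much of the error budget one confusable class
consumes).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import io as mio
from .balancing import SmoteBalancer, SmoteConfig, balance
from .datasets import (
    SimulationConfig,
    generate_annotation,
    generate_dataset,
    generate_gene_sets,
)
from .enrichment import enrich, probes_to_genes
from .mcfs import McfsConfig, ri_scores
from .model_eval import ClassifierSpec, confusion_metrics, cross_validate, ifs, multiclass_mcc
from .relevance import mr_filter

__all__ = ["PipelineConfig", "run_all", "plot_feature_distributions", "load_config"]

_STAGES = ("simulate", "annotation", "gene_sets", "mcfs", "smote", "cv")


def _stage_seeds(master_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :func:`load_config`."""

    seed: int = 1
    # synthetic-data stage (ignored when input_matrix is given)
    class_sizes: dict[str, int] | None = None
    n_probes: int = 2000
    n_informative: int = 100
    effect: float = 0.35
    dispersion: float = 10.0
    lum_proximity: bool = False
    # real-data mode
    input_matrix: str | None = None
    annotation_file: str | None = None
    gene_sets_file: str | None = None
    label_row_key: str = "subtype"
    # stages
    relevance_threshold: float = 0.2
    mcfs_p: int = 20
    mcfs_t: int = 50
    mcfs_m: int | None = None
    mcfs_min_leaf: int = 2
    mcfs_holdout: str = "oob"
    smote_k: int = 5
    leak_free: bool = False
    classifier: str = "svm_ovr"
    svm_degree: int = 1
    svm_C: float = 1.0
    rf_trees: int = 100
    score_mode: str = "decision"
    ifs_step: int = 10
    ifs_folds: int = 10
    ifs_max_k: int | None = None
    exclude_class: str | None = None
    # enrichment stage
    genes_per_probe_max: int = 2
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (5, 25)
    plant_term: bool = True
    enrichment_alpha: float = 0.05
    extra: dict = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    if "set_size_range" in kwargs:
        kwargs["set_size_range"] = tuple(kwargs["set_size_range"])
    return PipelineConfig(**kwargs, extra=extra)


def _json_dump(obj, path: Path) -> None:
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute every stage in order, persisting each stage's artifacts.

    Returns a summary dict (also written as ``manifest.json``) with the
    stage seeds, artifact names, optimum feature count and headline metrics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, str] = {}

    # ---- stage 1: obtain the labeled beta matrix --------------------------
    truth = None
    if config.input_matrix:
        matrix = mio.read_series_matrix(config.input_matrix, config.label_row_key)
        if config.annotation_file is None:
            raise ValueError("real-data mode requires annotation_file")
        annotation = mio.read_probe_annotation(config.annotation_file)
    else:
        sim = SimulationConfig(
            class_sizes=dict(config.class_sizes or SimulationConfig().class_sizes),
            n_probes=config.n_probes,
            n_informative=config.n_informative,
            effect=config.effect,
            dispersion=config.dispersion,
            lum_proximity=config.lum_proximity,
            seed=seeds["simulate"],
        )
        matrix, truth = generate_dataset(sim)
        annotation = generate_annotation(
            matrix.probe_ids, config.genes_per_probe_max, seed=seeds["annotation"]
        )
        mio.write_series_matrix(matrix, outdir / "series_matrix.tsv")
        mio.write_probe_annotation(annotation, outdir / "annotation.csv")
        _json_dump(
            {
                "informative_probes": sorted(truth.informative_probes),
                "class_mean_beta": {
                    probe: {c: float(v) for c, v in row.items()}
                    for probe, row in truth.class_mean_beta.iterrows()
                },
            },
            outdir / "ground_truth.json",
        )
        artifacts.update(
            series_matrix="series_matrix.tsv",
            annotation="annotation.csv",
            ground_truth="ground_truth.json",
        )

    if config.exclude_class:
        matrix = matrix.exclude_class(config.exclude_class)

    # ---- stage 2: maximum-relevance filter --------------------------------
    relevance = mr_filter(matrix, threshold=config.relevance_threshold)
    if not relevance.retained:
        raise RuntimeError(
            "relevance stage retained no probes; lower relevance_threshold"
        )
    mio.write_ranked_list(
        outdir / "relevance.tsv",
        relevance.retained,
        [relevance.scores[p] for p in relevance.retained],
    )
    artifacts["relevance"] = "relevance.tsv"
    retained = matrix.subset_probes(relevance.retained)

    # ---- stage 3: Monte Carlo feature selection ---------------------------
    # the relevance stage may retain fewer probes than the requested
    # projection size; cap m at the retained count
    m_eff = config.mcfs_m
    if m_eff is not None:
        m_eff = min(m_eff, retained.n_probes)
    table = ri_scores(
        retained,
        McfsConfig(
            p=config.mcfs_p,
            t=config.mcfs_t,
            m=m_eff,
            min_leaf=config.mcfs_min_leaf,
            holdout=config.mcfs_holdout,
            seed=seeds["mcfs"],
        ),
    )
    ranked = table.ranked
    mio.write_ranked_list(outdir / "ri.tsv", ranked, [table.scores[p] for p in ranked])
    artifacts["ri"] = "ri.tsv"

    # ---- stage 4: SMOTE balancing -----------------------------------------
    balancer = None
    if config.leak_free:
        eval_matrix = retained
        balancer = SmoteBalancer(k=config.smote_k, seed=seeds["smote"])
    else:
        eval_matrix = balance(
            retained, SmoteConfig(k=config.smote_k, seed=seeds["smote"])
        )
        mio.write_series_matrix(eval_matrix, outdir / "balanced.tsv")
        artifacts["balanced"] = "balanced.tsv"

    # ---- stage 5: incremental feature selection ---------------------------
    spec = ClassifierSpec(
        family=config.classifier,
        degree=config.svm_degree,
        C=config.svm_C,
        n_trees=config.rf_trees,
        score_mode=config.score_mode,
        seed=seeds["cv"],
    )
    sweep = ifs(
        ranked,
        eval_matrix,
        spec,
        step=config.ifs_step,
        folds=config.ifs_folds,
        seed=seeds["cv"],
        max_k=config.ifs_max_k,
        balancer=balancer,
    )
    best = sweep.optimum
    mio.write_ifs_table(outdir / "ifs.tsv", sweep.evaluations, eval_matrix.classes)
    mio.write_confusion(outdir / "confusion_best.tsv", best.confusion)
    mio.write_ranked_list(
        outdir / "optimum_features.tsv",
        best.features,
        [table.scores[p] for p in best.features],
    )
    artifacts.update(
        ifs="ifs.tsv",
        confusion_best="confusion_best.tsv",
        optimum_features="optimum_features.tsv",
    )

    metrics = {
        "optimum_k": best.k,
        "mcc": best.mcc,
        "accuracy": best.accuracy,
        "sensitivity": best.sensitivity,
        "specificity": best.specificity,
    }
    # companion report on original (non-oversampled) samples only
    if not config.leak_free and eval_matrix.synthetic.any():
        best_sub = eval_matrix.subset_probes(best.features)
        _, y_pred = cross_validate(
            best_sub, spec, folds=config.ifs_folds, seed=seeds["cv"]
        )
        orig = ~eval_matrix.synthetic
        y_true_o = best_sub.labels[orig].astype(str)
        y_pred_o = y_pred[orig].astype(str)
        conf_o = pd.DataFrame(
            _sk_confusion(y_true_o, y_pred_o, labels=eval_matrix.classes),
            index=eval_matrix.classes,
            columns=eval_matrix.classes,
        )
        mio.write_confusion(outdir / "confusion_best_original.tsv", conf_o)
        artifacts["confusion_best_original"] = "confusion_best_original.tsv"
        om = confusion_metrics(conf_o)
        metrics["original_samples_only"] = {
            "mcc": multiclass_mcc(y_pred_o, y_true_o),
            "accuracy": om["accuracy"],
            "sensitivity": om["sensitivity"],
            "specificity": om["specificity"],
        }

    # ---- stage 6: enrichment ----------------------------------------------
    universe = probes_to_genes(relevance.retained, annotation)
    hit_genes = probes_to_genes(best.features, annotation)
    if config.gene_sets_file:
        catalogue = mio.read_gene_sets(config.gene_sets_file)
    else:
        all_genes = annotation.all_genes()
        planted = sorted(hit_genes) if (config.plant_term and hit_genes) else None
        catalogue = generate_gene_sets(
            sorted(all_genes),
            n_sets=config.n_gene_sets,
            set_size_range=config.set_size_range,
            planted_term=planted,
            seed=seeds["gene_sets"],
        )
        mio.write_gene_sets(catalogue, outdir / "gene_sets.tsv")
        artifacts["gene_sets"] = "gene_sets.tsv"
    results = enrich(hit_genes, catalogue, universe, alpha=config.enrichment_alpha)
    with (outdir / "enrichment.tsv").open("w") as fh:
        fh.write("term_id\tterm_size\thit_overlap\tuniverse_size\tp_value\tfdr\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_size}\t{r.hit_overlap}\t{r.universe_size}\t"
                f"{repr(r.p_value)}\t{repr(r.fdr)}\t{int(r.significant)}\n"
            )
    artifacts["enrichment"] = "enrichment.tsv"

    manifest = {
        "package": "methylsubtypes",
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stage_seeds": seeds,
        "artifacts": artifacts,
        "class_sizes": matrix.class_sizes(),
        "n_retained": len(relevance.retained),
        "metrics": metrics,
        "n_significant_terms": sum(r.significant for r in results),
    }
    _json_dump(manifest, outdir / "manifest.json")
    return manifest


def plot_feature_distributions(matrix, features, path) -> None:
    """Per-feature boxplots of beta values stratified by subtype.

    One panel per feature, classes on the x-axis; raises on an empty feature
    list.
    """
    features = list(features)
    if not features:
        raise ValueError("no features to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = matrix.classes
    ncols = min(5, len(features))
    nrows = -(-len(features) // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3 * ncols, 2.5 * nrows), squeeze=False
    )
    col_of = {p: i for i, p in enumerate(matrix.probe_ids)}
    for ax in axes.ravel()[len(features):]:
        ax.set_visible(False)
    for ax, probe in zip(axes.ravel(), features):
        if probe not in col_of:
            raise KeyError(f"unknown probe {probe!r}")
        data = [
            matrix.values[matrix.labels == c, col_of[probe]] for c in classes
        ]
        ax.boxplot(data, tick_labels=classes)
        ax.set_title(probe, fontsize=8)
        ax.tick_params(axis="x", labelrotation=45, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
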