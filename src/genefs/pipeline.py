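"""End-to-end pipeline: split -> FDR screen -> rank -> subset -> evaluate.

Every stochastic stage derives its seed from the single top-level seed via
:func:`genefs._rand.child_seed`; the run log written next to the other
artifacts records the resolved parameters and all derived seeds, so a run
is reproducible from the log alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Any

import yaml

from ._rand import child_seed
from .evaluate import EvalReport, evaluate_subset, select_best_subset
from .io_expr import ExpressionMatrix, read_expression, stratified_split
from .mrmr import mrmr_rank, select_candidate_size
from .param_opt import ParamPair, SearchSpace
from .prefilter import differential_expression, filter_by_q
from .rffs import rffs_gs, rffs_rank
from .svm_rfe import rfe_rank
from .synthetic import SyntheticSpec, generate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

SELECTORS = (
    "svm-rfe", "svm-rfe-gs", "svm-rfe-pso", "svm-rfe-ga",
    "rffs", "rffs-gs", "mrmr",
)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    # input: either a file or a synthetic spec
    input_path: str | None = None
    orientation: str = "samples-by-genes"
    label_source: str | None = None
    delimiter: str | None = None
    positive_label: str | None = None
    synthetic: SyntheticSpec | None = None

    seed: int = 0
    test_fraction: float = 0.5
    q_threshold: float = 0.2

    selector: str = "svm-rfe-pso"
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None
    reoptimize_every: int = 1
    search_space: SearchSpace = dataclasses.field(default_factory=SearchSpace)
    optimizer_kwargs: dict = dataclasses.field(default_factory=dict)
    rf_max_features_grid: list[int] | None = None
    rf_n_estimators_grid: list[int] | None = None
    rffs_folds: int = 10
    mrmr_n: int | None = None
    mrmr_tolerance: float = 0.01
    eval_folds: int = 5
    max_subset_size: int | None = None

    outdir: str = "genefs_out"

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path or synthetic must be set")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        if "search_space" in raw and isinstance(raw["search_space"], dict):
            ss = raw["search_space"]
            raw["search_space"] = SearchSpace(
                log2C_range=tuple(ss.get("log2C_range", (-5.0, 15.0, 2.0))),
                log2gamma_range=tuple(ss.get("log2gamma_range", (-15.0, 3.0, 2.0))),
            )
        return cls(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage '{name}': {e}") from e
        return inner
    return wrap


@_stage("load")
def _load(config: PipelineConfig) -> ExpressionMatrix:
    if config.synthetic is not None:
        expr, _ = generate(config.synthetic)
        return expr
    return read_expression(
        config.input_path,
        orientation=config.orientation,
        label_source=config.label_source,
        delimiter=config.delimiter,
        positive_label=config.positive_label,
    )


@_stage("rank")
def _rank(config: PipelineConfig, train: ExpressionMatrix, seed: int):
    """Returns (ordered gene list, extra artifacts dict)."""
    sel = config.selector
    fixed = ParamPair(C=config.C, gamma=config.gamma or 1.0 / train.n_genes)
    if sel in ("svm-rfe", "svm-rfe-gs", "svm-rfe-pso", "svm-rfe-ga"):
        optimizer = {"svm-rfe": "none", "svm-rfe-gs": "grid",
                     "svm-rfe-pso": "pso", "svm-rfe-ga": "ga"}[sel]
        ranked = rfe_rank(
            train,
            optimizer=optimizer,
            kernel=config.kernel,
            fixed_params=fixed,
            reoptimize_every=config.reoptimize_every,
            seed=seed,
            space=config.search_space,
            cv_folds=config.eval_folds,
            optimizer_kwargs=config.optimizer_kwargs,
        )
        return ranked.by_rank(), {"ranked_list": ranked}
    if sel in ("rffs", "rffs-gs"):
        if sel == "rffs":
            res = rffs_rank(train, folds=config.rffs_folds, seed=seed)
        else:
            res = rffs_gs(
                train,
                max_features_grid=config.rf_max_features_grid,
                n_estimators_grid=config.rf_n_estimators_grid,
                folds=config.rffs_folds,
                seed=seed,
            )
        return list(res.fg_sort), {"rffs_result": res}
    ranking = mrmr_rank(train, n=config.mrmr_n)
    return list(ranking.selection_order), {"mrmr_ranking": ranking}


def run_pipeline(config: PipelineConfig) -> EvalReport:
    """Execute the full pipeline and write artifacts under ``config.outdir``.

    Artifacts: ``ranked_list.tsv`` (rank order), ``subset.tsv`` (chosen
    genes), ``metrics.tsv``, ``roc_points.tsv`` and ``run_log.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: dict[str, Any] = {"seed": config.seed, "selector": config.selector,
                           "stages": {}}

    expr = _load(config)
    log["stages"]["load"] = {"n_samples": expr.n_samples, "n_genes": expr.n_genes}

    split_seed = child_seed(config.seed, "split")
    try:
        train, test = stratified_split(expr, config.test_fraction, split_seed)
    except Exception as e:
        raise PipelineError(f"stage 'split': {e}") from e
    log["stages"]["split"] = {
        "seed": split_seed,
        "train": train.n_samples,
        "test": test.n_samples,
    }

    try:
        de = differential_expression(train)
        train_f = filter_by_q(train, de, config.q_threshold)
        test_f = test.subset_genes(train_f.gene_ids)
    except Exception as e:
        raise PipelineError(f"stage 'prefilter': {e}") from e
    de.to_tsv(outdir / "differential_expression.tsv")
    log["stages"]["prefilter"] = {
        "q_threshold": config.q_threshold, "genes_kept": train_f.n_genes,
    }

    rank_seed = child_seed(config.seed, "rank")
    order, artifacts = _rank(config, train_f, rank_seed)
    with open(outdir / "ranked_list.tsv", "w") as fh:
        fh.write("rank\tgene_id\n")
        for r, g in enumerate(order, start=1):
            fh.write(f"{r}\t{g}\n")
    log["stages"]["rank"] = {"seed": rank_seed, "n_ranked": len(order)}

    select_seed = child_seed(config.seed, "select")
    try:
        if config.selector == "mrmr":
            cand = select_candidate_size(
                artifacts["mrmr_ranking"], train_f,
                folds=config.eval_folds, tolerance=config.mrmr_tolerance,
                seed=select_seed, kernel=config.kernel, C=config.C,
                gamma=config.gamma,
            )
            subset = order[: cand.n_star]
            subset_cv = 1.0 - cand.e_star
            log["stages"]["select"] = {
                "seed": select_seed, "n_star": cand.n_star,
                "e_star": cand.e_star, "omega": cand.omega,
            }
        else:
            subset, subset_cv = select_best_subset(
                order, train_f, kernel=config.kernel, C=config.C,
                gamma=config.gamma, folds=config.eval_folds, seed=select_seed,
                max_size=config.max_subset_size,
            )
            log["stages"]["select"] = {
                "seed": select_seed, "subset_size": len(subset),
                "cv_accuracy": subset_cv,
            }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage 'select': {e}") from e
    with open(outdir / "subset.tsv", "w") as fh:
        fh.write("gene_id\n")
        for g in subset:
            fh.write(g + "\n")

    try:
        report = evaluate_subset(
            train_f, test_f, subset, kernel=config.kernel, C=config.C,
            gamma=config.gamma,
        )
    except Exception as e:
        raise PipelineError(f"stage 'evaluate': {e}") from e
    report.to_tsv(outdir / "metrics.tsv")
    report.roc_to_tsv(outdir / "roc_points.tsv")
    log["stages"]["evaluate"] = {
        "accuracy": report.accuracy, "auc": report.auc,
        "subset_size": len(subset),
    }
    log["elapsed_seconds"] = round(time.time() - t0, 3)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return report
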