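"""Config-driven orchestration of the full sweep-detection study.

One :class:`ExperimentConfig` describes a complete experiment: simulate a
balanced neutral/sweep dataset, preprocess it into images, train the
requested networks, fit summary-statistic thresholds on the training
split, and evaluate everything on the held-out test split, producing an
accuracy table and cross-method comparison matrices.

Stages are cached on disk keyed by a hash of the config section that
feeds them (plus the master seed), so retraining a model does not
re-simulate, and re-running a stage from cached upstream artifacts
reproduces downstream outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .demography import (
    DemographyModel,
    LabeledDataset,
    SimRegionParams,
    SweepParams,
    build_single_pop_demography,
    build_three_pop_demography,
    generate_dataset,
    load_dataset,
    save_dataset,
)
from .evaluate import EvalReport, agreement_matrix, evaluate_scores, spearman_matrix
from .models import (
    TrainConfig,
    TrainedModel,
    build_deepset,
    build_imagene,
    build_mini_cnn,
    load_model,
    predict,
    save_model,
    train,
)
from .preprocess import PreprocessConfig, preprocess_dataset, stack_images
from .stats import (
    StatResult,
    evaluate_statistic,
    fit_ihs_standardizer,
    garud_h1,
    max_abs_ihs,
    segregating_sites,
)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "compare_width_strategies"]

log = logging.getLogger("sweepnet")

THREE_POP_MUTATION_RATE = 2.363e-8


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    demography: str = "single_pop"  # single_pop | three_pop
    s_het: float = 0.01
    target_population: str | None = None  # three_pop only (e.g. "CEU")
    n_per_class: int = 2000
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    sequence_length_bp: int = 80_000
    n_haplotypes: int = 128
    mutation_rate: float | None = None  # None: per-demography default
    recombination_rate: float = 1e-8
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    models: tuple[str, ...] = ("mini_cnn", "imagene", "deepset")
    statistics: tuple[str, ...] = ("h1", "s")
    epochs: int = 2
    batch_size: int = 64
    learning_rate: float = 0.001
    restarts: int = 10
    restart_overrides: tuple[tuple[str, int], ...] = ()
    seed: int = 1
    ihs_standardizer_sims: int = 300
    # CNN decision thresholds for the agreement comparison are fitted on a
    # deterministic subsample of the training split of this size (None: all)
    threshold_fit_samples: int | None = None

    def restarts_for(self, model_name: str) -> int:
        return dict(self.restart_overrides).get(model_name, self.restarts)

    def region(self) -> SimRegionParams:
        mu = self.mutation_rate
        if mu is None:
            mu = THREE_POP_MUTATION_RATE if self.demography == "three_pop" else 1.5e-8
        return SimRegionParams(
            sequence_length_bp=self.sequence_length_bp,
            mutation_rate_per_bp_per_gen=mu,
            recombination_rate_per_bp_per_gen=self.recombination_rate,
            n_haplotypes=self.n_haplotypes,
            seed=self.seed,
        )

    def demography_model(self) -> DemographyModel:
        if self.demography == "single_pop":
            return build_single_pop_demography()
        if self.demography == "three_pop":
            return build_three_pop_demography()
        raise ValueError(f"unknown demography {self.demography!r}")

    def sweep(self) -> SweepParams:
        return SweepParams(s_het=self.s_het, target_population=self.target_population)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["preprocess"] = dataclasses.asdict(self.preprocess)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        doc = dict(doc)
        if "preprocess" in doc and isinstance(doc["preprocess"], dict):
            doc["preprocess"] = PreprocessConfig(**doc["preprocess"])
        for key in ("split_fractions", "models", "statistics"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        if "restart_overrides" in doc:
            doc["restart_overrides"] = tuple(
                tuple(item) for item in doc["restart_overrides"]
            )
        return cls(**doc)


def _hash(doc) -> str:
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    accuracy_table: pd.DataFrame
    eval_reports: dict[str, EvalReport]
    agreement: pd.DataFrame
    spearman: pd.DataFrame
    models: dict[str, TrainedModel]
    stat_results: dict[str, StatResult]
    metadata: dict


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def simulate_stage(cfg: ExperimentConfig, cache_dir: Path | None = None) -> LabeledDataset:
    key = _hash(
        {
            "demography": cfg.demography,
            "s_het": cfg.s_het,
            "target": cfg.target_population,
            "n_per_class": cfg.n_per_class,
            "split": cfg.split_fractions,
            "region": dataclasses.asdict(cfg.region()),
            "seed": cfg.seed,
        }
    )
    if cache_dir is not None:
        path = Path(cache_dir) / "datasets" / key
        if (path / "metadata.json").exists():
            log.info("simulate: cache hit %s", key)
            return load_dataset(path)
    t0 = time.time()
    ds = generate_dataset(
        cfg.demography_model(),
        cfg.region(),
        cfg.sweep(),
        n_per_class=cfg.n_per_class,
        split_fractions=cfg.split_fractions,
        seed=cfg.seed,
    )
    log.info("simulate: %d samples in %.1fs", len(ds), time.time() - t0)
    if cache_dir is not None:
        save_dataset(ds, path)
    return ds


def preprocess_stage(
    ds: LabeledDataset, config: PreprocessConfig
) -> dict:
    """Images (n, H, W) float32 plus per-sample source widths."""
    t0 = time.time()
    images = preprocess_dataset(ds.samples, config)
    out = {
        "images": stack_images(images),
        "source_widths": np.array([im.source_width for im in images]),
        "target_width": images[0].pixels.shape[1],
        "config": config,
    }
    log.info("preprocess[%s]: width %d in %.1fs", config.width_strategy,
             out["target_width"], time.time() - t0)
    return out


def stats_stage(
    cfg: ExperimentConfig, ds: LabeledDataset
) -> dict[str, StatResult]:
    """Per-sample statistic values with training-split-fitted thresholds.

    Statistics are computed on the filtered (major/minor, MAF >= 1%) but
    unstandardized-width matrices, except iHS which keeps ancestral/derived
    coding and is standardized against matched neutral simulations.
    """
    from .preprocess import filter_minor_allele, polarize_major_minor

    results: dict[str, StatResult] = {}
    train_idx = ds.splits["train"]
    filtered = [
        filter_minor_allele(polarize_major_minor(m), cfg.preprocess.min_maf)
        for m in ds.samples
    ]
    for stat in cfg.statistics:
        t0 = time.time()
        if stat == "h1":
            values = np.array([garud_h1(m) for m in filtered])
        elif stat == "s":
            values = np.array(
                [float(segregating_sites(m)) for m in filtered], dtype=float
            )
        elif stat == "ihs":
            values = _ihs_values(cfg, ds)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
        results[stat] = evaluate_statistic(stat, values, ds.labels, train_idx)
        log.info("stats[%s]: fitted threshold %.4g in %.1fs", stat,
                 results[stat].threshold, time.time() - t0)
    return results


def _ihs_values(cfg: ExperimentConfig, ds: LabeledDataset) -> np.ndarray:
    import dataclasses as dc

    from .demography import simulate_neutral
    from .preprocess import filter_minor_allele

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 97]))
    dem = cfg.demography_model()
    neutral = []
    for _ in range(cfg.ihs_standardizer_sims):
        seed = int(rng.integers(1, 2**31 - 1))
        region = dc.replace(cfg.region(), seed=seed)
        neutral.append(
            filter_minor_allele(
                simulate_neutral(dem, region, population=cfg.target_population),
                cfg.preprocess.min_maf,
            )
        )
    std = fit_ihs_standardizer(neutral)
    values = []
    for m in ds.samples:
        filtered = filter_minor_allele(m, cfg.preprocess.min_maf)
        v = max_abs_ihs(filtered, std)
        values.append(0.0 if np.isnan(v) else v)
    return np.asarray(values)


_ARCHES = {
    "mini_cnn": lambda h, w: build_mini_cnn(h, w),
    "mini_cnn_1x2": lambda h, w: build_mini_cnn(h, w, kernel=(1, 2)),
    "mini_cnn_linear": lambda h, w: build_mini_cnn(h, w, relu=False),
    "imagene": lambda h, w: build_imagene(h, w),
    "deepset": lambda h, w: build_deepset(h, w),
}


def _base_arch(model_name: str) -> str:
    return model_name[: -len("_unsorted")] if model_name.endswith("_unsorted") else model_name


def train_stage(
    cfg: ExperimentConfig,
    model_name: str,
    images: np.ndarray,
    ds: LabeledDataset,
    cache_dir: Path | None = None,
) -> TrainedModel:
    arch = _base_arch(model_name)
    if arch not in _ARCHES:
        raise ValueError(f"unknown model {model_name!r}")
    key = _hash(
        {
            "model": model_name,
            "preprocess": dataclasses.asdict(cfg.preprocess),
            "train": [cfg.epochs, cfg.batch_size, cfg.learning_rate, cfg.restarts_for(model_name)],
            "data": [cfg.demography, cfg.s_het, cfg.target_population, cfg.n_per_class],
            "seed": cfg.seed,
        }
    )
    if cache_dir is not None:
        path = Path(cache_dir) / "models" / key
        if (path / "spec.json").exists():
            log.info("train[%s]: cache hit %s", model_name, key)
            return load_model(path)
    h, w = images.shape[1], images.shape[2]
    spec = _ARCHES[arch](h, w)
    tc = TrainConfig(
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        restarts=cfg.restarts_for(model_name),
        seed=cfg.seed,
    )
    tr, va = ds.splits["train"], ds.splits["val"]
    t0 = time.time()
    model = train(spec, images[tr], ds.labels[tr], images[va], ds.labels[va], tc)
    log.info(
        "train[%s]: val acc %.4f (restart %d) in %.1fs",
        model_name, model.val_accuracy, model.restart_index, time.time() - t0,
    )
    if cache_dir is not None:
        save_model(model, path)
    return model


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def run_experiment(
    cfg: ExperimentConfig,
    output_dir: str | Path | None = None,
    cache_dir: str | Path | None = None,
) -> ExperimentReport:
    """Simulate, preprocess, train, fit thresholds and evaluate.

    CNN accuracies in the table use the 0.5 score cutoff; the agreement
    matrix uses training-set-optimal thresholds for every method (CNNs and
    statistics alike).  Deterministic given ``cfg.seed``.
    """
    cache_dir = Path(cache_dir) if cache_dir else None
    ds = simulate_stage(cfg, cache_dir)
    branches: dict[str, dict] = {}

    def branch_for(model_name: str) -> dict:
        sorted_branch = not model_name.endswith("_unsorted")
        key = "sorted" if sorted_branch else "unsorted"
        if key not in branches:
            pp = cfg.preprocess if sorted_branch else dataclasses.replace(
                cfg.preprocess, row_sorting="none"
            )
            branches[key] = preprocess_stage(ds, pp)
        return branches[key]

    test_idx, train_idx = ds.splits["test"], ds.splits["train"]
    y_test = ds.labels[test_idx]
    if cfg.threshold_fit_samples and cfg.threshold_fit_samples < len(train_idx):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 41]))
        thr_idx = np.sort(rng.choice(train_idx, cfg.threshold_fit_samples, replace=False))
    else:
        thr_idx = train_idx

    models: dict[str, TrainedModel] = {}
    reports: dict[str, EvalReport] = {}
    test_scores: dict[str, np.ndarray] = {}
    optimal_calls: dict[str, np.ndarray] = {}

    for pos, model_name in enumerate(cfg.models):
        branch = branch_for(model_name)
        model = train_stage(cfg, model_name, branch["images"], ds, cache_dir)
        models[model_name] = model
        eval_idx = np.concatenate([thr_idx, test_idx])
        eval_scores = predict(model, branch["images"][eval_idx])
        scores = np.full(len(ds), np.nan)
        scores[eval_idx] = eval_scores
        # release preprocessing branches no later model needs (peak-memory)
        still_needed = {
            "unsorted" if m.endswith("_unsorted") else "sorted"
            for m in cfg.models[pos + 1 :]
        }
        for key in list(branches):
            if key not in still_needed:
                branches.pop(key)
        test_scores[model_name] = scores[test_idx]
        reports[model_name] = evaluate_scores(model_name, scores[test_idx], y_test)
        # training-set-optimal threshold for the agreement comparison
        from .stats import fit_threshold

        clf = fit_threshold(scores[thr_idx], ds.labels[thr_idx])
        optimal_calls[model_name] = clf.predict(scores[test_idx])

    stat_results = stats_stage(cfg, ds)
    for name, res in stat_results.items():
        calls = res.classifier.predict(res.values[test_idx])
        reports[name] = evaluate_scores(name, res.values[test_idx], y_test, calls=calls)
        test_scores[name] = res.values[test_idx]
        optimal_calls[name] = calls

    sp_mat, sp_names = spearman_matrix(test_scores)
    ag_mat, ag_names = agreement_matrix(optimal_calls)
    spearman_df = pd.DataFrame(sp_mat, index=sp_names, columns=sp_names)
    agreement_df = pd.DataFrame(ag_mat, index=ag_names, columns=ag_names)

    rows = [
        {
            "method": name,
            "accuracy": rep.accuracy,
            "ci_low": rep.ci_low,
            "ci_high": rep.ci_high,
            "auc": rep.auc,
            "n_test": rep.n_test,
        }
        for name, rep in reports.items()
    ]
    table = pd.DataFrame(rows).set_index("method")

    metadata = {
        "config": cfg.to_dict(),
        "config_hash": _hash(cfg.to_dict()),
        "seed": cfg.seed,
        "engine": ds.metadata.get("engine"),
        "code_version": __version__,
        "n_samples": len(ds),
    }
    report = ExperimentReport(
        config=cfg,
        accuracy_table=table,
        eval_reports=reports,
        agreement=agreement_df,
        spearman=spearman_df,
        models=models,
        stat_results=stat_results,
        metadata=metadata,
    )
    if output_dir is not None:
        _write_report(report, Path(output_dir))
    return report


def _write_report(report: ExperimentReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"# config_hash={report.metadata['config_hash']} seed={report.metadata['seed']} "
        f"engine={report.metadata['engine']} version={report.metadata['code_version']}\n"
    )
    for name, df in (
        ("accuracy.csv", report.accuracy_table),
        ("agreement.csv", report.agreement),
        ("spearman.csv", report.spearman),
    ):
        with open(out / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh)
    (out / "metadata.json").write_text(json.dumps(report.metadata, indent=2, default=str))
    for model_name, model in report.models.items():
        save_model(model, out / "models" / model_name)


def compare_width_strategies(
    cfg: ExperimentConfig,
    output_dir: str | Path | None = None,
    cache_dir: str | Path | None = None,
    attribution_images: int = 25,
) -> pd.DataFrame:
    """Run the same dataset through resize, zero_pad and trim branches.

    Returns a table of per-branch image widths and test accuracies for
    each model and statistic, plus edge-versus-center mean |attribution|
    summaries for the first configured model.
    """
    cache_dir = Path(cache_dir) if cache_dir else None
    ds = simulate_stage(cfg, cache_dir)
    test_idx = ds.splits["test"]
    y_test = ds.labels[test_idx]
    stat_results = stats_stage(cfg, ds)

    rows = []
    for strategy in ("resize", "zero_pad", "trim"):
        branch_cfg = dataclasses.replace(
            cfg, preprocess=dataclasses.replace(cfg.preprocess, width_strategy=strategy)
        )
        branch = preprocess_stage(ds, branch_cfg.preprocess)
        row: dict = {"strategy": strategy, "width": branch["target_width"]}
        for model_name in cfg.models:
            model = train_stage(branch_cfg, model_name, branch["images"], ds, cache_dir)
            scores = predict(model, branch["images"][test_idx])
            row[f"acc_{model_name}"] = evaluate_scores(model_name, scores, y_test).accuracy
            if model_name == cfg.models[0] and attribution_images > 0:
                row.update(_edge_attribution_summary(model, branch, ds, attribution_images))
        for stat, res in stat_results.items():
            calls = res.classifier.predict(res.values[test_idx])
            row[f"acc_{stat}"] = float(np.mean(calls == y_test))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("strategy")
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "width_strategies.csv")
    return table


def _edge_attribution_summary(
    model: TrainedModel, branch: dict, ds: LabeledDataset, n_images: int
) -> dict:
    from .interpret import average_attribution

    images = branch["images"]
    tr = ds.splits["train"]
    neutral_bg = images[tr][ds.labels[tr] == 0][:20]
    sweep_bg = images[tr][ds.labels[tr] == 1][:20]
    background = np.concatenate([neutral_bg, sweep_bg])
    te = ds.splits["test"]
    by_class = {
        "neutral": images[te][ds.labels[te] == 0][:n_images],
        "sweep": images[te][ds.labels[te] == 1][:n_images],
    }
    maps = average_attribution(model, by_class, background, steps=16)
    mean_abs = np.mean(
        [np.abs(m.values) for m in maps.values()], axis=0
    ).mean(axis=0)  # per-column
    width = mean_abs.size
    edge = width // 10
    return {
        "attr_edge_columns": float(np.mean(np.concatenate([mean_abs[:edge], mean_abs[-edge:]]))),
        "attr_center_columns": float(np.mean(mean_abs[edge:-edge])),
    }
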