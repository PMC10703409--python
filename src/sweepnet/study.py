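"""Desk-scale reproduction of the headline single-population study.

Runs the complete comparison on the three-epoch single-population model
with a moderate hard sweep (s_het = 0.01): Garud's H1 and S threshold
classifiers, mini-CNN (with and without its ReLU), the Imagene-style CNN
(trained on sorted and unsorted images) and the DeepSet network, all on
one shared simulated dataset, and returns the headline quantities
(per-method held-out accuracies, the mini-CNN/Imagene gap, the ReLU
ablation drop, and H1-vs-CNN binary agreement).

Scale defaults: 2,000 simulations per class and reduced restart counts
(3 for the mini-CNN variants, 2 for the Imagene models, 1 for DeepSet,
whose 1x5/64-kernel stack dominates CPU cost).  Paper-scale settings
(50,000 per class, 10 restarts) are reachable through
:class:`~sweepnet.pipeline.ExperimentConfig`.
"""

from __future__ import annotations

from pathlib import Path

from .pipeline import ExperimentConfig, ExperimentReport, run_experiment

__all__ = ["single_pop_study_config", "run_single_pop_study", "headline_numbers"]


def single_pop_study_config(seed: int, n_per_class: int = 2000) -> ExperimentConfig:
    return ExperimentConfig(
        demography="single_pop",
        s_het=0.01,
        n_per_class=n_per_class,
        models=(
            "mini_cnn",
            "mini_cnn_linear",
            "imagene",
            "imagene_unsorted",
            "deepset",
        ),
        statistics=("h1", "s"),
        restarts=5,
        restart_overrides=(("imagene", 2), ("imagene_unsorted", 1), ("deepset", 1)),
        threshold_fit_samples=1600,
        seed=seed,
    )


def run_single_pop_study(
    seed: int,
    n_per_class: int = 2000,
    cache_dir: str | Path | None = None,
    output_dir: str | Path | None = None,
) -> ExperimentReport:
    cfg = single_pop_study_config(seed, n_per_class)
    return run_experiment(cfg, output_dir=output_dir, cache_dir=cache_dir)


def headline_numbers(report: ExperimentReport) -> dict[str, float]:
    """Headline quantities, in percent, from a finished study report."""
    acc = {name: rep.accuracy * 100 for name, rep in report.eval_reports.items()}
    agreement = report.agreement
    h1_cnn_agreement = (
        (agreement.loc["h1", "mini_cnn"] + agreement.loc["h1", "imagene"]) / 2 * 100
    )
    return {
        "h1_accuracy": acc["h1"],
        "mini_cnn_accuracy": acc["mini_cnn"],
        "imagene_accuracy": acc["imagene"],
        "deepset_accuracy": acc["deepset"],
        "s_accuracy": acc["s"],
        "mini_imagene_gap": abs(acc["imagene"] - acc["mini_cnn"]),
        "relu_removal_drop": acc["mini_cnn"] - acc["mini_cnn_linear"],
        "h1_cnn_agreement": h1_cnn_agreement,
        "imagene_unsorted_accuracy": acc["imagene_unsorted"],
        "n_test": report.eval_reports["h1"].n_test,
    }
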