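"""Figure bundle: weight maps and attribution maps as raster images."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .interpret import average_attribution
from .models import TrainedModel, extract_mini_cnn_weights
from .pipeline import ExperimentConfig, preprocess_stage, simulate_stage, train_stage

__all__ = ["plot_weight_map", "plot_attribution_maps", "explain_figures"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_weight_map(model: TrainedModel, path: Path) -> Path:
    """Convolution kernel and dense-weight map of a mini-CNN."""
    plt = _mpl()
    kernel, dense = extract_mini_cnn_weights(model)
    fig, (ax0, ax1) = plt.subplots(
        1, 2, figsize=(8, 4), gridspec_kw={"width_ratios": [1, 6]}
    )
    ax0.imshow(kernel, cmap="gray")
    ax0.set_title("kernel")
    for (i, j), v in np.ndenumerate(kernel):
        ax0.text(j, i, f"{v:.2f}", ha="center", va="center", color="red")
    im = ax1.imshow(dense, cmap="gray", aspect="auto")
    ax1.set_title("dense weights map")
    ax1.set_xlabel("site column")
    ax1.set_ylabel("row pair")
    fig.colorbar(im, ax=ax1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_attribution_maps(maps: dict, path: Path) -> Path:
    """Class-averaged attribution maps, red toward sweep / blue toward neutral."""
    plt = _mpl()
    fig, axes = plt.subplots(1, len(maps), figsize=(5 * len(maps), 4))
    if len(maps) == 1:
        axes = [axes]
    vmax = max(np.abs(m.values).max() for m in maps.values()) or 1.0
    for ax, (name, amap) in zip(axes, maps.items()):
        im = ax.imshow(amap.values, cmap="bwr", vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_title(f"mean attribution: {name}")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def explain_figures(
    cfg: ExperimentConfig,
    model_name: str | None,
    out: Path,
    cache_dir: str | Path | None = None,
    n_per_class: int = 50,
) -> list[Path]:
    """Train (or load cached) one model and write its explanation figures."""
    model_name = model_name or cfg.models[0]
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_stage(cfg, Path(cache_dir) if cache_dir else None)
    branch = preprocess_stage(ds, cfg.preprocess)
    model = train_stage(cfg, model_name, branch["images"], ds,
                        Path(cache_dir) if cache_dir else None)
    paths = []
    if model.spec.name.startswith("mini_cnn"):
        paths.append(plot_weight_map(model, out / f"{model_name}_weights.png"))
    images = branch["images"]
    tr, te = ds.splits["train"], ds.splits["test"]
    background = np.concatenate(
        [images[tr][ds.labels[tr] == 0][:20], images[tr][ds.labels[tr] == 1][:20]]
    )
    by_class = {
        "neutral": images[te][ds.labels[te] == 0][:n_per_class],
        "sweep": images[te][ds.labels[te] == 1][:n_per_class],
    }
    maps = average_attribution(model, by_class, background, steps=16)
    paths.append(plot_attribution_maps(maps, out / f"{model_name}_attribution.png"))
    return paths
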