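"""Attribution maps and weight-map visualization for trained models.

Attribution follows the expected-gradients scheme: for an input image x
and a background sample b, the model score f is integrated along the
straight path from b to x,

    attr(x; b) = (x - b) * integral_0^1 grad f(b + a (x - b)) da,

and averaged over the background set (20 neutral + 20 sweep images by
default).  The path integral is evaluated by a midpoint rule, so the
attributions satisfy the completeness identity

    sum_pixels attr(x) ~= f(x) - mean_b f(b)

up to quadrature error (exact for linear models).  Positive values push
the prediction toward the sweep class, negative toward neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import TrainedModel

__all__ = ["AttributionMap", "attribution_map", "average_attribution"]

DEFAULT_STEPS = 32


class InputError(ValueError):
    pass


@dataclass
class AttributionMap:
    """Per-pixel additive importance values for one image (or a class mean).

    Sign convention: positive pushes the score toward sweep.
    """

    values: np.ndarray
    background_size: int
    steps: int
    completeness_residual: float | None = None


def _as_image_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    return x[None] if x.ndim == 2 else x


def attribution_map(
    model: TrainedModel,
    image: np.ndarray,
    background: np.ndarray,
    steps: int = DEFAULT_STEPS,
) -> AttributionMap:
    """Expected-gradients attribution of one image against a background set.

    ``background`` is an (n, height, width) stack; the recommended default
    is 20 neutral plus 20 sweep training images.
    """
    image = np.asarray(image, dtype=np.float32)
    background = _as_image_batch(background)
    if background.shape[0] == 0:
        raise InputError("background must be nonempty")
    if image.shape != background.shape[1:]:
        raise InputError(
            f"image shape {image.shape} does not match background {background.shape[1:]}"
        )
    net = model.network()
    n_bg = background.shape[0]
    # midpoint quadrature nodes on (0, 1)
    alphas = (np.arange(steps, dtype=np.float32) + 0.5) / steps
    diffs = image[None] - background  # (n_bg, H, W)
    total = np.zeros_like(image, dtype=np.float64)
    # batch the path points background-sample by background-sample
    for i in range(n_bg):
        points = background[i][None] + alphas[:, None, None] * diffs[i][None]
        grads = net.input_gradient(points)  # (steps, H, W)
        total += diffs[i] * grads.mean(axis=0)
    values = (total / n_bg).astype(np.float32)

    f_x = float(net.predict(image[None])[0])
    f_bg = float(net.predict(background).mean())
    residual = abs(float(values.sum()) - (f_x - f_bg))
    return AttributionMap(
        values=values,
        background_size=n_bg,
        steps=steps,
        completeness_residual=residual,
    )


def average_attribution(
    model: TrainedModel,
    images_by_class: dict[str, np.ndarray],
    background: np.ndarray,
    n_per_class: int = 1000,
    steps: int = DEFAULT_STEPS,
) -> dict[str, AttributionMap]:
    """Element-wise mean attribution maps per class.

    ``images_by_class`` maps class name (e.g. "neutral"/"sweep") to image
    stacks; at most ``n_per_class`` images per class are used.
    """
    out: dict[str, AttributionMap] = {}
    for name, images in images_by_class.items():
        images = _as_image_batch(images)
        if images.shape[0] == 0:
            raise InputError(f"class {name!r} has no images")
        used = images[:n_per_class]
        maps = [attribution_map(model, img, background, steps=steps) for img in used]
        mean_vals = np.mean([m.values for m in maps], axis=0).astype(np.float32)
        out[name] = AttributionMap(
            values=mean_vals,
            background_size=maps[0].background_size,
            steps=steps,
            completeness_residual=float(np.mean([m.completeness_residual for m in maps])),
        )
    return out
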