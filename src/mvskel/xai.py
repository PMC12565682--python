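"""Class-activation-map decision interpretation.

Two variants are provided.  :func:`compute_cam` is the classic formulation:
the final convolutional feature maps are weighted per channel by the final
dense layer's weights for the requested class, summed, rectified, upsampled
to the input size and min-max normalized to [0, 1]; it requires the final
dense layer's input width to equal the conv channel count (e.g. a GAP head).
:func:`gradient_cam` weights channels by the spatial mean of the class
score's gradient with respect to the feature maps instead, which works for
arbitrary head topologies and is what the CLI uses on the hierarchical
models.  Both are deterministic and invariant to positive rescaling of the
class weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform

from .nn import Conv2D, Dense, Sequential

__all__ = ["ActivationMap", "compute_cam", "gradient_cam", "overlay"]


@dataclass(frozen=True)
class ActivationMap:
    """Normalized activation heat map aligned with the input image."""

    grid: np.ndarray  # 2-D, values in [0, 1]
    class_index: int
    layer: str


def _find_layer(model: Sequential, kind, which: str, index: int | None = None) -> int:
    hits = [i for i, l in enumerate(model.layers) if isinstance(l, kind)]
    if not hits:
        raise ValueError(f"model has no {which} layer on the requested path")
    if index is None:
        return hits[-1]
    if index not in hits:
        raise ValueError(f"layer {index} is not a {which} layer (candidates: {hits})")
    return index


def _finalize(raw: np.ndarray, out_shape: tuple[int, int], class_index: int,
              layer: str) -> ActivationMap:
    raw = np.maximum(raw, 0.0)  # rectify: drop negatively-contributing regions
    up = transform.resize(raw, out_shape, order=1, mode="reflect",
                          anti_aliasing=False, preserve_range=True)
    peak = up.max()
    grid = up / peak if peak > 0 else np.zeros_like(up)  # zero-safe
    return ActivationMap(grid=np.clip(grid, 0.0, 1.0), class_index=class_index,
                         layer=layer)


def compute_cam(
    model: Sequential,
    x: np.ndarray,
    class_index: int,
    conv_layer: int | None = None,
) -> ActivationMap:
    """Weighted-sum CAM using the final dense layer's class weights.

    ``x`` is a single input, shape (H, W, C).  The channel weights are the
    final :class:`Dense` layer's column for ``class_index``; its input width
    must equal the conv layer's channel count.
    """
    x = np.asarray(x, dtype=np.float64)[None]
    ci = _find_layer(model, Conv2D, "convolutional", conv_layer)
    di = _find_layer(model, Dense, "dense")
    maps = model.forward_upto(x, ci)[0]  # (h, w, C)
    W = model.layers[di].W
    if W.shape[0] != maps.shape[-1]:
        raise ValueError(
            f"final dense input width ({W.shape[0]}) does not match conv "
            f"channels ({maps.shape[-1]}); use gradient_cam for this head"
        )
    if not 0 <= class_index < W.shape[1]:
        raise ValueError(f"class_index {class_index} out of range for {W.shape[1]} outputs")
    raw = maps @ W[:, class_index]
    return _finalize(raw, x.shape[1:3], class_index, f"conv[{ci}]")


def gradient_cam(
    model: Sequential,
    x: np.ndarray,
    class_index: int,
    conv_layer: int | None = None,
) -> ActivationMap:
    """Gradient-weighted CAM: channel weights are the spatially averaged
    gradients of the class score with respect to the feature maps."""
    x = np.asarray(x, dtype=np.float64)[None]
    ci = _find_layer(model, Conv2D, "convolutional", conv_layer)
    out = model.forward(x, train=False)
    g = np.zeros_like(out)
    g[..., class_index] = 1.0
    grad = model.grad_wrt_layer(x, g, ci)  # d score / d conv output
    maps = model.forward_upto(x, ci)[0]
    weights = grad[0].mean(axis=(0, 1))
    raw = maps @ weights
    return _finalize(raw, x.shape[1:3], class_index, f"conv[{ci}]")


def overlay(
    image: np.ndarray,
    activation_map: ActivationMap | np.ndarray,
    alpha: float = 0.4,
    cmap: str = "inferno",
) -> np.ndarray:
    """Blend a colormapped activation over a grayscale image.

    Returns an (H, W, 3) float RGB image in [0, 1]; ``alpha=0`` reproduces
    the input (replicated to color), ``alpha=1`` the pure colormapped map.
    """
    import matplotlib

    grid = activation_map.grid if isinstance(activation_map, ActivationMap) else np.asarray(activation_map)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape != grid.shape:
        raise ValueError(
            f"image and activation map must be matching 2-D grids, got "
            f"{image.shape} vs {grid.shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    colored = matplotlib.colormaps[cmap](grid)[..., :3]
    gray_rgb = np.repeat(image[..., None], 3, axis=-1)
    return np.clip((1.0 - alpha) * gray_rgb + alpha * colored, 0.0, 1.0)
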