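"""Hierarchical classifier families.

Two families share the same three-level shape — a shared trunk feeds an L1
binary head, the L1 penultimate representation feeds the L2 head (3
independent sigmoid outputs, one per retained anatomical subclass), and the
L2 penultimate feeds the L3 head (10 sigmoid outputs) — but differ in the
trunk and head topology:

* **backbone family**: a convolutional feature extractor (a small trainable
  CNN by default; any module producing a spatial feature map can be plugged
  in) is trained end-to-end with the L1 head (GAP -> dense(32, ReLU) ->
  dense(1, sigmoid)).  The L2/L3 heads reshape their input vector into a
  small 3-D tensor and apply conv -> max-pool -> flatten -> three dense ReLU
  layers with L2 weight decay -> sigmoid outputs.
* **cae family**: a convolutional autoencoder is trained to reconstruct the
  input under MSE; its encoder latent is the shared representation.  L1 is a
  dense sigmoid probe on the latent; the L2/L3 heads are dense-only stacks
  with dropout (no further convolution on already-convolved features).

Lower levels are frozen before a higher level trains, so learned features
are retained bit-exactly while the new head adapts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .nn import (
    Conv2D, Dense, Dropout, FitConfig, Flatten, GlobalAveragePooling,
    MaxPool2, ReLU, Reshape, Sequential, Sigmoid, Upsample2, fit,
)
from .taxonomy import TaxonomyMap

__all__ = [
    "REFERENCE_TRAIN_CONFIGS",
    "CHECKPOINT_SCHEMA_VERSION",
    "CAE",
    "build_cae",
    "train_cae",
    "build_small_backbone",
    "build_l1_backbone_classifier",
    "build_l1_latent_probe",
    "build_l2_head",
    "build_l3_head",
    "extract_combined_features",
    "reshape_dims",
    "HierarchicalModel",
]

CHECKPOINT_SCHEMA_VERSION = 1

#: Recorded full-scale training settings (Adam, BCE, 100 epochs, batch 32,
#: patience 3): per-level learning rates for the backbone family and the
#: single small rate used by the CAE-family heads.  Desk-scale phantom runs
#: use larger rates (see evaluation.ExperimentConfig); these constants are
#: the documented reference configuration.
REFERENCE_TRAIN_CONFIGS: dict[str, dict[int, FitConfig]] = {
    "backbone": {
        1: FitConfig(learning_rate=0.001),
        2: FitConfig(learning_rate=0.0001),
        3: FitConfig(learning_rate=0.00011),
    },
    "cae": {
        1: FitConfig(learning_rate=0.00001),
        2: FitConfig(learning_rate=0.00001),
        3: FitConfig(learning_rate=0.00001),
    },
}


def reshape_dims(n: int) -> tuple[int, int, int]:
    """Smallest square-ish 3-D tensor (h, h, c) with even h for a vector of
    length n (e.g. 32 -> (4, 4, 2))."""
    for h in range(int(np.sqrt(n)) // 2 * 2, 1, -2):
        if n % (h * h) == 0:
            return (h, h, n // (h * h))
    raise ValueError(f"cannot reshape a {n}-vector into an even square-ish tensor")


# ---------------------------------------------------------------------------
# Convolutional autoencoder
# ---------------------------------------------------------------------------

@dataclass
class CAE:
    """Encoder/decoder pair; ``encode`` yields the latent feature map."""

    encoder: Sequential
    decoder: Sequential
    input_shape: tuple[int, int, int]
    latent_shape: tuple[int, int, int]
    trained: bool = False

    @property
    def autoencoder(self) -> Sequential:
        return Sequential([self.encoder, self.decoder])

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(x, train=False)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x, train=train), train=train)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode reconstruction clipped to the [0, 1] image range."""
        return np.clip(self.forward(x, train=False), 0.0, 1.0)


def build_cae(
    input_shape: tuple[int, int, int],
    filters: Sequence[int] = (64, 128),
    seed: int = 0,
) -> CAE:
    """Stacked conv+pool encoder mirrored by a conv+upsample decoder.

    Each filter entry adds one 2x reduction, so the spatial dims must be
    divisible by ``2 ** len(filters)``.  The reference configuration
    (224, 224, 3) with filters (64, 128) gives a 56x56x128 latent; the
    desk-scale (64, 64, 3) with (16, 32) gives 16x16x32.
    """
    h, w, c = input_shape
    factor = 2 ** len(filters)
    if h % factor or w % factor:
        raise ValueError(
            f"spatial dims {h}x{w} not divisible by the pooling chain ({factor}x)"
        )
    rng = np.random.default_rng(seed)
    enc: list[nn.Layer] = []
    c_prev = c
    for f in filters:
        enc += [Conv2D(c_prev, f, rng), ReLU(), MaxPool2()]
        c_prev = f
    dec: list[nn.Layer] = []
    for f in reversed(filters[:-1]):
        dec += [Conv2D(c_prev, f, rng), ReLU(), Upsample2()]
        c_prev = f
    # linear output: with mostly-dark radiographs a sigmoid output saturates
    # under MSE and stalls training; reconstructions are clipped at eval time
    dec += [Conv2D(c_prev, c_prev, rng), ReLU(), Upsample2(),
            Conv2D(c_prev, c, rng)]
    latent = (h // factor, w // factor, filters[-1])
    return CAE(Sequential(enc), Sequential(dec), tuple(input_shape), latent)


def train_cae(
    cae: CAE,
    composites: np.ndarray,
    config: FitConfig = FitConfig(),
    val_composites: np.ndarray | None = None,
    val_fraction: float = 0.2,
) -> nn.History:
    """Train the autoencoder to reconstruct its input under MSE.

    Without an explicit validation set the trailing ``val_fraction`` of a
    seeded shuffle is held out for early stopping.
    """
    X = np.asarray(composites, dtype=nn.DTYPE)
    if len(X) == 0:
        raise ValueError("train_cae requires at least one composite")
    if val_composites is None:
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(X))
        n_val = max(1, int(round(val_fraction * len(X)))) if len(X) > 1 else 0
        if n_val == 0:
            X_tr = X_val = X
        else:
            X_val, X_tr = X[order[:n_val]], X[order[n_val:]]
    else:
        X_tr, X_val = X, np.asarray(val_composites, dtype=nn.DTYPE)
    history = fit(cae.autoencoder, nn.mse_loss, X_tr, X_tr, X_val, X_val, config)
    cae.trained = True
    return history


# ---------------------------------------------------------------------------
# Trunks and heads
# ---------------------------------------------------------------------------

def build_small_backbone(
    c_in: int, filters: Sequence[int] = (8, 16, 32), seed: int = 0
) -> Sequential:
    """Desk-scale trainable CNN trunk: (conv+ReLU+pool)* conv+ReLU."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_prev = c_in
    for f in filters[:-1]:
        layers += [Conv2D(c_prev, f, rng), ReLU(), MaxPool2()]
        c_prev = f
    layers += [Conv2D(c_prev, filters[-1], rng), ReLU()]
    return Sequential(layers)


def build_l1_backbone_classifier(n_channels: int, seed: int = 0,
                                 width: int = 32) -> Sequential:
    """L1 head on a spatial feature map: GAP -> dense(32, ReLU) -> sigmoid(1).

    ``n_channels`` is the trunk feature map's channel count (the GAP output
    width, e.g. 1024 for a 7x7x1024 map).
    """
    rng = np.random.default_rng(seed)
    return Sequential([
        GlobalAveragePooling(),
        Dense(n_channels, width, rng),
        ReLU(),
        Dense(width, 1, rng),
        Sigmoid(),
    ])


def build_l1_latent_probe(latent_shape: tuple[int, int, int], seed: int = 0,
                          width: int = 32) -> Sequential:
    """CAE-family L1: dense sigmoid probe on the flattened encoder latent."""
    rng = np.random.default_rng(seed)
    n = int(np.prod(latent_shape))
    return Sequential([
        Flatten(), Dense(n, width, rng), ReLU(), Dense(width, 1, rng), Sigmoid(),
    ])


def _conv_head(n_in: int, n_out: int, rng: np.random.Generator,
               conv_filters: int = 32, dense_widths: Sequence[int] = (128, 64, 32),
               l2: float = 1e-4) -> Sequential:
    h, w, c = reshape_dims(n_in)
    flat = (h // 2) * (w // 2) * conv_filters
    layers: list[nn.Layer] = [
        Reshape((h, w, c)), Conv2D(c, conv_filters, rng), ReLU(), MaxPool2(), Flatten(),
    ]
    prev = flat
    for d in dense_widths:
        layers += [Dense(prev, d, rng, l2=l2), ReLU()]
        prev = d
    layers += [Dense(prev, n_out, rng), Sigmoid()]
    return Sequential(layers)


def _dense_head(n_in: int, n_out: int, rng: np.random.Generator,
                widths: Sequence[int] = (256, 128), dropout: float = 0.1,
                flatten: bool = False) -> Sequential:
    layers: list[nn.Layer] = [Flatten()] if flatten else []
    prev = n_in
    for d in widths:
        layers += [Dense(prev, d, rng), ReLU(), Dropout(dropout, rng)]
        prev = d
    layers += [Dense(prev, n_out, rng), Sigmoid()]
    return Sequential(layers)


def build_l2_head(penultimate_width: int, family: str, seed: int = 0,
                  n_out: int = 3) -> Sequential:
    """L2 head: 3 independent subclass probabilities (multi-label)."""
    rng = np.random.default_rng(seed)
    if family == "backbone":
        return _conv_head(penultimate_width, n_out, rng)
    if family == "cae":
        # latent feature maps are flattened; no further convolution is
        # applied to already-convolved encoder features
        return _dense_head(penultimate_width, n_out, rng, flatten=True)
    raise ValueError(f"unknown family {family!r}")


def build_l3_head(penultimate_width: int, family: str, seed: int = 0,
                  n_out: int = 10) -> Sequential:
    """L3 head: 10 independent subclass probabilities (multi-label)."""
    rng = np.random.default_rng(seed)
    if family == "backbone":
        return _conv_head(penultimate_width, n_out, rng)
    if family == "cae":
        return _dense_head(penultimate_width, n_out, rng)
    raise ValueError(f"unknown family {family!r}")


def extract_combined_features(
    dv_images: np.ndarray, lat_images: np.ndarray, backbone: Sequential
) -> np.ndarray:
    """Channel-wise concatenation of per-view backbone feature maps."""
    f_dv = backbone.forward(np.asarray(dv_images, dtype=nn.DTYPE), train=False)
    f_lat = backbone.forward(np.asarray(lat_images, dtype=nn.DTYPE), train=False)
    if f_dv.shape[:3] != f_lat.shape[:3]:
        raise ValueError(
            f"incompatible per-view feature maps: {f_dv.shape} vs {f_lat.shape}"
        )
    return np.concatenate([f_dv, f_lat], axis=-1)


# ---------------------------------------------------------------------------
# The chained three-level model
# ---------------------------------------------------------------------------

def _penultimate_index(head: Sequential) -> int:
    """Index of the layer feeding the final Dense->Sigmoid pair."""
    return len(head.layers) - 3


class HierarchicalModel:
    """Chained L1/L2/L3 model with level-wise training and freezing.

    Levels must be trained in order; training a level freezes everything
    below it.  ``predict_hierarchy`` emits 1 + 3 + 10 probabilities; the
    L2+L3 concatenation aligns with the taxonomy's 13-slot label vector.
    """

    def __init__(
        self,
        family: str,
        input_shape: tuple[int, int, int],
        taxonomy: TaxonomyMap,
        seed: int = 0,
        backbone: Sequential | None = None,
        backbone_filters: Sequence[int] = (8, 16, 32),
        cae_filters: Sequence[int] = (16, 32),
        l1_width: int = 32,
    ) -> None:
        if family not in ("backbone", "cae"):
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.input_shape = tuple(input_shape)
        self.taxonomy = taxonomy
        self.seed = seed
        self._meta = {
            "backbone_filters": list(backbone_filters),
            "cae_filters": list(cae_filters),
            "l1_width": l1_width,
        }
        n2, n3 = len(taxonomy.retained_l2), len(taxonomy.retained_l3)
        if family == "backbone":
            self.trunk: Sequential | CAE = backbone or build_small_backbone(
                input_shape[2], backbone_filters, seed=seed
            )
            probe = self.trunk.forward(
                np.zeros((1,) + self.input_shape, dtype=nn.DTYPE), train=False)
            self.l1_head = build_l1_backbone_classifier(
                probe.shape[-1], seed=seed + 1, width=l1_width
            )
        else:
            self.trunk = build_cae(input_shape, cae_filters, seed=seed)
            self.l1_head = build_l1_latent_probe(
                self.trunk.latent_shape, seed=seed + 1, width=l1_width
            )
        self.l2_head = build_l2_head(
            l1_width if family == "backbone" else int(np.prod(self._latent_shape())),
            family, seed=seed + 2, n_out=n2,
        )
        l2_pen = {"backbone": 32, "cae": 128}[family]
        self.l3_head = build_l3_head(l2_pen, family, seed=seed + 3, n_out=n3)
        self.histories: dict[str, nn.History] = {}
        self.trained_levels: set[int] = set()

    # -- feature plumbing ---------------------------------------------------

    def _latent_shape(self) -> tuple[int, int, int]:
        if self.family == "cae":
            return self.trunk.latent_shape
        return (0, 0, 0)

    def _trunk_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=nn.DTYPE)
        if self.family == "cae":
            return self.trunk.encode(X)
        return self.trunk.forward(X, train=False)

    def _l1_penultimate(self, X: np.ndarray) -> np.ndarray:
        """Representation handed to the L2 head (h1 / encoder latent)."""
        feats = self._trunk_features(X)
        if self.family == "backbone":
            return self.l1_head.forward_upto(feats, 2)  # ReLU after dense(32)
        return feats  # CAE: the latent map itself (L2 head flattens it)

    def _l2_penultimate(self, X: np.ndarray) -> np.ndarray:
        h = self._l1_penultimate(X)
        return self.l2_head.forward_upto(h, _penultimate_index(self.l2_head))

    def level_features(self, level: int, X: np.ndarray) -> np.ndarray:
        """Input representation consumed by the given level's head."""
        if level == 1:
            return self._trunk_features(X)
        if level == 2:
            return self._l1_penultimate(X)
        if level == 3:
            return self._l2_penultimate(X)
        raise ValueError(f"level must be 1, 2 or 3, got {level}")

    # -- training -----------------------------------------------------------

    def train_level(
        self,
        level: int,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        config: FitConfig,
        recon_config: FitConfig | None = None,
    ) -> nn.History:
        """Train one level (lower levels must already be trained).

        Inputs are composites/single-view images; targets are the binary
        labels for that level (L1 scalar, L2 3-vector, L3 10-vector).  For
        the CAE family at level 1, the autoencoder is first trained under
        MSE (``recon_config``) and the latent probe then under BCE.
        Everything below the trained level is frozen afterwards.
        """
        if len(X) == 0:
            raise ValueError(f"empty training split for level {level}")
        missing = {l for l in range(1, level) if l not in self.trained_levels}
        if missing:
            raise RuntimeError(f"levels {sorted(missing)} must be trained before {level}")
        y = np.asarray(y, dtype=np.float64)
        y_val = np.asarray(y_val, dtype=np.float64)
        if level == 1:
            if self.family == "cae":
                h_rec = train_cae(self.trunk, X, recon_config or config,
                                  val_composites=X_val)
                self.histories["cae_reconstruction"] = h_rec
                self.trunk.encoder.freeze()
                self.trunk.decoder.freeze()
                feats = self._trunk_features(X)
                feats_val = self._trunk_features(X_val)
                hist = fit(self.l1_head, nn.bce_loss, feats, y.reshape(-1, 1),
                           feats_val, y_val.reshape(-1, 1), config)
            else:
                full = Sequential([self.trunk, self.l1_head])
                hist = fit(full, nn.bce_loss, X, y.reshape(-1, 1),
                           X_val, y_val.reshape(-1, 1), config)
            self.histories["level1"] = hist
            self.trained_levels.add(1)
            return hist
        if level == 2:
            self._freeze_below(2)
            feats = self._l1_penultimate(X)
            feats_val = self._l1_penultimate(X_val)
            hist = fit(self.l2_head, nn.bce_loss, feats, y, feats_val, y_val, config)
            self.histories["level2"] = hist
            self.trained_levels.add(2)
            return hist
        if level == 3:
            self._freeze_below(3)
            feats = self._l2_penultimate(X)
            feats_val = self._l2_penultimate(X_val)
            hist = fit(self.l3_head, nn.bce_loss, feats, y, feats_val, y_val, config)
            self.histories["level3"] = hist
            self.trained_levels.add(3)
            return hist
        raise ValueError(f"level must be 1, 2 or 3, got {level}")

    def _freeze_below(self, level: int) -> None:
        if self.family == "cae":
            self.trunk.encoder.freeze()
            self.trunk.decoder.freeze()
        else:
            self.trunk.freeze()
        self.l1_head.freeze()
        if level >= 3:
            self.l2_head.freeze()

    # -- inference ----------------------------------------------------------

    def predict_hierarchy(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Threshold-free probabilities: (p_l1 (N,), p_l2 (N,3), p_l3 (N,10))."""
        if self.trained_levels != {1, 2, 3}:
            raise RuntimeError(
                f"model not fully trained (levels done: {sorted(self.trained_levels)})"
            )
        X = np.asarray(X, dtype=nn.DTYPE)
        feats = self._trunk_features(X)
        p1 = self.l1_head.forward(feats, train=False).ravel()
        h1 = self._l1_penultimate(X)
        p2 = self.l2_head.forward(h1, train=False)
        z2 = self.l2_head.forward_upto(h1, _penultimate_index(self.l2_head))
        p3 = self.l3_head.forward(z2, train=False)
        return p1, p2, p3

    def l1_path(self) -> Sequential:
        """Flat input->L1-probability layer stack (for activation maps)."""
        trunk_layers = (
            self.trunk.encoder.layers if self.family == "cae" else self.trunk.layers
        )
        return Sequential(list(trunk_layers) + list(self.l1_head.layers))

    def predict_label_vector(self, X: np.ndarray) -> np.ndarray:
        """(N, 13) probabilities aligned with the taxonomy's slot order."""
        _, p2, p3 = self.predict_hierarchy(X)
        return np.concatenate([p2, p3], axis=1)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint all parameters plus a schema-versioned metadata blob."""
        arrays: dict[str, np.ndarray] = {}
        for name, part in self._parts():
            for i, p in enumerate(part.all_params()):
                arrays[f"{name}__{i}"] = p
        meta = {
            "schema_version": CHECKPOINT_SCHEMA_VERSION,
            "family": self.family,
            "input_shape": list(self.input_shape),
            "seed": self.seed,
            "trained_levels": sorted(self.trained_levels),
            **self._meta,
        }
        np.savez(Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    def _parts(self) -> list[tuple[str, Sequential]]:
        parts: list[tuple[str, Sequential]] = []
        if self.family == "cae":
            parts += [("encoder", self.trunk.encoder), ("decoder", self.trunk.decoder)]
        else:
            parts += [("trunk", self.trunk)]
        parts += [("l1", self.l1_head), ("l2", self.l2_head), ("l3", self.l3_head)]
        return parts

    @classmethod
    def load(cls, path: str | Path, taxonomy: TaxonomyMap) -> "HierarchicalModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["schema_version"] != CHECKPOINT_SCHEMA_VERSION:
                raise ValueError(
                    f"checkpoint schema {meta['schema_version']} unsupported "
                    f"(expected {CHECKPOINT_SCHEMA_VERSION})"
                )
            model = cls(
                meta["family"], tuple(meta["input_shape"]), taxonomy,
                seed=meta["seed"],
                backbone_filters=meta["backbone_filters"],
                cae_filters=meta["cae_filters"],
                l1_width=meta["l1_width"],
            )
            for name, part in model._parts():
                params = part.all_params()
                for i, p in enumerate(params):
                    p[...] = data[f"{name}__{i}"]
            model.trained_levels = set(meta["trained_levels"])
            if model.family == "cae" and model.trained_levels:
                model.trunk.trained = True
        return model
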