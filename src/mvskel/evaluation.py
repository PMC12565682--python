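"""Multi-seed single-view vs. multiview evaluation protocol.

For each seed and each view mode (DV, LAT, MV) the curated specimens are
split 70/20/10 (train/validation/test, stratified by the L1 label), a
hierarchical model is trained level by level, and threshold-free per-class
ROC-AUC is computed on the held-out test split — L1 on all test specimens,
L2/L3 on the abnormal test specimens only (matching the training
population).  Per-class AUCs are averaged across seeds (mean and standard
deviation) and per-level means are unweighted averages over classes,
skipping classes that were absent from a test split (flagged as missing,
never imputed).  For the CAE family the report also carries reconstruction
MSE and SSIM on the test split.

View modes select channels of the multiview composite: DV -> channel 0
(mean DV), LAT -> channel 1 (mean LAT), MV -> all three channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.metrics import structural_similarity
from sklearn.model_selection import train_test_split

from .curation import CuratedDataset
from .models import HierarchicalModel
from .nn import FitConfig
from .taxonomy import TaxonomyMap

__all__ = [
    "SplitSpec",
    "ExperimentConfig",
    "MetricsReport",
    "make_splits",
    "roc_auc",
    "per_level_mean_auc",
    "reconstruction_mse",
    "reconstruction_ssim",
    "run_experiment",
    "VIEW_MODE_CHANNELS",
]

logger = logging.getLogger(__name__)

#: Composite channels consumed per view mode.
VIEW_MODE_CHANNELS: dict[str, tuple[int, ...]] = {
    "DV": (0,),
    "LAT": (1,),
    "MV": (0, 1, 2),
}


@dataclass(frozen=True)
class SplitSpec:
    """Split fractions and the seeds of the repeated simulations."""

    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("split seeds must be distinct")


def make_splits(
    l1_labels: Sequence[str],
    spec: SplitSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, L1-stratified index splits (train, val, test)."""
    labels = np.asarray(l1_labels)
    n = len(labels)
    if n < 10:
        raise ValueError(f"need at least 10 specimens to split, got {n}")
    f_train, f_val, f_test = spec.fractions
    idx = np.arange(n)
    try:
        train_idx, rest = train_test_split(
            idx, train_size=f_train, random_state=seed, stratify=labels
        )
        val_idx, test_idx = train_test_split(
            rest, train_size=f_val / (f_val + f_test), random_state=seed,
            stratify=labels[rest],
        )
    except ValueError as err:
        raise ValueError(
            f"stratified split failed ({err}); use a larger dataset"
        ) from err
    for name, part in (("train", train_idx), ("val", val_idx), ("test", test_idx)):
        if len(set(labels[part])) < len(set(labels)):
            raise ValueError(
                f"L1 stratum empty in the {name} split; use a larger dataset"
            )
    return np.sort(train_idx), np.sort(val_idx), np.sort(test_idx)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold-free ROC-AUC via the Mann-Whitney statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    outscores the negative, ties counted 1/2.  Returns NaN (flagged
    missing) when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def per_level_mean_auc(per_class_aucs: Mapping[str, float]) -> tuple[float, int]:
    """Unweighted mean over a level's classes, skipping missing entries.

    Returns (mean, number skipped); the mean is NaN if all are missing.
    """
    vals = np.array(list(per_class_aucs.values()), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("per_level_mean_auc requires at least one class")
    missing = int(np.isnan(vals).sum())
    if missing == vals.size:
        return float("nan"), missing
    return float(np.nanmean(vals)), missing


def reconstruction_mse(x: np.ndarray, x_rec: np.ndarray) -> float:
    """Mean squared per-pixel difference over all pixels."""
    x, x_rec = np.asarray(x, dtype=np.float64), np.asarray(x_rec, dtype=np.float64)
    if x.shape != x_rec.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}")
    return float(np.mean((x - x_rec) ** 2))


def reconstruction_ssim(x: np.ndarray, x_rec: np.ndarray) -> float:
    """Structural similarity (k1=0.01, k2=0.03, unit range, 7x7 window)."""
    x, x_rec = np.asarray(x, dtype=np.float64), np.asarray(x_rec, dtype=np.float64)
    if x.shape != x_rec.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}")
    channel_axis = -1 if x.ndim == 3 else None
    return float(
        structural_similarity(
            x, x_rec, data_range=1.0, win_size=7, K1=0.01, K2=0.03,
            gaussian_weights=False, channel_axis=channel_axis,
        )
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale training settings for the phantom benchmark.

    The recorded full-scale reference settings live in
    ``models.REFERENCE_TRAIN_CONFIGS``; at phantom scale, training from random
    initialization on a few hundred specimens, larger learning rates and a
    tighter CAE epoch cap are used.
    """

    family: str = "cae"
    cae_filters: tuple[int, ...] = (16, 32)
    backbone_filters: tuple[int, ...] = (8, 16, 32)
    recon_learning_rate: float = 2e-3
    recon_epochs: int = 20
    recon_batch_size: int = 8
    head_learning_rate: float = 1e-3
    head_epochs: int = 80
    batch_size: int = 16
    patience: int = 5


@dataclass
class MetricsReport:
    """Across-seed AUC summary per view mode, level and class."""

    per_class: pd.DataFrame   # view_mode, level, class, mean_auc, std_auc, n_missing
    per_level: pd.DataFrame   # view_mode, level, mean_auc, n_classes_skipped
    per_seed: pd.DataFrame    # raw per-seed, per-class AUCs (audit trail)
    reconstruction: pd.DataFrame  # view_mode, mse_mean, mse_std, ssim_mean, ssim_std

    def level_mean(self, view_mode: str, level: int) -> float:
        sel = self.per_level[
            (self.per_level.view_mode == view_mode) & (self.per_level.level == level)
        ]
        return float(sel.mean_auc.iloc[0])

    def to_json(self) -> str:
        import json

        payload = {
            "per_class": self.per_class.to_dict(orient="records"),
            "per_level": self.per_level.to_dict(orient="records"),
            "reconstruction": self.reconstruction.to_dict(orient="records"),
        }
        return json.dumps(payload, default=float, indent=2,
                          allow_nan=True)


def standard_phantom_benchmark(
    phantom_seed: int = 11,
    split_seeds: tuple[int, ...] = (0, 1, 2),
    n_specimens: int = 600,
    config: ExperimentConfig = ExperimentConfig(),
) -> tuple[CuratedDataset, "MetricsReport"]:
    """The standard phantom benchmark: 600 specimens at 64x64, five
    single-view-visible abnormality classes, CAE family, three seeds.

    This is the package's stand-in for a full-scale multiview-versus-
    single-view comparison: the generator's view-visibility contract makes
    single views uninformative for the classes hidden in their orthogonal
    plane, so the multiview composite should dominate at levels 2 and 3.
    """
    from .curation import CurationConfig, curate_dataset
    from .synthetic import PhantomConfig, generate_records
    from .taxonomy import load_taxonomy

    taxonomy = load_taxonomy()
    phantom_cfg = PhantomConfig(
        n_specimens=n_specimens, image_size=(64, 64), abnormal_fraction=0.5,
        seed=phantom_seed,
    )
    records, _ = generate_records(phantom_cfg, taxonomy)
    dataset = curate_dataset(records, taxonomy, CurationConfig(target_size=64))
    report = run_experiment(
        dataset, taxonomy, SplitSpec(seeds=split_seeds), config
    )
    return dataset, report


def _level_targets(dataset: CuratedDataset, taxonomy: TaxonomyMap):
    y1 = np.array([1 if lab.l1 == "abnormal" else 0 for lab in dataset.labels])
    Y = dataset.label_matrix.astype(np.float64)
    n2 = len(taxonomy.retained_l2)
    return y1, Y[:, :n2], Y[:, n2:]


def run_experiment(
    dataset: CuratedDataset,
    taxonomy: TaxonomyMap,
    split_spec: SplitSpec = SplitSpec(),
    config: ExperimentConfig = ExperimentConfig(),
    view_modes: Sequence[str] = ("DV", "LAT", "MV"),
) -> MetricsReport:
    """Train and evaluate the hierarchy per seed and view mode.

    Deterministic for fixed dataset, spec and config: every source of
    randomness (splits, init, shuffling, dropout) derives from the split
    seeds.
    """
    X_all = dataset.X  # float32
    y1, Y2, Y3 = _level_targets(dataset, taxonomy)
    rows = []
    recon_rows = []
    for view_mode in view_modes:
        chans = VIEW_MODE_CHANNELS[view_mode]
        X_mode = X_all[..., list(chans)]
        recon_metrics = {"mse": [], "ssim": []}
        for seed in split_spec.seeds:
            tr, va, te = make_splits([lab.l1 for lab in dataset.labels], split_spec, seed)
            model = HierarchicalModel(
                config.family,
                X_mode.shape[1:],
                taxonomy,
                seed=seed,
                backbone_filters=config.backbone_filters,
                cae_filters=config.cae_filters,
            )
            head_cfg = FitConfig(
                learning_rate=config.head_learning_rate, epochs=config.head_epochs,
                batch_size=config.batch_size, patience=config.patience, seed=seed,
            )
            recon_cfg = FitConfig(
                learning_rate=config.recon_learning_rate, epochs=config.recon_epochs,
                batch_size=config.recon_batch_size, patience=config.patience,
                seed=seed,
            )
            model.train_level(1, X_mode[tr], y1[tr], X_mode[va], y1[va],
                              head_cfg, recon_config=recon_cfg)
            ab_tr, ab_va = tr[y1[tr] == 1], va[y1[va] == 1]
            if len(ab_tr) == 0 or len(ab_va) == 0:
                raise ValueError("no abnormal specimens in a split; use a larger dataset")
            model.train_level(2, X_mode[ab_tr], Y2[ab_tr], X_mode[ab_va], Y2[ab_va],
                              head_cfg)
            model.train_level(3, X_mode[ab_tr], Y3[ab_tr], X_mode[ab_va], Y3[ab_va],
                              head_cfg)

            p1, p2, p3 = model.predict_hierarchy(X_mode[te])
            rows.append({"view_mode": view_mode, "seed": seed, "level": 1,
                         "class": "Binary", "auc": roc_auc(p1, y1[te])})
            ab_te_mask = y1[te] == 1
            for j, cls in enumerate(taxonomy.retained_l2):
                rows.append({"view_mode": view_mode, "seed": seed, "level": 2,
                             "class": cls,
                             "auc": roc_auc(p2[ab_te_mask, j], Y2[te][ab_te_mask, j])})
            for j, cls in enumerate(taxonomy.retained_l3):
                rows.append({"view_mode": view_mode, "seed": seed, "level": 3,
                             "class": cls,
                             "auc": roc_auc(p3[ab_te_mask, j], Y3[te][ab_te_mask, j])})
            if config.family == "cae":
                rec = model.trunk.reconstruct(X_mode[te])
                recon_metrics["mse"].append(
                    np.mean([reconstruction_mse(a, b) for a, b in zip(X_mode[te], rec)])
                )
                recon_metrics["ssim"].append(
                    np.mean([reconstruction_ssim(a, b) for a, b in zip(X_mode[te], rec)])
                )
            logger.info("evaluated view_mode=%s seed=%d", view_mode, seed)
        if config.family == "cae":
            recon_rows.append({
                "view_mode": view_mode,
                "mse_mean": float(np.mean(recon_metrics["mse"])),
                "mse_std": float(np.std(recon_metrics["mse"])),
                "ssim_mean": float(np.mean(recon_metrics["ssim"])),
                "ssim_std": float(np.std(recon_metrics["ssim"])),
            })

    per_seed = pd.DataFrame(rows)
    agg = []
    for (view_mode, level, cls), grp in per_seed.groupby(
        ["view_mode", "level", "class"], sort=False
    ):
        vals = grp.auc.to_numpy()
        agg.append({
            "view_mode": view_mode, "level": level, "class": cls,
            "mean_auc": float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan"),
            "std_auc": float(np.nanstd(vals)) if not np.all(np.isnan(vals)) else float("nan"),
            "n_missing": int(np.isnan(vals).sum()),
        })
    per_class = pd.DataFrame(agg)
    lvl_rows = []
    for (view_mode, level), grp in per_class.groupby(["view_mode", "level"], sort=False):
        mean, skipped = per_level_mean_auc(dict(zip(grp["class"], grp["mean_auc"])))
        lvl_rows.append({"view_mode": view_mode, "level": level,
                         "mean_auc": mean, "n_classes_skipped": skipped})
    per_level = pd.DataFrame(lvl_rows)
    recon = pd.DataFrame(
        recon_rows, columns=["view_mode", "mse_mean", "mse_std", "ssim_mean", "ssim_std"]
    )
    return MetricsReport(per_class, per_level, per_seed, recon)
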