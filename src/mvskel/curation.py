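"""Specimen-wise multiview composite construction.

A specimen is represented by a single 3-channel image built from all of its
full-body radiographs: channel 0 is the pixel-wise mean of its dorsoventral
(DV) acquisitions, channel 1 the mean of its lateral (LAT) acquisitions, and
channel 2 a weighted blend of the Canny edge maps of those two means (DV
slightly favoured, since coronal anatomy is the easier to read).  Averaging
repeated acquisitions suppresses acquisition noise while keeping anatomy;
the edge channel injects explicit structural cues from both projections
into one plane.

Pipeline order: quality filter -> resize/normalize -> group by specimen
(discarding non-full-body views and specimens missing either view) -> mean
per view -> Canny -> small-component cleaning -> weighted blend -> stack.
The whole pipeline is deterministic for fixed inputs and config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import feature, morphology, transform

from .taxonomy import SpecimenLabel, TaxonomyMap, specimen_union

__all__ = [
    "VIEW_DV",
    "VIEW_LAT",
    "VIEW_OTHER",
    "ImageRecord",
    "MultiviewComposite",
    "CurationConfig",
    "CuratedDataset",
    "filter_images",
    "resize_normalize",
    "group_by_specimen",
    "mean_view",
    "canny_edge_map",
    "clean_edge_map",
    "blend_edges",
    "compose_multiview",
    "curate_dataset",
    "is_full_body_view",
    "full_body_totals",
]

logger = logging.getLogger(__name__)

VIEW_DV = "DV"
VIEW_LAT = "LAT"
VIEW_OTHER = "OTHER"


@dataclass
class ImageRecord:
    """One grayscale radiograph with its specimen/view metadata.

    ``pixels`` holds intensities in [0, 1]; ``codes`` carries the image-level
    expert abnormality codes (empty for a normal image).
    """

    specimen_id: str
    view: str
    pixels: np.ndarray
    codes: frozenset[str] = frozenset()
    source_center: str | None = None
    original_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale image, got shape {self.pixels.shape}")
        if self.original_size is None:
            self.original_size = self.pixels.shape
        if self.view not in (VIEW_DV, VIEW_LAT, VIEW_OTHER):
            raise ValueError(f"unknown view {self.view!r}")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < 0.0 or hi > 1.0 + 1e-9:
            raise ValueError(f"intensities must lie in [0,1], got range [{lo}, {hi}]")


@dataclass(frozen=True)
class MultiviewComposite:
    """3-channel specimen representation: (mean DV, mean LAT, edge blend)."""

    specimen_id: str
    channels: np.ndarray  # (H, W, 3), values in [0, 1]
    provenance: Mapping[str, int] = field(default_factory=dict)  # images per view


@dataclass(frozen=True)
class CurationConfig:
    """Tunable curation parameters.

    ``target_size`` is the square output resolution (224 for full scale;
    the phantom benchmarks use 64).  Canny thresholds act on [0, 1]
    intensities.  ``w_dv`` is the DV weight in the edge blend (the LAT
    weight is its complement).  Edge components smaller than
    ``min_edge_component`` pixels (8-connectivity) are removed.
    """

    target_size: int = 224
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.2
    w_dv: float = 0.6
    min_edge_component: int = 10
    intensity_k: float = 3.0
    aspect_band: tuple[float, float] = (0.3, 3.3)


def filter_images(
    records: Sequence[ImageRecord],
    config: CurationConfig = CurationConfig(),
) -> tuple[list[ImageRecord], list[dict]]:
    """Quality filter: drop intensity outliers and bad fields of view.

    Rule (a): an image whose mean intensity falls outside mean +/- k*std of
    its per-view cohort is rejected.  Rule (b): an image whose width/height
    aspect ratio falls outside the configured band is rejected.  Every
    rejection is logged with the rule that fired.
    """
    rejections: list[dict] = []
    kept: list[ImageRecord] = []
    means = {}
    by_view: dict[str, list[float]] = {}
    for rec in records:
        m = float(rec.pixels.mean())
        means[id(rec)] = m
        by_view.setdefault(rec.view, []).append(m)
    stats = {
        v: (float(np.mean(ms)), float(np.std(ms))) for v, ms in by_view.items()
    }
    lo_ar, hi_ar = config.aspect_band
    for rec in records:
        rows, cols = rec.original_size
        aspect = cols / rows
        mu, sigma = stats[rec.view]
        if sigma > 0 and abs(means[id(rec)] - mu) > config.intensity_k * sigma:
            rejections.append(
                {"specimen_id": rec.specimen_id, "view": rec.view,
                 "rule": "intensity_outlier",
                 "detail": f"mean {means[id(rec)]:.4f} outside "
                           f"[{mu - config.intensity_k * sigma:.4f}, "
                           f"{mu + config.intensity_k * sigma:.4f}]"}
            )
            continue
        if not (lo_ar <= aspect <= hi_ar):
            rejections.append(
                {"specimen_id": rec.specimen_id, "view": rec.view,
                 "rule": "field_of_view",
                 "detail": f"aspect ratio {aspect:.3f} outside [{lo_ar}, {hi_ar}]"}
            )
            continue
        kept.append(rec)
    return kept, rejections


def resize_normalize(record: ImageRecord, target_size: int = 224) -> ImageRecord:
    """Bilinear resize to a square grid, then min-max normalize to [0, 1].

    A constant image maps to all zeros.  Degenerate (single-row/column)
    inputs are rejected.
    """
    if min(record.pixels.shape) < 2:
        raise ValueError(
            f"image for specimen {record.specimen_id!r} is degenerate "
            f"(shape {record.pixels.shape})"
        )
    out = transform.resize(
        record.pixels, (target_size, target_size), order=1,
        mode="reflect", anti_aliasing=True, preserve_range=True,
    )
    lo, hi = out.min(), out.max()
    out = np.zeros_like(out) if hi <= lo else (out - lo) / (hi - lo)
    return replace(record, pixels=np.clip(out, 0.0, 1.0))


def group_by_specimen(
    records: Sequence[ImageRecord],
) -> tuple[dict[str, dict[str, list[ImageRecord]]], list[dict]]:
    """Group full-body records per specimen; drop OTHER views.

    Specimens missing either the DV or the LAT view cannot form a multiview
    composite; they are excluded and logged.
    """
    groups: dict[str, dict[str, list[ImageRecord]]] = {}
    for rec in records:
        if rec.view == VIEW_OTHER:
            continue
        groups.setdefault(rec.specimen_id, {VIEW_DV: [], VIEW_LAT: []})[rec.view].append(rec)
    excluded = []
    for sid in list(groups):
        missing = [v for v in (VIEW_DV, VIEW_LAT) if not groups[sid][v]]
        if missing:
            excluded.append({"specimen_id": sid, "reason": f"missing view(s) {missing}"})
            del groups[sid]
    return groups, excluded


def mean_view(images: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise arithmetic mean of same-shaped images (>= 1)."""
    if not len(images):
        raise ValueError("mean_view requires at least one image")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"mean_view requires identical shapes, got {sorted(shapes)}")
    return np.mean(np.stack([np.asarray(im, dtype=np.float64) for im in images]), axis=0)


def canny_edge_map(
    image: np.ndarray,
    sigma: float = 1.0,
    low_threshold: float = 0.1,
    high_threshold: float = 0.2,
) -> np.ndarray:
    """Binary Canny edge map (Gaussian smoothing, NMS, hysteresis).

    Returned as a {0, 1} float array.  Thresholds apply to [0, 1]
    intensities and must satisfy low < high.
    """
    if low_threshold >= high_threshold:
        raise ValueError(
            f"canny low threshold ({low_threshold}) must be < high ({high_threshold})"
        )
    edges = feature.canny(
        np.asarray(image, dtype=np.float64), sigma=sigma,
        low_threshold=low_threshold, high_threshold=high_threshold,
    )
    return edges.astype(np.float64)


def clean_edge_map(edges: np.ndarray, min_size: int = 10) -> np.ndarray:
    """Drop connected edge components below ``min_size`` px (8-connectivity)."""
    if min_size <= 1:
        return np.asarray(edges, dtype=np.float64)
    # remove components of size < min_size (i.e. <= min_size - 1)
    cleaned = morphology.remove_small_objects(
        np.asarray(edges) > 0.5, max_size=min_size - 1, connectivity=2
    )
    return cleaned.astype(np.float64)


def blend_edges(dv_edges: np.ndarray, lat_edges: np.ndarray, w_dv: float = 0.6) -> np.ndarray:
    """Convex combination ``w_dv * dv + (1 - w_dv) * lat``, clipped to [0, 1]."""
    dv_edges = np.asarray(dv_edges, dtype=np.float64)
    lat_edges = np.asarray(lat_edges, dtype=np.float64)
    if dv_edges.shape != lat_edges.shape:
        raise ValueError(
            f"edge map shapes differ: {dv_edges.shape} vs {lat_edges.shape}"
        )
    if not 0.0 <= w_dv <= 1.0:
        raise ValueError(f"w_dv must lie in [0, 1], got {w_dv}")
    return np.clip(w_dv * dv_edges + (1.0 - w_dv) * lat_edges, 0.0, 1.0)


def compose_multiview(
    mean_dv: np.ndarray,
    mean_lat: np.ndarray,
    edge_blend: np.ndarray,
    specimen_id: str,
    provenance: Mapping[str, int] | None = None,
) -> MultiviewComposite:
    """Stack (mean DV, mean LAT, edge blend) into the 3-channel composite."""
    planes = [np.asarray(p, dtype=np.float64) for p in (mean_dv, mean_lat, edge_blend)]
    shapes = {p.shape for p in planes}
    if len(shapes) != 1 or planes[0].ndim != 2:
        raise ValueError(f"channels must be identically-shaped 2-D grids, got {shapes}")
    for name, p in zip(("mean_dv", "mean_lat", "edge_blend"), planes):
        if p.min() < 0.0 or p.max() > 1.0 + 1e-9:
            raise ValueError(f"channel {name} out of [0,1] range")
    return MultiviewComposite(
        specimen_id=specimen_id,
        channels=np.stack(planes, axis=-1),
        provenance=dict(provenance or {}),
    )


@dataclass
class CuratedDataset:
    """Aligned composites and specimen labels, plus curation logs."""

    specimen_ids: list[str]
    composites: list[MultiviewComposite]
    labels: list[SpecimenLabel]
    rejections: list[dict] = field(default_factory=list)
    exclusions: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.specimen_ids)

    @property
    def X(self) -> np.ndarray:
        """(N, H, W, 3) stack of composite channels."""
        return np.stack([c.channels for c in self.composites]).astype(np.float32)

    @property
    def label_matrix(self) -> np.ndarray:
        """(N, 13) binary label vectors."""
        return np.array([lab.vector for lab in self.labels], dtype=np.int8)


def curate_dataset(
    records: Sequence[ImageRecord],
    taxonomy: TaxonomyMap,
    config: CurationConfig = CurationConfig(),
) -> CuratedDataset:
    """Run the full curation pipeline on image records.

    Returns composites plus hierarchical specimen labels (the union of the
    image-level code sets of each specimen's kept full-body images).
    """
    kept, rejections = filter_images(records, config)
    resized = [resize_normalize(r, config.target_size) for r in kept]
    groups, exclusions = group_by_specimen(resized)
    ids, composites, labels = [], [], []
    for sid in sorted(groups):
        views = groups[sid]
        means = {
            v: mean_view([r.pixels for r in views[v]]) for v in (VIEW_DV, VIEW_LAT)
        }
        edges = {
            v: clean_edge_map(
                canny_edge_map(
                    means[v], config.canny_sigma, config.canny_low, config.canny_high
                ),
                config.min_edge_component,
            )
            for v in (VIEW_DV, VIEW_LAT)
        }
        blend = blend_edges(edges[VIEW_DV], edges[VIEW_LAT], config.w_dv)
        composite = compose_multiview(
            means[VIEW_DV], means[VIEW_LAT], blend, sid,
            provenance={v: len(views[v]) for v in (VIEW_DV, VIEW_LAT)},
        )
        image_codes = [r.codes for v in (VIEW_DV, VIEW_LAT) for r in views[v]]
        labels.append(specimen_union(image_codes, sid, taxonomy))
        ids.append(sid)
        composites.append(composite)
    logger.info(
        "curated %d specimens (%d image rejections, %d specimen exclusions)",
        len(ids), len(rejections), len(exclusions),
    )
    return CuratedDataset(ids, composites, labels, rejections, exclusions)


def is_full_body_view(view_label: str) -> bool:
    """True for whole-body view labels (e.g. 'Full body-DV'), false for
    region views (skull, forelimbs, hindlimbs)."""
    return view_label.strip().lower().startswith("full body")


def full_body_totals(
    view_table: pd.DataFrame,
    view_col: str = "view",
    image_col: str = "n_images",
    abnormality_col: str = "n_abnormalities",
) -> dict[str, int]:
    """Apply the full-body-views-only selection to a per-view count table.

    Returns the retained image and retained abnormality totals — the
    specimen-representation subset used for multiview analysis.
    """
    mask = view_table[view_col].map(is_full_body_view)
    sel = view_table[mask]
    return {
        "n_images": int(sel[image_col].sum()),
        "n_abnormalities": int(sel[abnormality_col].sum()),
        "n_views": int(mask.sum()),
    }
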