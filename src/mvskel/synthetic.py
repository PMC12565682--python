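"""Phantom mouse-skeleton radiograph generator.

Produces paired dorsoventral (DV, coronal projection) and lateral (LAT,
sagittal projection) renders of a stylized skeleton phantom, with injected,
hierarchically labelled abnormalities.  The generator emulates the
*structure* of multi-center phenotyping image data — two full-body views
per specimen, repeated acquisitions, class imbalance, co-occurring
abnormalities, per-center brightness jitter — not mouse anatomy or X-ray
physics.

The phantom lives in a simple 3-D coordinate frame: ``u`` runs along the
body axis (rows), ``x`` is the lateral offset (visible in DV columns) and
``z`` the dorsoventral offset (visible in LAT columns).  Each abnormality
class is a deterministic geometric edit with a declared view visibility;
classes edited only in the coronal plane are pixel-invisible in the
noiseless LAT render and vice versa.  That contract is what makes the
multiview-versus-single-view comparison testable: a single view is
uninformative for the classes hidden in its orthogonal plane.

Edits per level-3 class
-----------------------
========== ============================================== ==========
class      geometric edit                                 visibility
========== ============================================== ==========
Cervical   sagittal displacement of cervical vertebrae    LAT only
Thoracic   coronal displacement of thoracic vertebrae     DV only
Lumbar     sagittal displacement of lumbar vertebrae      LAT only
Caudal     truncated caudal vertebral series              both
Morphology increased stroke width (bone thickening)       both
Shape      global body-axis compression                   both
Fusion     merged adjacent rib arcs                       DV only
Joints     forelimb/hindlimb joint gap                    DV only
Other      dense pelvic blob                              both
Digits     fused forepaw digits                           DV only
========== ============================================== ==========

Additional code-level edits ``kyphosis`` (smooth sagittal spine arc, LAT
only) and ``scoliosis`` (smooth coronal arc, DV only) are available through
:func:`inject_code`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .curation import VIEW_DV, VIEW_LAT, ImageRecord
from .taxonomy import SpecimenLabel, TaxonomyMap, specimen_union

__all__ = [
    "GENERATOR_CODES",
    "VIEW_VISIBILITY",
    "PhantomConfig",
    "SkeletonPhantom",
    "normal_phantom",
    "inject_abnormality",
    "inject_code",
    "sample_abnormality_classes",
    "sample_phantom",
    "render_view",
    "generate_records",
    "generate_dataset",
    "expected_conditional_prevalence",
]

#: Abnormality code emitted for each injectable level-3 class.  All codes
#: exist in the bundled default taxonomy with the matching l3 tag.
GENERATOR_CODES: dict[str, str] = {
    "Cervical": "vertebral-displacement-cervical",
    "Thoracic": "vertebral-displacement-thoracic",
    "Lumbar": "vertebral-displacement-lumbar",
    "Caudal": "caudal-truncation",
    "Morphology": "spine-morphology",
    "Shape": "spine-shape",
    "Fusion": "rib-fusion",
    "Joints": "joint-gap",
    "Other": "pelvis-anomaly",
    "Digits": "syndactylism",
}

#: Views in which each class's edit is visible (the renderer guarantees
#: pixel-identity in the orthogonal view for single-view classes).
VIEW_VISIBILITY: dict[str, tuple[str, ...]] = {
    "Cervical": (VIEW_LAT,),
    "Thoracic": (VIEW_DV,),
    "Lumbar": (VIEW_LAT,),
    "Caudal": (VIEW_DV, VIEW_LAT),
    "Morphology": (VIEW_DV, VIEW_LAT),
    "Shape": (VIEW_DV, VIEW_LAT),
    "Fusion": (VIEW_DV,),
    "Joints": (VIEW_DV,),
    "Other": (VIEW_DV, VIEW_LAT),
    "Digits": (VIEW_DV,),
}

_N_CERVICAL, _N_THORACIC, _N_LUMBAR = 5, 10, 5
_N_SPINE = _N_CERVICAL + _N_THORACIC + _N_LUMBAR
_TAIL_FULL = 12


def _default_prevalence() -> dict[str, float]:
    # Moderate, roughly uniform co-occurrence probabilities; Digits is kept
    # rare (its Limbs parent is excluded from the modelled label bits, so it
    # only exercises the L1-only pathway).
    prev = {cls: 0.22 for cls in GENERATOR_CODES}
    prev["Digits"] = 0.05
    return prev


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings (the emulated study conditions).

    ``abnormal_fraction`` is the probability a specimen carries at least one
    injected abnormality; given abnormal, each class is drawn independently
    with its ``class_prevalence`` (resampling the rare all-empty draw).
    ``center_jitter`` is the multiplicative brightness perturbation scale
    emulating between-center acquisition differences; ``noise_sigma`` the
    additive Gaussian noise per acquisition.
    """

    n_specimens: int = 100
    image_size: tuple[int, int] = (128, 128)
    abnormal_fraction: float = 0.3
    class_prevalence: Mapping[str, float] = field(default_factory=_default_prevalence)
    acquisitions_per_view: tuple[int, int] = (1, 3)
    center_jitter: float = 0.15
    noise_sigma: float = 0.02
    blur_sigma: float = 0.7
    stroke: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must lie in [0, 1]")
        for cls, p in self.class_prevalence.items():
            if cls not in GENERATOR_CODES:
                raise ValueError(f"unknown abnormality class {cls!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {cls!r} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class SkeletonPhantom:
    """Parametric skeleton geometry (normalized body coordinates).

    ``coronal_offsets``/``sagittal_offsets`` displace each of the 20 main
    vertebrae in the x (DV) and z (LAT) planes respectively.  A normal
    phantom has near-zero offsets and the full caudal count.
    """

    coronal_offsets: tuple[float, ...]
    sagittal_offsets: tuple[float, ...]
    tail_n: int = _TAIL_FULL
    stroke_width: float = 1.0
    y_scale: float = 1.0
    skull: tuple[float, float, float] = (0.09, 0.050, 0.042)  # (center u, ru, rx)
    rib_merge: bool = False
    joint_gap: float = 0.0
    digit_fused: bool = False
    pelvis_blob: bool = False

    def __post_init__(self) -> None:
        if len(self.coronal_offsets) != _N_SPINE or len(self.sagittal_offsets) != _N_SPINE:
            raise ValueError(f"expected {_N_SPINE} vertebral offsets per plane")
        if not 0 <= self.tail_n <= _TAIL_FULL:
            raise ValueError(f"tail_n must lie in [0, {_TAIL_FULL}]")


def normal_phantom(rng: np.random.Generator | None = None) -> SkeletonPhantom:
    """A normal phantom, with mild benign geometric variation if ``rng``."""
    if rng is None:
        cor = sag = (0.0,) * _N_SPINE
        stroke = 1.0
        skull = (0.09, 0.050, 0.042)
    else:
        t = np.linspace(0, np.pi, _N_SPINE)
        cor = tuple(0.006 * rng.normal() * np.sin(t + rng.uniform(0, np.pi)))
        sag = tuple(0.006 * rng.normal() * np.sin(t + rng.uniform(0, np.pi)))
        stroke = float(1.0 + 0.1 * rng.uniform(-1, 1))
        skull = (0.09, 0.050 * (1 + 0.08 * rng.uniform(-1, 1)),
                 0.042 * (1 + 0.08 * rng.uniform(-1, 1)))
    return SkeletonPhantom(coronal_offsets=cor, sagittal_offsets=sag,
                           stroke_width=stroke, skull=skull)


def _bump(n: int, amplitude: float) -> np.ndarray:
    return amplitude * np.sin(np.pi * np.linspace(0.1, 0.9, n))


def inject_abnormality(phantom: SkeletonPhantom, l3_class: str) -> SkeletonPhantom:
    """Apply the deterministic geometric edit for a level-3 class."""
    cor = np.array(phantom.coronal_offsets)
    sag = np.array(phantom.sagittal_offsets)
    c0, c1 = 0, _N_CERVICAL
    t0, t1 = _N_CERVICAL, _N_CERVICAL + _N_THORACIC
    l0, l1 = t1, _N_SPINE
    if l3_class == "Cervical":
        sag[c0:c1] += _bump(c1 - c0, 0.055)
        return replace(phantom, sagittal_offsets=tuple(sag))
    if l3_class == "Thoracic":
        cor[t0:t1] += _bump(t1 - t0, 0.055)
        return replace(phantom, coronal_offsets=tuple(cor))
    if l3_class == "Lumbar":
        sag[l0:l1] += _bump(l1 - l0, 0.055)
        return replace(phantom, sagittal_offsets=tuple(sag))
    if l3_class == "Caudal":
        return replace(phantom, tail_n=5)
    if l3_class == "Morphology":
        return replace(phantom, stroke_width=phantom.stroke_width * 1.9)
    if l3_class == "Shape":
        return replace(phantom, y_scale=phantom.y_scale * 0.82)
    if l3_class == "Fusion":
        return replace(phantom, rib_merge=True)
    if l3_class == "Joints":
        return replace(phantom, joint_gap=0.035)
    if l3_class == "Other":
        return replace(phantom, pelvis_blob=True)
    if l3_class == "Digits":
        return replace(phantom, digit_fused=True)
    raise ValueError(f"unknown abnormality class {l3_class!r}")


def inject_code(phantom: SkeletonPhantom, code: str) -> SkeletonPhantom:
    """Code-level edits beyond the canonical per-class ones."""
    if code == "kyphosis":  # smooth sagittal arc over the whole spine
        sag = np.array(phantom.sagittal_offsets) + _bump(_N_SPINE, 0.06)
        return replace(phantom, sagittal_offsets=tuple(sag))
    if code == "scoliosis":  # smooth coronal S-curve
        t = np.linspace(0, 2 * np.pi, _N_SPINE)
        cor = np.array(phantom.coronal_offsets) + 0.05 * np.sin(t)
        return replace(phantom, coronal_offsets=tuple(cor))
    inv = {v: k for k, v in GENERATOR_CODES.items()}
    if code in inv:
        return inject_abnormality(phantom, inv[code])
    raise ValueError(f"no geometric edit defined for code {code!r}")


def sample_abnormality_classes(
    config: PhantomConfig, rng: np.random.Generator
) -> set[str]:
    """Independent per-class draws, resampled until at least one class."""
    classes = sorted(config.class_prevalence)
    probs = np.array([config.class_prevalence[c] for c in classes])
    if not np.any(probs > 0):
        raise ValueError("at least one class prevalence must be positive")
    while True:
        hits = rng.random(len(classes)) < probs
        if hits.any():
            return {c for c, h in zip(classes, hits) if h}


def expected_conditional_prevalence(config: PhantomConfig) -> dict[str, float]:
    """Exact per-class frequency among abnormal specimens.

    The sampler rejects the all-empty draw, so the marginal frequency of
    class c among abnormal specimens is p_c / (1 - prod_j(1 - p_j)).
    """
    probs = np.array(list(config.class_prevalence.values()))
    norm = 1.0 - np.prod(1.0 - probs)
    return {c: p / norm for c, p in config.class_prevalence.items()}


def sample_phantom(
    config: PhantomConfig, rng: np.random.Generator
) -> tuple[SkeletonPhantom, frozenset[str]]:
    """Draw one phantom and its ground-truth abnormality code set."""
    phantom = normal_phantom(rng)
    codes: set[str] = set()
    if rng.random() < config.abnormal_fraction:
        for cls in sorted(sample_abnormality_classes(config, rng)):
            phantom = inject_abnormality(phantom, cls)
            codes.add(GENERATOR_CODES[cls])
    return phantom, frozenset(codes)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _stamp(canvas: np.ndarray, r: float, c: float, radius: float, value: float = 1.0) -> None:
    rr, cc = draw.disk((r, c), max(radius, 0.8), shape=canvas.shape)
    canvas[rr, cc] = np.maximum(canvas[rr, cc], value)


def _stroke(canvas, p0, p1, radius, value=1.0):
    # stamp disks along the segment at sub-pixel spacing
    n = max(2, int(np.hypot(p1[0] - p0[0], p1[1] - p0[1]) / 0.7) + 1)
    for t in np.linspace(0.0, 1.0, n):
        _stamp(canvas, p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1]),
               radius, value)


def _spine_u() -> np.ndarray:
    return np.linspace(0.17, 0.70, _N_SPINE)


def _tail_u() -> np.ndarray:
    return np.linspace(0.73, 0.95, _TAIL_FULL)


def render_view(
    phantom: SkeletonPhantom,
    view: str,
    config: PhantomConfig = PhantomConfig(),
    rng: np.random.Generator | None = None,
    specimen_id: str = "phantom",
) -> ImageRecord:
    """Rasterize one projection: bright strokes on a dark background.

    DV projects the coronal plane (ribs, limbs, digits drawn here); LAT the
    sagittal plane (spine profile, skull, tail).  After rasterization a
    Gaussian blur, multiplicative brightness jitter (center effect) and
    additive Gaussian noise are applied; the last two need ``rng`` and are
    skipped without one, making the render deterministic.
    """
    if view not in (VIEW_DV, VIEW_LAT):
        raise ValueError(f"view must be DV or LAT, got {view!r}")
    H, W = config.image_size
    canvas = np.zeros((H, W), dtype=np.float64)
    stroke = phantom.stroke_width * config.stroke * max(H, W) / 96.0

    def pt(u: float, off: float) -> tuple[float, float]:
        row = (0.5 + (u - 0.5) * phantom.y_scale) * (H - 1)
        return row, (0.5 + off) * (W - 1)

    offsets = phantom.coronal_offsets if view == VIEW_DV else phantom.sagittal_offsets
    spine_u = _spine_u()
    pts = [pt(u, off) for u, off in zip(spine_u, offsets)]
    for p0, p1 in zip(pts[:-1], pts[1:]):
        _stroke(canvas, p0, p1, 0.6 * stroke)
    for p in pts:
        _stamp(canvas, *p, 1.25 * stroke)

    # skull: ellipse outline around the cranial end
    su, ru, rx = phantom.skull
    sc_r, sc_c = pt(su, 0.0)
    rr, cc = draw.ellipse_perimeter(
        int(round(sc_r)), int(round(sc_c)),
        max(1, int(round(ru * phantom.y_scale * (H - 1)))),
        max(1, int(round(rx * (W - 1)))), shape=(H, W),
    )
    for r_, c_ in zip(rr, cc):
        _stamp(canvas, float(r_), float(c_), 0.55 * stroke)

    # tail: caudal vertebrae continuing the spine, gently curved
    tail_u = _tail_u()
    tail_curve = 0.03 * np.sin(np.linspace(0, np.pi, _TAIL_FULL))
    base_off = offsets[-1]
    for i in range(phantom.tail_n):
        r_, c_ = pt(tail_u[i], base_off * (1 - i / _TAIL_FULL) + tail_curve[i])
        _stamp(canvas, r_, c_, 0.75 * stroke)

    if view == VIEW_DV:
        # rib arcs on the thoracic vertebrae
        arcs: dict[int, list[list[tuple[float, float]]]] = {-1: [], 1: []}
        for idx in range(_N_CERVICAL, _N_CERVICAL + _N_THORACIC):
            u0, off0 = spine_u[idx], offsets[idx]
            for side in (-1, 1):
                arc = [
                    pt(u0 + 0.030 * t ** 1.4, off0 + side * (0.035 + 0.155 * t))
                    for t in np.linspace(0.0, 1.0, 6)
                ]
                for p0, p1 in zip(arc[:-1], arc[1:]):
                    _stroke(canvas, p0, p1, 0.5 * stroke)
                arcs[side].append(arc)
        if phantom.rib_merge:
            # fuse adjacent arcs: bony webbing bridges mid-arc and tip
            for side in (-1, 1):
                for a0, a1 in zip(arcs[side][:-1], arcs[side][1:]):
                    _stroke(canvas, a0[2], a1[2], 0.7 * stroke)
                    _stroke(canvas, a0[-1], a1[-1], 0.7 * stroke)

        # limbs: two-segment fore/hind limbs with optional joint gap
        gap = phantom.joint_gap
        limbs = [
            ((0.24, 0.05), (0.31, 0.18), (0.27, 0.30)),   # forelimb
            ((0.68, 0.05), (0.76, 0.18), (0.82, 0.28)),   # hindlimb
        ]
        for (u_a, x_a), (u_j, x_j), (u_b, x_b) in limbs:
            for side in (-1, 1):
                a, j, b = (pt(u_a, side * x_a), pt(u_j, side * x_j), pt(u_b, side * x_b))
                if gap > 0:
                    s = gap / max(np.hypot(*(np.subtract(j, a))) / (H - 1), 1e-9)
                    j_a = (a[0] + (j[0] - a[0]) * (1 - s), a[1] + (j[1] - a[1]) * (1 - s))
                    s2 = gap / max(np.hypot(*(np.subtract(b, j))) / (H - 1), 1e-9)
                    j_b = (j[0] + (b[0] - j[0]) * s2, j[1] + (b[1] - j[1]) * s2)
                else:
                    j_a = j_b = j
                _stroke(canvas, a, j_a, 0.55 * stroke)
                _stroke(canvas, j_b, b, 0.55 * stroke)

        # forepaw digits
        for side in (-1, 1):
            paw = pt(0.27, side * 0.30)
            if phantom.digit_fused:
                _stroke(canvas, paw, (paw[0] - 0.035 * (H - 1), paw[1] + side * 0.02 * (W - 1)),
                        0.9 * stroke)
            else:
                for k, ang in enumerate((-0.35, 0.0, 0.35)):
                    tip = (paw[0] - 0.035 * (H - 1) * np.cos(ang),
                           paw[1] + side * 0.030 * (W - 1) * np.sin(ang + 0.6))
                    _stroke(canvas, paw, tip, 0.45 * stroke)

    if phantom.pelvis_blob:
        off = 0.06 if view == VIEW_DV else 0.05
        _stamp(canvas, *pt(0.715, off), 2.1 * stroke)

    canvas = np.clip(canvas, 0.0, 1.0)
    if config.blur_sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, config.blur_sigma)
        peak = canvas.max()
        if peak > 0:
            canvas = canvas / peak
    if rng is not None:
        canvas = canvas * (1.0 + config.center_jitter * rng.uniform(-1, 1))
        if config.noise_sigma > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sigma, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    return ImageRecord(specimen_id=specimen_id, view=view, pixels=canvas)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def generate_records(
    config: PhantomConfig, taxonomy: TaxonomyMap
) -> tuple[list[ImageRecord], list[SpecimenLabel]]:
    """Generate the in-memory dataset: image records plus specimen labels."""
    for code in GENERATOR_CODES.values():
        taxonomy[code]  # fail early on incompatible taxonomies
    rng = np.random.default_rng(config.seed)
    lo, hi = config.acquisitions_per_view
    records: list[ImageRecord] = []
    labels: list[SpecimenLabel] = []
    for i in range(config.n_specimens):
        sid = f"S{i:05d}"
        phantom, codes = sample_phantom(config, rng)
        for view in (VIEW_DV, VIEW_LAT):
            for _ in range(int(rng.integers(lo, hi + 1))):
                rec = render_view(phantom, view, config, rng, specimen_id=sid)
                rec.codes = codes
                records.append(rec)
        labels.append(specimen_union([codes], sid, taxonomy))
    return records, labels


def generate_dataset(
    config: PhantomConfig,
    taxonomy: TaxonomyMap,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, list[SpecimenLabel]]:
    """Write a dataset in the curation module's external formats.

    Emits 8-bit grayscale PNGs, a ``metadata.csv`` (specimen_id, view, path,
    codes) and a ``manifest.json`` recording the config and seed.
    """
    from .io import write_image, write_metadata  # local import avoids cycles

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    records, labels = generate_records(config, taxonomy)
    rows = []
    counters: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.specimen_id, rec.view)
        counters[key] = counters.get(key, 0) + 1
        rel = f"images/{rec.specimen_id}_{rec.view}_{counters[key]}.png"
        write_image(rec.pixels, out_dir / rel)
        rows.append(
            {"specimen_id": rec.specimen_id, "view": rec.view, "path": rel,
             "codes": ";".join(sorted(rec.codes))}
        )
    metadata = pd.DataFrame(rows, columns=["specimen_id", "view", "path", "codes"])
    write_metadata(metadata, out_dir / "metadata.csv")
    manifest = {
        "generator": "mvskel.synthetic",
        "seed": config.seed,
        "n_specimens": config.n_specimens,
        "image_size": list(config.image_size),
        "abnormal_fraction": config.abnormal_fraction,
        "class_prevalence": dict(config.class_prevalence),
        "acquisitions_per_view": list(config.acquisitions_per_view),
        "center_jitter": config.center_jitter,
        "noise_sigma": config.noise_sigma,
        "blur_sigma": config.blur_sigma,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return metadata, labels
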