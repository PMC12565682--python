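"""Readers/writers for the artifact formats and run configuration.

Formats: comma-separated UTF-8 metadata with a mandatory header row
(columns ``specimen_id, view, path, codes``; codes semicolon-separated),
8/16-bit grayscale PNG/TIFF images in, PNG composites and overlays out,
CSV manifests/reports, JSON provenance records, YAML run configs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .curation import VIEW_DV, VIEW_LAT, VIEW_OTHER, CurationConfig, ImageRecord

__all__ = [
    "MetadataRow",
    "RunConfig",
    "normalize_view",
    "read_metadata",
    "write_metadata",
    "read_image",
    "write_image",
    "load_records",
    "write_composite",
    "write_provenance",
    "setup_logging",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("specimen_id", "view", "path", "codes")


@dataclass(frozen=True)
class MetadataRow:
    """One metadata line: an image record stub (pixels not yet loaded)."""

    specimen_id: str
    view: str
    path: str
    codes: frozenset[str]


def normalize_view(view: str) -> str:
    """Case-insensitive view normalization; unknown strings map to OTHER."""
    v = view.strip().upper()
    if v == "DV":
        return VIEW_DV
    if v in ("LAT", "LV", "LATERAL"):
        return VIEW_LAT
    return VIEW_OTHER


def read_metadata(path: str | Path) -> list[MetadataRow]:
    """Parse and validate a metadata CSV into image-record stubs."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing column(s): {sorted(missing)}")
    rows = []
    for r in df.itertuples():
        view = normalize_view(r.view)
        if view == VIEW_OTHER and r.view.strip().upper() not in ("", "OTHER"):
            logger.warning(
                "unknown view %r for specimen %s mapped to OTHER", r.view, r.specimen_id
            )
        codes = frozenset(c.strip() for c in r.codes.split(";") if c.strip())
        rows.append(MetadataRow(str(r.specimen_id), view, r.path, codes))
    return rows


def write_metadata(rows: pd.DataFrame | list[MetadataRow], path: str | Path) -> None:
    if isinstance(rows, list):
        rows = pd.DataFrame(
            [
                {"specimen_id": r.specimen_id, "view": r.view, "path": r.path,
                 "codes": ";".join(sorted(r.codes))}
                for r in rows
            ],
            columns=list(REQUIRED_COLUMNS),
        )
    rows.to_csv(path, index=False)


def read_image(path: str | Path) -> np.ndarray:
    """Load an 8/16-bit grayscale PNG/TIFF as floats in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # color input: average channels to grayscale
        arr = arr.mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype in (np.uint16, np.int32):
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale array as 8-bit PNG."""
    arr = (np.clip(np.asarray(pixels), 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_records(
    rows: list[MetadataRow], image_root: str | Path
) -> tuple[list[ImageRecord], list[dict]]:
    """Load pixel data for metadata stubs; missing files are skipped and logged."""
    image_root = Path(image_root)
    records, skipped = [], []
    for row in rows:
        p = image_root / row.path
        if not p.exists():
            skipped.append({"specimen_id": row.specimen_id, "path": str(p),
                            "reason": "missing image file"})
            logger.warning("skipping specimen %s: missing image %s", row.specimen_id, p)
            continue
        records.append(
            ImageRecord(row.specimen_id, row.view, read_image(p), codes=row.codes)
        )
    return records, skipped


def write_composite(channels: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) composite in [0, 1] as RGB PNG."""
    arr = (np.clip(np.asarray(channels), 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


@dataclass
class RunConfig:
    """End-to-end run settings (mirrors the training hyperparameter table)."""

    metadata: str = "metadata.csv"
    image_root: str = "."
    output_dir: str = "out"
    taxonomy: str | None = None  # None -> bundled default
    family: str = "cae"
    target_size: int = 224
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.2
    w_dv: float = 0.6
    min_edge_component: int = 10
    optimizer: str = "adam"
    loss: str = "binary cross-entropy"
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    patience: int = 3
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    log_level: str = "INFO"

    def curation_config(self) -> CurationConfig:
        return CurationConfig(
            target_size=self.target_size, canny_sigma=self.canny_sigma,
            canny_low=self.canny_low, canny_high=self.canny_high,
            w_dv=self.w_dv, min_edge_component=self.min_edge_component,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "seeds" in raw:
            raw["seeds"] = tuple(raw["seeds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({**dataclasses.asdict(self), "seeds": list(self.seeds)})
        )


def write_provenance(out_dir: str | Path, config: object, seed: int | None = None) -> Path:
    """Write a machine-readable provenance record for reproducibility."""
    from importlib.metadata import version

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    cfg = json.loads(json.dumps(cfg, default=str))
    blob = json.dumps(cfg, sort_keys=True).encode()
    record = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "python": sys.version.split()[0],
        "versions": {
            pkg: _safe_version(pkg)
            for pkg in ("mvskel", "numpy", "scipy", "pandas", "scikit-image",
                        "scikit-learn")
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path


def _safe_version(pkg: str) -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version(pkg)
    except PackageNotFoundError:
        return "unknown"


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
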