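"""Three-level hierarchical label algebra for mouse skeletal phenotyping.

IMPC expert screens annotate each radiograph with zero or more abnormality
codes drawn from a fixed vocabulary of 53 observations.  This module turns
those flat code sets into a three-level hierarchy:

* **L1** — binary: a specimen is *abnormal* iff it carries at least one code.
* **L2** — anatomical subclass: each code maps to exactly one of
  {Limbs, Ribcage, Skull, Spine, Whole-body}; a specimen's L2 label is the
  image of its code set under that map.  Skull and Limbs are excluded from
  the modelled set by default (too few occurrences), leaving three classes.
* **L3** — localized subclass: each code also maps to exactly one of ten
  finer classes (Caudal, Thoracic, Cervical, Lumbar, Morphology, Shape,
  Digits, Fusion, Joints, Other).

The retained L2 (3) and L3 (10) classes define the slots of the 13-element
binary label vector that the hierarchical classifiers predict.  Codes whose
L2 class is excluded still make a specimen L1-abnormal but contribute no
L2/L3 bits.

The taxonomy itself (code -> subclass tags) is a CSV config; a bundled
default covers every subclass member the phenotyping vocabulary names plus
documented placeholders.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "L2_FULL",
    "L3_FULL",
    "DEFAULT_RETAINED_L2",
    "DEFAULT_RETAINED_L3",
    "AbnormalityCode",
    "TaxonomyMap",
    "SpecimenLabel",
    "TaxonomyError",
    "load_taxonomy",
    "assign_l1",
    "map_l2",
    "map_l3",
    "specimen_union",
    "encode_label_vector",
    "decode_label_vector",
    "DatasetSummary",
    "summarize_dataset",
]

#: Full L2 codomain (alphabetical, as listed in the phenotyping vocabulary).
L2_FULL: tuple[str, ...] = ("Limbs", "Ribcage", "Skull", "Spine", "Whole-body")

#: Full L3 codomain, in its canonical listing order (this order fixes the
#: L3 slots of the label vector).
L3_FULL: tuple[str, ...] = (
    "Caudal",
    "Thoracic",
    "Cervical",
    "Lumbar",
    "Morphology",
    "Shape",
    "Digits",
    "Fusion",
    "Joints",
    "Other",
)

#: L2 classes retained for modelling; Skull and Limbs are excluded by
#: default because abnormalities there are rare in the full-body views.
DEFAULT_RETAINED_L2: tuple[str, ...] = ("Spine", "Ribcage", "Whole-body")
DEFAULT_RETAINED_L3: tuple[str, ...] = L3_FULL


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy files or unknown codes/classes."""


@dataclass(frozen=True)
class AbnormalityCode:
    """One expert abnormality observation and its subclass tags."""

    code: str
    name: str
    l2_class: str
    l3_class: str

    def __post_init__(self) -> None:
        if self.l2_class not in L2_FULL:
            raise TaxonomyError(
                f"code {self.code!r}: unknown level-2 subclass {self.l2_class!r} "
                f"(expected one of {L2_FULL})"
            )
        if self.l3_class not in L3_FULL:
            raise TaxonomyError(
                f"code {self.code!r}: unknown level-3 subclass {self.l3_class!r} "
                f"(expected one of {L3_FULL})"
            )


@dataclass(frozen=True)
class TaxonomyMap:
    """The abnormality vocabulary with its subclass maps and retained classes.

    ``retained_l2`` followed by ``retained_l3`` defines the slot order of the
    binary label vector (length 13 with the defaults).
    """

    codes: Mapping[str, AbnormalityCode]
    retained_l2: tuple[str, ...] = DEFAULT_RETAINED_L2
    retained_l3: tuple[str, ...] = DEFAULT_RETAINED_L3

    def __post_init__(self) -> None:
        if not self.codes:
            raise TaxonomyError("taxonomy must be nonempty")
        if not set(self.retained_l2) <= set(L2_FULL):
            raise TaxonomyError(f"retained_l2 {self.retained_l2} not a subset of {L2_FULL}")
        if not set(self.retained_l3) <= set(L3_FULL):
            raise TaxonomyError(f"retained_l3 {self.retained_l3} not a subset of {L3_FULL}")

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __getitem__(self, code: str) -> AbnormalityCode:
        try:
            return self.codes[code]
        except KeyError:
            raise TaxonomyError(f"unknown abnormality code {code!r}") from None

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def vector_classes(self) -> tuple[str, ...]:
        """Slot order of the label vector: retained L2 then retained L3."""
        return self.retained_l2 + self.retained_l3

    @property
    def vector_length(self) -> int:
        return len(self.retained_l2) + len(self.retained_l3)

    def retained_codes(self, codes: Iterable[str]) -> set[str]:
        """Subset of ``codes`` whose L2 class is retained for modelling."""
        return {c for c in codes if self[c].l2_class in self.retained_l2}


@dataclass(frozen=True)
class SpecimenLabel:
    """A specimen's abnormality set and its derived hierarchical labels."""

    specimen_id: str
    abnormality_set: frozenset[str]
    l1: str  # "normal" | "abnormal"
    l2_set: frozenset[str]
    l3_set: frozenset[str]
    vector: tuple[int, ...] = ()


def _default_taxonomy_path() -> Path:
    return Path(str(resources.files("mvskel").joinpath("data/default_taxonomy.csv")))


def load_taxonomy(
    path: str | Path | None = None,
    retained_l2: Sequence[str] = DEFAULT_RETAINED_L2,
    retained_l3: Sequence[str] = DEFAULT_RETAINED_L3,
) -> TaxonomyMap:
    """Load and validate a taxonomy CSV (columns: code, name, l2, l3).

    With ``path=None`` the bundled 53-code default is loaded.  Duplicate
    codes, missing columns, unknown subclass tags and empty files all raise
    :class:`TaxonomyError`.
    """
    path = _default_taxonomy_path() if path is None else Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"code", "name", "l2", "l3"}
    missing = required - set(df.columns)
    if missing:
        raise TaxonomyError(f"taxonomy file {path} missing columns: {sorted(missing)}")
    if df.empty:
        raise TaxonomyError("taxonomy must be nonempty")
    dupes = df["code"][df["code"].duplicated()].tolist()
    if dupes:
        raise TaxonomyError(f"duplicate abnormality codes in taxonomy: {dupes}")
    codes = {
        row.code: AbnormalityCode(row.code, row.name, row.l2, row.l3)
        for row in df.itertuples()
    }
    return TaxonomyMap(codes, tuple(retained_l2), tuple(retained_l3))


def _check_known(abnormality_set: Iterable[str], taxonomy: TaxonomyMap) -> set[str]:
    s = set(abnormality_set)
    for code in s:
        taxonomy[code]  # raises TaxonomyError on unknown codes
    return s


def assign_l1(abnormality_set: Iterable[str], taxonomy: TaxonomyMap) -> str:
    """``abnormal`` iff the specimen carries at least one abnormality code."""
    return "abnormal" if _check_known(abnormality_set, taxonomy) else "normal"


def map_l2(abnormality_set: Iterable[str], taxonomy: TaxonomyMap) -> set[str]:
    """Image of the code set under the code -> level-2 subclass map."""
    return {taxonomy[c].l2_class for c in _check_known(abnormality_set, taxonomy)}


def map_l3(abnormality_set: Iterable[str], taxonomy: TaxonomyMap) -> set[str]:
    """Image of the code set under the code -> level-3 subclass map."""
    return {taxonomy[c].l3_class for c in _check_known(abnormality_set, taxonomy)}


def specimen_union(
    image_labels: Sequence[Iterable[str]],
    specimen_id: str,
    taxonomy: TaxonomyMap,
) -> SpecimenLabel:
    """Derive a specimen label from its per-image abnormality sets.

    The specimen's abnormality set is the union over its images.  L1 counts
    every code; the L2/L3 sets only count codes whose L2 class is retained,
    intersected with the retained class lists.
    """
    if not image_labels:
        raise ValueError(f"specimen {specimen_id!r} has no images")
    union: set[str] = set()
    for labels in image_labels:
        union |= _check_known(labels, taxonomy)
    retained = taxonomy.retained_codes(union)
    l2_set = frozenset(map_l2(retained, taxonomy) & set(taxonomy.retained_l2))
    l3_set = frozenset(map_l3(retained, taxonomy) & set(taxonomy.retained_l3))
    label = SpecimenLabel(
        specimen_id=specimen_id,
        abnormality_set=frozenset(union),
        l1=assign_l1(union, taxonomy),
        l2_set=l2_set,
        l3_set=l3_set,
    )
    vector = tuple(int(v) for v in encode_label_vector(label, taxonomy))
    return SpecimenLabel(**{**label.__dict__, "vector": vector})


def encode_label_vector(label: SpecimenLabel, taxonomy: TaxonomyMap) -> np.ndarray:
    """Binary slot vector: retained L2 classes first, then retained L3.

    A normal specimen encodes to all zeros; vector length is 13 with the
    default taxonomy.
    """
    unknown = (label.l2_set - set(taxonomy.retained_l2)) | (
        label.l3_set - set(taxonomy.retained_l3)
    )
    if unknown:
        raise TaxonomyError(
            f"label sets contain classes outside the retained lists: {sorted(unknown)}"
        )
    vec = np.zeros(taxonomy.vector_length, dtype=np.int8)
    for i, cls in enumerate(taxonomy.retained_l2):
        if cls in label.l2_set:
            vec[i] = 1
    off = len(taxonomy.retained_l2)
    for i, cls in enumerate(taxonomy.retained_l3):
        if cls in label.l3_set:
            vec[off + i] = 1
    return vec


def decode_label_vector(
    vector: Sequence[int], taxonomy: TaxonomyMap
) -> tuple[set[str], set[str]]:
    """Inverse of :func:`encode_label_vector`: recover (l2_set, l3_set)."""
    vector = np.asarray(vector)
    if vector.shape != (taxonomy.vector_length,):
        raise TaxonomyError(
            f"expected vector of length {taxonomy.vector_length}, got shape {vector.shape}"
        )
    n2 = len(taxonomy.retained_l2)
    l2 = {cls for i, cls in enumerate(taxonomy.retained_l2) if vector[i]}
    l3 = {cls for i, cls in enumerate(taxonomy.retained_l3) if vector[n2 + i]}
    return l2, l3


@dataclass(frozen=True)
class DatasetSummary:
    """Counts of specimens per distinct L2 combination, plus totals."""

    table: pd.DataFrame  # columns: l1_label, l2_combination, n_specimens
    n_abnormal: int
    n_normal: int

    def to_frame(self) -> pd.DataFrame:
        """Summary with a trailing total-abnormal row (report layout)."""
        total = pd.DataFrame(
            [{"l1_label": "Total Abnormal count", "l2_combination": "-",
              "n_specimens": self.n_abnormal}]
        )
        return pd.concat([self.table, total], ignore_index=True)


def summarize_dataset(labels: Iterable[SpecimenLabel]) -> DatasetSummary:
    """Tabulate abnormal specimens by their L2 combination, sorted by count."""
    combos: Counter[tuple[str, ...]] = Counter()
    n_normal = 0
    for lab in labels:
        if lab.l1 == "abnormal":
            combos[tuple(sorted(lab.l2_set))] += 1
        else:
            n_normal += 1
    rows = [
        {
            "l1_label": "Abnormal",
            "l2_combination": "[" + ", ".join(combo) + "]",
            "n_specimens": n,
        }
        for combo, n in sorted(combos.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    table = pd.DataFrame(rows, columns=["l1_label", "l2_combination", "n_specimens"])
    return DatasetSummary(table=table, n_abnormal=sum(combos.values()), n_normal=n_normal)
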