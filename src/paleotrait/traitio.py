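"""Reading, validating and transforming the per-species count table.

The table carries one row per species: observed count minimum/maximum/mean,
whether intraspecific variation was actually reported, an extinct flag and,
for extinct species, a stratigraphic first/last-appearance interval. The
soft-range rule widens point records by +/-1 (lower-clamped at zero) and a
ceiling rule turns means into integer states for the discrete Markov models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .treekit import DatedTree, StratRange

__all__ = [
    "TraitError",
    "TraitRecord",
    "TraitVector",
    "COLUMNS",
    "VARIANTS",
    "read_trait_table",
    "write_trait_table",
    "resolve_soft_range",
    "discretize_mean",
    "map_to_tips",
    "strat_ranges",
]

COLUMNS = [
    "species",
    "old_label",
    "count_min",
    "count_max",
    "count_mean",
    "polymorphism_reported",
    "extinct",
    "fad",
    "lad",
]

#: supported trait-vector variants
VARIANTS = ("mean", "soft_min", "soft_max", "discrete", "discrete_min", "discrete_max")


class TraitError(ValueError):
    """Invalid trait table or mapping request."""


@dataclass(frozen=True)
class TraitRecord:
    species: str
    old_label: str
    count_min: int
    count_max: int | None  # None encodes "minimum with unknown maximum"
    count_mean: float
    polymorphism_reported: bool
    extinct: bool
    fad: float | None = None
    lad: float | None = None

    def __post_init__(self) -> None:
        if self.count_min < 0:
            raise TraitError(f"{self.species}: negative count_min")
        if self.count_max is not None:
            if self.count_min > self.count_max:
                raise TraitError(
                    f"{self.species}: count_min {self.count_min} > count_max {self.count_max}"
                )
            if not (self.count_min <= self.count_mean <= self.count_max):
                raise TraitError(
                    f"{self.species}: count_mean {self.count_mean} outside "
                    f"[{self.count_min}, {self.count_max}]"
                )
        elif self.count_mean < self.count_min:
            raise TraitError(f"{self.species}: count_mean below count_min")
        if self.extinct:
            if self.fad is None or self.lad is None:
                raise TraitError(f"{self.species}: extinct record lacks fad/lad")
            if not (self.fad >= self.lad >= 0):
                raise TraitError(f"{self.species}: fad >= lad >= 0 violated")


@dataclass(frozen=True)
class TraitVector:
    """Per-tip trait values, aligned with a tree's tip order."""

    values: np.ndarray
    variant: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise TraitError(f"unknown variant {self.variant!r}")
        if len(self.values) != len(self.labels):
            raise TraitError("values/labels length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise TraitError("missing values in trait vector")

    def __len__(self) -> int:
        return len(self.values)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n", ""):
        return False
    raise TraitError(f"cannot parse boolean field {x!r}")


def read_trait_table(
    path,
    corrections: Mapping[str, int] | None = None,
) -> list[TraitRecord]:
    """Read and validate the count table (CSV with the ``COLUMNS`` header).

    ``corrections`` optionally overrides the point count of named species
    (min = max = mean = value), e.g. for post-publication errata, before
    validation.
    """
    df = pd.read_csv(path, dtype={"species": str, "old_label": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TraitError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise TraitError("no records")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise TraitError(f"duplicated species labels: {sorted(set(dupes))}")

    records = []
    for row in df.itertuples(index=False):
        cmax = None if pd.isna(row.count_max) else int(row.count_max)
        cmin = int(row.count_min)
        cmean = float(row.count_mean) if not pd.isna(row.count_mean) else float(cmin)
        rec = TraitRecord(
            species=row.species,
            old_label=row.old_label if isinstance(row.old_label, str) else row.species,
            count_min=cmin,
            count_max=cmax,
            count_mean=cmean,
            polymorphism_reported=_parse_bool(row.polymorphism_reported),
            extinct=_parse_bool(row.extinct),
            fad=None if pd.isna(row.fad) else float(row.fad),
            lad=None if pd.isna(row.lad) else float(row.lad),
        )
        if corrections and rec.species in corrections:
            v = int(corrections[rec.species])
            rec = replace(rec, count_min=v, count_max=v, count_mean=float(v))
        records.append(rec)
    return records


def write_trait_table(records: Sequence[TraitRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "old_label": r.old_label,
                "count_min": r.count_min,
                "count_max": "" if r.count_max is None else r.count_max,
                "count_mean": r.count_mean,
                "polymorphism_reported": r.polymorphism_reported,
                "extinct": r.extinct,
                "fad": "" if r.fad is None else r.fad,
                "lad": "" if r.lad is None else r.lad,
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def resolve_soft_range(record: TraitRecord) -> tuple[int, int]:
    """Soft minimum/maximum for a record.

    Reported polymorphic ranges are kept as-is. A point count c without
    polymorphism data becomes (max(0, c-1), c+1); a minimum-only count m
    (unknown maximum) keeps its hard minimum and gets max m+1.
    """
    if record.count_max is None:
        return record.count_min, record.count_min + 1
    if record.polymorphism_reported:
        return record.count_min, record.count_max
    if record.count_min == record.count_max:
        c = record.count_min
        return max(0, c - 1), c + 1
    # un-flagged but non-degenerate range: treat the range itself as the report
    return record.count_min, record.count_max


def discretize_mean(record: TraitRecord) -> int:
    """Integer state for the ordered Markov models: ceiling of the mean."""
    return int(math.ceil(record.count_mean))


def _variant_value(record: TraitRecord, variant: str) -> float:
    low, high = resolve_soft_range(record)
    if variant == "mean":
        return record.count_mean
    if variant == "soft_min":
        return float(low)
    if variant == "soft_max":
        return float(high)
    if variant == "discrete":
        return float(discretize_mean(record))
    if variant == "discrete_min":
        return float(low)
    if variant == "discrete_max":
        return float(high)
    raise TraitError(f"unknown variant {variant!r}")


def map_to_tips(
    records: Iterable[TraitRecord],
    tree: DatedTree,
    variant: str = "mean",
    congeneric_swaps: Mapping[str, str] | None = None,
) -> tuple[TraitVector, list[str]]:
    """Build a tip-ordered trait vector; returns (vector, unmatched report).

    ``congeneric_swaps`` maps source labels (``old_label``) onto tree tips for
    records whose own species label is absent from the tree.
    """
    swaps = dict(congeneric_swaps or {})
    tipset = set(tree.tip_labels)
    by_tip: dict[str, TraitRecord] = {}
    unmatched: list[str] = []
    for rec in records:
        label = rec.species
        if label not in tipset and rec.old_label in swaps:
            label = swaps[rec.old_label]
        if label not in tipset:
            unmatched.append(rec.species)
            continue
        if label in by_tip:
            raise TraitError(f"two records map to tip {label!r}")
        by_tip[label] = rec
    missing = [t for t in tree.tip_labels if t not in by_tip]
    if missing:
        raise TraitError(
            f"{len(missing)} tree tips without trait records "
            f"(first few: {missing[:5]}); prune the tree first"
        )
    values = np.array([_variant_value(by_tip[t], variant) for t in tree.tip_labels])
    return TraitVector(values=values, variant=variant, labels=tuple(tree.tip_labels)), unmatched


def strat_ranges(records: Iterable[TraitRecord]) -> list[StratRange]:
    """Stratigraphic ranges of the extinct records, for tip-age resampling."""
    return [
        StratRange(taxon=r.species, fad=float(r.fad), lad=float(r.lad))
        for r in records
        if r.extinct
    ]
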