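"""Tile/patient/domain data model, manifest I/O, and leakage-safe splitting.

Tiles from one patient are highly correlated, so train/test membership is
decided at the *patient* level: a patient's tiles never straddle a split.
The manifest is a plain CSV (tile_path, patient_id, label, domain, case_id)
so cohorts round-trip through pandas without a database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .image import RGBTile, read_tile

MANIFEST_COLUMNS = ("tile_path", "patient_id", "label", "domain", "case_id")


class ManifestSchemaError(ValueError):
    """Manifest CSV is missing a required column."""


class CohortError(ValueError):
    """Structural problem in a cohort (duplicates, bad labels, ...)."""


@dataclass
class TileRecord:
    """One tile with its provenance: patient, binary label, institute tag, slide."""

    tile_ref: str
    patient_id: str
    label: int
    domain: str
    case_id: str
    tile: RGBTile | None = None   # in-memory pixels; else tile_ref is a path
    split: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise CohortError(f"label must be 0 or 1, got {self.label!r}")
        if not self.patient_id:
            raise CohortError("patient_id must be nonempty")


@dataclass
class Cohort:
    """An ordered collection of tile records with a name."""

    records: list[TileRecord]
    name: str = "cohort"

    def __post_init__(self) -> None:
        refs = [r.tile_ref for r in self.records]
        if len(set(refs)) != len(refs):
            dupes = sorted({r for r in refs if refs.count(r) > 1})
            raise CohortError(f"duplicate tile_ref entries: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def patients(self) -> list[str]:
        """Unique patient ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def domains(self) -> list[str]:
        return sorted({r.domain for r in self.records})

    def subset(self, indices, name: str | None = None) -> "Cohort":
        return Cohort([self.records[i] for i in indices], name or self.name)

    def filter_patients(self, patient_ids, name: str | None = None) -> "Cohort":
        keep = set(patient_ids)
        recs = [r for r in self.records if r.patient_id in keep]
        return Cohort(recs, name or self.name)

    def get_tile(self, record: TileRecord) -> RGBTile:
        """Materialize a record's pixels (lazy path load if not in memory)."""
        if record.tile is not None:
            return record.tile
        return read_tile(record.tile_ref)

    def class_balance(self) -> float:
        """Fraction of class-1 tiles."""
        if not self.records:
            raise CohortError("empty cohort has no class balance")
        return float(self.labels().mean())


def load_manifest(csv_path: str | Path, name: str | None = None) -> Cohort:
    """Read a manifest CSV into a cohort (one record per row, labels as ints)."""
    df = pd.read_csv(csv_path, comment="#", dtype=str)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ManifestSchemaError(f"manifest is missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            label = int(getattr(row, "label"))
        except (TypeError, ValueError):
            raise CohortError(f"row {i}: label {getattr(row, 'label')!r} is not an integer")
        if label not in (0, 1):
            raise CohortError(f"row {i}: label must be 0 or 1, got {label}")
        records.append(
            TileRecord(
                tile_ref=str(getattr(row, "tile_path")),
                patient_id=str(getattr(row, "patient_id")),
                label=label,
                domain=str(getattr(row, "domain")),
                case_id=str(getattr(row, "case_id")),
                split=str(getattr(row, "split")) if "split" in df.columns else None,
            )
        )
    return Cohort(records, name or Path(csv_path).stem)


def write_manifest(cohort: Cohort, csv_path: str | Path) -> None:
    """Write a cohort back to CSV, including split assignments when present."""
    rows = {
        "tile_path": [r.tile_ref for r in cohort],
        "patient_id": [r.patient_id for r in cohort],
        "label": [r.label for r in cohort],
        "domain": [r.domain for r in cohort],
        "case_id": [r.case_id for r in cohort],
    }
    if any(r.split is not None for r in cohort):
        rows["split"] = [r.split or "" for r in cohort]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def _split_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n patients to the split fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    rema = np.argsort([c - x for c, x in zip(counts, raw)])  # most-short first
    for i in range(n - sum(counts)):
        counts[rema[i % len(fractions)]] += 1
    return counts


def patient_stratified_split(
    cohort: Cohort,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    rng: np.random.Generator | None = None,
    balance_tolerance: float = 0.1,
    max_retries: int = 50,
) -> tuple[Cohort, Cohort, Cohort]:
    """Partition a cohort into train/val/test at the patient level.

    All tiles of a patient land in exactly one split. Draws are redrawn (up
    to ``max_retries``) until each split's class balance is within
    ``balance_tolerance`` of the cohort balance; if no draw satisfies the
    tolerance the best-balanced draw is returned with a warning.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = rng or np.random.default_rng()

    by_domain: dict[str, set[str]] = {}
    for r in cohort:
        by_domain.setdefault(r.patient_id, set()).add(r.domain)
    multi = sorted(p for p, d in by_domain.items() if len(d) > 1)
    if multi:
        raise CohortError(f"patients span multiple domains: {multi[:5]}")

    patients = cohort.patients()
    if len(patients) < 3:
        raise CohortError(
            f"need at least 3 patients for a 3-way split, got {len(patients)}"
        )
    counts = _split_counts(len(patients), fractions)
    target = cohort.class_balance()

    best: tuple[float, tuple] | None = None
    for _ in range(max_retries):
        perm = rng.permutation(len(patients))
        shuffled = [patients[i] for i in perm]
        parts = (
            shuffled[: counts[0]],
            shuffled[counts[0] : counts[0] + counts[1]],
            shuffled[counts[0] + counts[1] :],
        )
        splits = tuple(
            cohort.filter_patients(p, f"{cohort.name}/{nm}")
            for p, nm in zip(parts, ("train", "val", "test"))
        )
        err = max(abs(s.class_balance() - target) for s in splits if len(s))
        if any(len(s) == 0 for s in splits):
            err = np.inf
        if best is None or err < best[0]:
            best = (err, splits)
        if err <= balance_tolerance:
            break
    else:
        warnings.warn(
            f"no split within balance tolerance {balance_tolerance} after "
            f"{max_retries} draws; returning best (deviation {best[0]:.3f})",
            stacklevel=2,
        )
    splits = best[1]
    for s, nm in zip(splits, ("train", "val", "test")):
        for r in s.records:
            r.split = nm
    return splits


def sample_tiles_per_case(
    cohort: Cohort, n_per_class: int, rng: np.random.Generator | None = None
) -> Cohort:
    """Uniformly sample up to ``n_per_class`` tiles per (case, class), no replacement.

    Cases with fewer tiles than requested keep everything they have.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if len(cohort) == 0:
        raise CohortError("cannot sample from an empty cohort")
    rng = rng or np.random.default_rng()
    groups: dict[tuple[str, int], list[int]] = {}
    for i, r in enumerate(cohort):
        groups.setdefault((r.case_id, r.label), []).append(i)
    keep: list[int] = []
    for key in sorted(groups):
        idx = groups[key]
        if len(idx) <= n_per_class:
            keep.extend(idx)
        else:
            chosen = rng.choice(len(idx), size=n_per_class, replace=False)
            keep.extend(idx[j] for j in sorted(chosen))
    return cohort.subset(sorted(keep), f"{cohort.name}/sampled")
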