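"""Bagging and NoisyEnsemble training plans.

A NoisyEnsemble member trains on a fresh patient subset in which, for each
selected patient, at most one of the two classes may have all its tile
labels flipped, until roughly a target fraction (default 15 %) of the
member's training labels are noised. Flipping whole (patient, class) groups
— never individual tiles — keeps the injected noise structured: it mimics
coherent annotation error rather than i.i.d. label corruption, and is the
property that makes the ensemble diverse without destroying the signal.

Plans are pure data (JSON-serializable), decoupled from training, so the
exact subsets and flips of every member are reproducible and auditable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort, CohortError, TileRecord


class PlanningError(ValueError):
    """The target noise rate is unreachable on this cohort."""


@dataclass(frozen=True)
class NoiseGroup:
    """One patient's noised class: every tile of (patient, class) gets flipped."""

    patient_id: str
    noised_class: int


@dataclass
class MemberPlan:
    """One ensemble member's training recipe: subset, flips, realized noise."""

    member_index: int
    patient_subset: tuple[str, ...]
    noise_groups: tuple[NoiseGroup, ...]
    flipped_tiles: frozenset[str]
    realized_noise_rate: float

    def __post_init__(self) -> None:
        subset = set(self.patient_subset)
        patients = [g.patient_id for g in self.noise_groups]
        if len(set(patients)) != len(patients):
            raise PlanningError("a patient appears in more than one noise group")
        if not set(patients) <= subset:
            raise PlanningError("noise groups reference patients outside the subset")

    def to_dict(self) -> dict:
        return {
            "member_index": self.member_index,
            "patient_subset": list(self.patient_subset),
            "noise_groups": [
                {"patient_id": g.patient_id, "noised_class": g.noised_class}
                for g in self.noise_groups
            ],
            "flipped_tiles": sorted(self.flipped_tiles),
            "realized_noise_rate": self.realized_noise_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MemberPlan":
        return cls(
            member_index=d["member_index"],
            patient_subset=tuple(d["patient_subset"]),
            noise_groups=tuple(
                NoiseGroup(g["patient_id"], g["noised_class"])
                for g in d["noise_groups"]
            ),
            flipped_tiles=frozenset(d["flipped_tiles"]),
            realized_noise_rate=d["realized_noise_rate"],
        )


@dataclass
class EnsemblePlan:
    """A full ensemble: member plans plus the seed that generated them."""

    members: list[MemberPlan]
    target_noise_rate: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise PlanningError("ensemble needs at least one member")
        if not 0 <= self.target_noise_rate < 0.5:
            raise PlanningError("target_noise_rate must be in [0, 0.5)")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "target_noise_rate": self.target_noise_rate,
                "seed": self.seed,
                "members": [m.to_dict() for m in self.members],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "EnsemblePlan":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            members=[MemberPlan.from_dict(m) for m in d["members"]],
            target_noise_rate=d["target_noise_rate"],
            seed=d["seed"],
        )


def make_member_plan(
    cohort: Cohort,
    subset_fraction: float = 0.8,
    target_noise_rate: float = 0.15,
    rng: np.random.Generator | None = None,
    member_index: int = 0,
    with_replacement: bool = False,
) -> MemberPlan:
    """Draw one member's patient subset and (patient, class) label flips.

    Selected patients each get one candidate class (uniform). The candidate
    groups are visited in random order, flipping whole groups, stopping at
    the group boundary whose cumulative flipped fraction is closest to
    ``target_noise_rate``. Groups are never split, so the realized rate is
    within one group of the target whenever the target is reachable.
    """
    if not 0 < subset_fraction <= 1:
        raise PlanningError("subset_fraction must be in (0, 1]")
    if not 0 <= target_noise_rate < 0.5:
        raise PlanningError("target_noise_rate must be in [0, 0.5)")
    rng = rng or np.random.default_rng()

    patients = cohort.patients()
    if not patients:
        raise CohortError("cannot plan on an empty cohort")
    n_sel = math.ceil(subset_fraction * len(patients))
    if with_replacement:
        chosen = rng.choice(len(patients), size=n_sel, replace=True)
        subset = tuple(dict.fromkeys(patients[i] for i in chosen))
    else:
        chosen = rng.choice(len(patients), size=n_sel, replace=False)
        subset = tuple(patients[i] for i in sorted(chosen))
    subset_set = set(subset)

    member_tiles = [r for r in cohort if r.patient_id in subset_set]
    total = len(member_tiles)
    if target_noise_rate == 0:
        return MemberPlan(member_index, subset, (), frozenset(), 0.0)

    candidate_class = {p: int(rng.integers(0, 2)) for p in subset}
    order = [subset[i] for i in rng.permutation(len(subset))]

    group_tiles: dict[str, list[str]] = {
        p: [
            r.tile_ref
            for r in member_tiles
            if r.patient_id == p and r.label == candidate_class[p]
        ]
        for p in order
    }
    # cumulative flipped counts after each group boundary (k groups flipped)
    sizes = [len(group_tiles[p]) for p in order]
    cum = np.concatenate([[0], np.cumsum(sizes)])
    rates = cum / total
    k = int(np.argmin(np.abs(rates - target_noise_rate)))
    best_gap = abs(rates[k] - target_noise_rate)
    granularity = max(sizes) / total if sizes else 1.0
    if best_gap > 2.0 * granularity:
        raise PlanningError(
            f"target noise rate {target_noise_rate} unreachable: closest "
            f"attainable rate is {rates[k]:.3f} (group granularity {granularity:.3f})"
        )
    taken = order[:k]
    groups = tuple(NoiseGroup(p, candidate_class[p]) for p in taken)
    flipped = frozenset(ref for p in taken for ref in group_tiles[p])
    return MemberPlan(member_index, subset, groups, flipped, len(flipped) / total)


def make_ensemble_plan(
    cohort: Cohort,
    n_members: int = 15,
    subset_fraction: float = 0.8,
    target_noise_rate: float = 0.15,
    seed: int = 0,
    with_replacement: bool = False,
) -> EnsemblePlan:
    """Draw ``n_members`` independent member plans from a seed-derived stream."""
    if n_members < 1:
        raise PlanningError("n_members must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_members)
    members = [
        make_member_plan(
            cohort,
            subset_fraction=subset_fraction,
            target_noise_rate=target_noise_rate,
            rng=np.random.default_rng(s),
            member_index=i,
            with_replacement=with_replacement,
        )
        for i, s in enumerate(streams)
    ]
    return EnsemblePlan(members, target_noise_rate, seed)


def apply_member_plan(cohort: Cohort, plan: MemberPlan) -> Cohort:
    """Materialize a member's training cohort: subset patients, flip planned labels.

    Returns a new cohort with fresh records (pixel arrays are shared); the
    input cohort is never mutated. Applying the same flips twice restores the
    original labels (involution).
    """
    unknown = set(plan.patient_subset) - set(cohort.patients())
    if unknown:
        raise CohortError(f"plan references unknown patients: {sorted(unknown)[:5]}")
    subset = set(plan.patient_subset)
    records = []
    for r in cohort:
        if r.patient_id not in subset:
            continue
        label = 1 - r.label if r.tile_ref in plan.flipped_tiles else r.label
        records.append(
            TileRecord(r.tile_ref, r.patient_id, label, r.domain, r.case_id, r.tile)
        )
    return Cohort(records, f"{cohort.name}/member{plan.member_index}")


def aggregate(
    member_probs: list[np.ndarray] | np.ndarray, vote: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Combine member class-1 probabilities into an ensemble prediction.

    Default: unweighted probability mean, hard label 1 iff mean >= 0.5 (ties
    go to class 1). ``vote=True`` instead majority-votes member hard labels.
    """
    probs = np.asarray(member_probs, dtype=float)
    if probs.ndim == 1:
        probs = probs[None, :]
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError("member_probs must be a (n_members, n_tiles) array")
    if probs.shape[1] == 0:
        raise ValueError("no tiles to aggregate")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if vote:
        mean = (probs >= 0.5).mean(axis=0)
    else:
        mean = probs.mean(axis=0)
    return mean, (mean >= 0.5).astype(int)
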