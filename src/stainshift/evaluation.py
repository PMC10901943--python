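"""Internal/external evaluation, the Δ statistic, and the experiment protocols.

Three protocols mirror how transferability studies are run:

* normalization — train under {raw, stain-normalized, HSV-augmented} color
  handling and compare internal vs external (out-of-institute) accuracy;
* artifact — degrade test tiles along a strength sweep and compare models
  trained with vs without the artifact, summarized by
  Δ = accuracy(with artifact in training) − accuracy(without);
* ensemble — single model vs bagging vs NoisyEnsemble.

All protocols are paired by seed: every mode within one experiment sees the
same patient splits and the same training seeds, so per-seed differences are
paired observations and an exact binomial sign test applies at small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import binomtest

from .artifacts import ArtifactSpec, apply_artifact, artifact_sweep, injector
from .cohort import Cohort, CohortError, TileRecord, patient_stratified_split
from .models import (
    TileClassifier,
    TrainingConfig,
    _augment_cohort,
    reference_classifier,
    train_with_plan,
)
from .noisy_ensemble import aggregate, make_ensemble_plan
from .stain import (
    InsufficientTissueError,
    SparseFactorizationConfig,
    StainProfile,
    estimate_stain_profile,
    hsv_augment,
    normalize_to_reference,
)

NORMALIZATION_MODES = ("raw", "stain_normalized", "hsv_augmented")
ENSEMBLE_MODES = ("single", "bagging", "noisy")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def accuracy(predicted, true) -> float:
    """Fraction of exact label matches (tile-level accuracy)."""
    p = np.asarray(predicted)
    t = np.asarray(true)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("cannot compute accuracy of empty predictions")
    return float((p == t).mean())


def delta_performance(acc_with: float, acc_without: float) -> float:
    """Δ = accuracy with the artifact in training − accuracy without."""
    for a in (acc_with, acc_without):
        if not 0 <= a <= 1:
            raise ValueError(f"accuracy {a} outside [0, 1]")
    return acc_with - acc_without


def sign_test(differences: Sequence[float]) -> float:
    """Exact two-sided binomial sign test p-value on paired differences.

    Zeros are dropped (standard sign-test convention); returns 1.0 if
    everything ties.
    """
    d = np.asarray(list(differences), dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    return float(binomtest(int((d > 0).sum()), n=d.size, p=0.5).pvalue)


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-dataset accuracy summary for one mode, with per-seed detail."""

    name: str
    dataset_accuracy: dict[str, float]
    dataset_accuracy_sd: dict[str, float] = field(default_factory=dict)
    per_seed: dict[str, list[float]] = field(default_factory=dict)
    per_member: dict[str, list[list[float]]] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.dataset_accuracy.items():
            if not 0 <= v <= 1:
                raise ValueError(f"accuracy for {k!r} outside [0, 1]: {v}")

    @property
    def transfer_gap(self) -> float:
        """Internal minus external accuracy (positive = loss on transfer)."""
        return self.dataset_accuracy["internal"] - self.dataset_accuracy["external"]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "dataset_accuracy": self.dataset_accuracy,
            "dataset_accuracy_sd": self.dataset_accuracy_sd,
            "per_seed": self.per_seed,
            "per_member": self.per_member,
            "metadata": self.metadata,
        }


@dataclass
class RobustnessCurve:
    """Accuracy vs artifact strength, with and without train-time injection."""

    family: str
    strengths: list[float]
    accuracy_with_artifact_in_training: list[float]
    accuracy_without: list[float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.strengths)
        if not (
            len(self.accuracy_with_artifact_in_training) == n
            and len(self.accuracy_without) == n
        ):
            raise ValueError("curve arrays must all have one entry per strength")

    @property
    def delta(self) -> list[float]:
        return [
            delta_performance(w, wo)
            for w, wo in zip(self.accuracy_with_artifact_in_training, self.accuracy_without)
        ]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "strengths": self.strengths,
            "accuracy_with_artifact_in_training": self.accuracy_with_artifact_in_training,
            "accuracy_without": self.accuracy_without,
            "delta": self.delta,
            "metadata": self.metadata,
        }


def validate_report(d: dict) -> None:
    """Structural validation of a serialized EvaluationReport dict."""
    for key in ("name", "dataset_accuracy"):
        if key not in d:
            raise ValueError(f"report missing required key {key!r}")
    if not isinstance(d["dataset_accuracy"], dict) or not d["dataset_accuracy"]:
        raise ValueError("dataset_accuracy must be a nonempty mapping")
    for k, v in d["dataset_accuracy"].items():
        if not isinstance(v, (int, float)) or not 0 <= v <= 1:
            raise ValueError(f"dataset_accuracy[{k!r}] must be a number in [0, 1]")


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------

def _check_disjoint(internal: Cohort, external: Cohort) -> None:
    overlap = set(internal.patients()) & set(external.patients())
    if overlap:
        raise CohortError(f"internal and external cohorts share patients: {sorted(overlap)[:5]}")
    if set(internal.domains()) & set(external.domains()):
        raise CohortError("internal and external cohorts must come from different domains")


def _transform_cohort(cohort: Cohort, fn: Callable[[TileRecord], "object"]) -> Cohort:
    records = [
        TileRecord(r.tile_ref, r.patient_id, r.label, r.domain, r.case_id, fn(r), r.split)
        for r in cohort
    ]
    return Cohort(records, cohort.name)


def pick_reference_profile(
    cohort: Cohort, stain_config: SparseFactorizationConfig | None = None
) -> StainProfile:
    """Deterministic reference for normalization: first fit-able tile by tile_ref."""
    cfg = stain_config or SparseFactorizationConfig()
    for r in sorted(cohort, key=lambda r: r.tile_ref):
        try:
            return estimate_stain_profile(cohort.get_tile(r), cfg)
        except InsufficientTissueError:
            continue
    raise InsufficientTissueError("no tile in the cohort has enough tissue")


def normalize_cohort(
    cohort: Cohort,
    reference: StainProfile,
    stain_config: SparseFactorizationConfig | None = None,
) -> Cohort:
    """Stain-normalize every tile to the reference (tissue-free tiles pass through)."""
    cfg = stain_config or SparseFactorizationConfig()
    return _transform_cohort(
        cohort,
        lambda r: normalize_to_reference(
            cohort.get_tile(r), reference, cfg, pass_through_on_insufficient_tissue=True
        ),
    )


def corrupt_cohort(cohort: Cohort, spec: ArtifactSpec) -> Cohort:
    """Apply one artifact spec to every tile of a cohort."""
    return _transform_cohort(cohort, lambda r: apply_artifact(cohort.get_tile(r), spec))


def _seed_int(*parts: int) -> int:
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def _fit_single(
    factory: Callable[[TrainingConfig], TileClassifier],
    train: Cohort,
    config: TrainingConfig,
    augmentations: Sequence = (),
    augment_replicates: int = 1,
) -> TileClassifier:
    rng = np.random.default_rng(config.seed)
    train = _augment_cohort(train, augmentations, rng, augment_replicates)
    clf = factory(config)
    clf.fit(train, config)
    return clf


def _eval_on(clf: TileClassifier, datasets: dict[str, Cohort]) -> dict[str, float]:
    out = {}
    for name, cohort in datasets.items():
        probs = np.asarray(clf.predict_proba(cohort))
        out[name] = accuracy((probs >= 0.5).astype(int), cohort.labels())
    return out


def _summarize(
    name: str, per_seed: dict[str, list[float]], metadata: dict, per_member=None
) -> EvaluationReport:
    return EvaluationReport(
        name=name,
        dataset_accuracy={k: float(np.mean(v)) for k, v in per_seed.items()},
        dataset_accuracy_sd={k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                             for k, v in per_seed.items()},
        per_seed={k: list(map(float, v)) for k, v in per_seed.items()},
        per_member=per_member,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Experiment protocols
# ---------------------------------------------------------------------------

def run_normalization_experiment(
    internal: Cohort,
    external: Cohort,
    classifier_factory: Callable[[TrainingConfig], TileClassifier] | None = None,
    n_seeds: int = 5,
    base_seed: int = 0,
    modes: Sequence[str] = NORMALIZATION_MODES,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    config: TrainingConfig | None = None,
    stain_config: SparseFactorizationConfig | None = None,
    hsv_replicates: int = 3,
) -> dict[str, EvaluationReport]:
    """Compare color-handling modes on the internal→external transfer.

    Stain normalization is applied to training *and* test tiles (both
    institutes mapped onto one reference from the internal cohort); HSV
    augmentation is applied to training tiles only. Splits and training
    seeds are shared across modes, so per-seed accuracies are paired.
    """
    _check_disjoint(internal, external)
    factory = classifier_factory or (lambda cfg: reference_classifier(cfg))
    base_cfg = config or TrainingConfig()
    unknown = set(modes) - set(NORMALIZATION_MODES)
    if unknown:
        raise ValueError(f"unknown modes: {sorted(unknown)}")

    cohorts = {"raw": (internal, external)}
    if "stain_normalized" in modes:
        reference = pick_reference_profile(internal, stain_config)
        cohorts["stain_normalized"] = (
            normalize_cohort(internal, reference, stain_config),
            normalize_cohort(external, reference, stain_config),
        )

    per_seed: dict[str, dict[str, list[float]]] = {
        m: {"internal": [], "external": []} for m in modes
    }
    for s in range(n_seeds):
        split_rng = np.random.default_rng(_seed_int(base_seed, s, 101))
        train_raw, _val_raw, test_raw = patient_stratified_split(
            internal, fractions, split_rng
        )
        train_patients = train_raw.patients()
        test_patients = test_raw.patients()
        cfg = TrainingConfig(
            epochs=base_cfg.epochs, learning_rate=base_cfg.learning_rate,
            optimizer_name=base_cfg.optimizer_name, loss_name=base_cfg.loss_name,
            seed=_seed_int(base_seed, s, 202), batch_size=base_cfg.batch_size,
            l2=base_cfg.l2,
        )
        for mode in modes:
            src_int, src_ext = cohorts.get(mode, cohorts["raw"])
            train = src_int.filter_patients(train_patients)
            tests = {
                "internal": src_int.filter_patients(test_patients),
                "external": src_ext,
            }
            if mode == "hsv_augmented":
                aug = [lambda t, rng: hsv_augment(t, rng=rng)]
                clf = _fit_single(factory, train, cfg, aug, hsv_replicates)
            else:
                clf = _fit_single(factory, train, cfg)
            for ds, acc in _eval_on(clf, tests).items():
                per_seed[mode][ds].append(acc)

    meta = {"n_seeds": n_seeds, "base_seed": base_seed, "protocol": "normalization"}
    return {m: _summarize(m, per_seed[m], dict(meta, mode=m)) for m in modes}


def run_artifact_experiment(
    internal: Cohort,
    external: Cohort,
    family: str,
    strengths: Sequence[float],
    classifier_factory: Callable[[TrainingConfig], TileClassifier] | None = None,
    n_seeds: int = 3,
    base_seed: int = 0,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    config: TrainingConfig | None = None,
) -> dict[str, RobustnessCurve]:
    """Robustness curves: clean-trained vs artifact-trained, on artifacted tests.

    For each strength, both arms are evaluated on test tiles carrying the
    artifact at that strength (internal and external); the artifact-trained
    arm saw the same spec on its training tiles. Returns one curve per
    evaluation dataset.
    """
    _check_disjoint(internal, external)
    specs = artifact_sweep(family, list(strengths))
    factory = classifier_factory or (lambda cfg: reference_classifier(cfg))
    base_cfg = config or TrainingConfig()

    acc = {
        ds: {"with": np.zeros((n_seeds, len(specs))), "without": np.zeros((n_seeds, len(specs)))}
        for ds in ("internal", "external")
    }
    for s in range(n_seeds):
        split_rng = np.random.default_rng(_seed_int(base_seed, s, 101))
        train, _val, test_int = patient_stratified_split(internal, fractions, split_rng)
        cfg = TrainingConfig(
            epochs=base_cfg.epochs, learning_rate=base_cfg.learning_rate,
            seed=_seed_int(base_seed, s, 202), batch_size=base_cfg.batch_size,
            l2=base_cfg.l2,
        )
        clean = _fit_single(factory, train, cfg)
        for j, spec in enumerate(specs):
            tests = {
                "internal": corrupt_cohort(test_int, spec),
                "external": corrupt_cohort(external, spec),
            }
            trained = _fit_single(factory, train, cfg, [injector(spec)])
            for ds in tests:
                acc[ds]["without"][s, j] = _eval_on(clean, {ds: tests[ds]})[ds]
                acc[ds]["with"][s, j] = _eval_on(trained, {ds: tests[ds]})[ds]

    out = {}
    for ds in acc:
        out[ds] = RobustnessCurve(
            family=family,
            strengths=[sp.strength for sp in specs],
            accuracy_with_artifact_in_training=list(acc[ds]["with"].mean(axis=0)),
            accuracy_without=list(acc[ds]["without"].mean(axis=0)),
            metadata={
                "dataset": ds,
                "n_seeds": n_seeds,
                "base_seed": base_seed,
                "per_seed_with": acc[ds]["with"].tolist(),
                "per_seed_without": acc[ds]["without"].tolist(),
            },
        )
    return out


def run_ensemble_experiment(
    internal: Cohort,
    external: Cohort,
    classifier_factory: Callable[[TrainingConfig], TileClassifier] | None = None,
    n_members: int = 15,
    n_seeds: int = 5,
    base_seed: int = 0,
    subset_fraction: float = 0.8,
    target_noise_rate: float = 0.15,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    config: TrainingConfig | None = None,
    modes: Sequence[str] = ENSEMBLE_MODES,
) -> dict[str, EvaluationReport]:
    """Single model vs bagging vs NoisyEnsemble, paired by seed.

    Bagging and NoisyEnsemble share the ensemble-plan seed, so their member
    patient subsets are identical and the label flips are the only
    difference between the two arms.
    """
    _check_disjoint(internal, external)
    factory = classifier_factory or (lambda cfg: reference_classifier(cfg))
    base_cfg = config or TrainingConfig()

    per_seed = {m: {"internal": [], "external": []} for m in modes}
    per_member = {m: {"internal": [], "external": []} for m in modes}
    for s in range(n_seeds):
        split_rng = np.random.default_rng(_seed_int(base_seed, s, 101))
        train, _val, test_int = patient_stratified_split(internal, fractions, split_rng)
        tests = {"internal": test_int, "external": external}
        cfg = TrainingConfig(
            epochs=base_cfg.epochs, learning_rate=base_cfg.learning_rate,
            seed=_seed_int(base_seed, s, 202), batch_size=base_cfg.batch_size,
            l2=base_cfg.l2,
        )
        plan_seed = _seed_int(base_seed, s, 303)
        for mode in modes:
            if mode == "single":
                clf = _fit_single(factory, train, cfg)
                for ds, a in _eval_on(clf, tests).items():
                    per_seed[mode][ds].append(a)
                continue
            noise = target_noise_rate if mode == "noisy" else 0.0
            plan = make_ensemble_plan(
                train, n_members=n_members, subset_fraction=subset_fraction,
                target_noise_rate=noise, seed=plan_seed,
            )
            members = train_with_plan(factory, train, plan, (), cfg)
            for ds, cohort in tests.items():
                probs = np.stack([m.predict_proba(cohort) for m in members])
                mean_prob, labels = aggregate(probs)
                per_seed[mode][ds].append(accuracy(labels, cohort.labels()))
                per_member[mode][ds].append(
                    [accuracy((p >= 0.5).astype(int), cohort.labels()) for p in probs]
                )

    meta = {
        "n_seeds": n_seeds, "base_seed": base_seed, "n_members": n_members,
        "subset_fraction": subset_fraction, "target_noise_rate": target_noise_rate,
        "protocol": "ensemble",
    }
    return {
        m: _summarize(
            m, per_seed[m], dict(meta, mode=m),
            per_member[m] if per_member[m]["internal"] else None,
        )
        for m in modes
    }


def paired_differences(
    report_a: EvaluationReport, report_b: EvaluationReport, dataset: str = "external"
) -> np.ndarray:
    """Per-seed paired accuracy differences a − b on one dataset."""
    a = np.asarray(report_a.per_seed[dataset])
    b = np.asarray(report_b.per_seed[dataset])
    if a.shape != b.shape:
        raise ValueError("reports have different seed counts")
    return a - b
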