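"""The pluggable tile-classifier contract and a desk-scale reference classifier.

Any model (CNN, ViT, ...) can participate in the experiments by satisfying a
two-method contract: ``fit(cohort, config)`` and ``predict_proba(cohort) ->
class-1 probabilities``, deterministic given the config seed. The shipped
reference classifier is a deliberately small feature-based logistic model —
fixed image features (mean-pooled pixels, channel histograms, a gradient
texture summary) with a linear decision rule trained by AdaMax-style
gradient steps under binary cross-entropy. It is *not* a stand-in for a deep
network's capacity; it exists so every experiment protocol runs end-to-end
in seconds on a laptop CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.transform import resize

from .cohort import Cohort
from .image import RGBTile
from .noisy_ensemble import EnsemblePlan, apply_member_plan


class NotFittedError(RuntimeError):
    """predict_proba called before fit."""


class ContractViolation(AssertionError):
    """A classifier broke the TileClassifier behavioral contract."""


@dataclass
class TrainingConfig:
    """Training hyperparameters for the reference classifier.

    Defaults mirror a typical tile-classifier setup: 25 epochs of AdaMax-type
    adaptive gradient steps at learning rate 0.001 under binary cross-entropy.
    """

    epochs: int = 25
    learning_rate: float = 1e-3
    optimizer_name: str = "adamax"
    loss_name: str = "binary_cross_entropy"
    seed: int = 0
    batch_size: int = 32
    l2: float = 1e-4

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@runtime_checkable
class TileClassifier(Protocol):
    """Behavioral contract every pluggable classifier must satisfy."""

    def fit(self, cohort: Cohort, config: TrainingConfig) -> "TileClassifier": ...

    def predict_proba(self, cohort: Cohort) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Fixed image features
# ---------------------------------------------------------------------------

def tile_features(tile: RGBTile, pool: int = 8, hist_bins: int = 8) -> np.ndarray:
    """Deterministic fixed features: pooled pixels + channel histograms + texture.

    * ``pool x pool`` mean-downsampled RGB (coarse layout and color),
    * per-channel intensity histograms (colorimetry),
    * mean and std of the grayscale gradient magnitude (edge density — this
      is the morphology-sensitive, largely color-robust component).
    """
    cached = getattr(tile, "_feature_cache", None)
    if cached is not None and cached[0] == (pool, hist_bins):
        return cached[1]
    px = tile.pixels.astype(float) / 255.0
    small = resize(px, (pool, pool, 3), anti_aliasing=True, mode="reflect")
    hists = [
        np.histogram(px[..., ch], bins=hist_bins, range=(0, 1), density=True)[0]
        / hist_bins
        for ch in range(3)
    ]
    gray = px.mean(axis=2)
    gy, gx = np.gradient(gray)
    gmag = np.hypot(gx, gy)
    feat = np.concatenate(
        [small.ravel(), *hists, [gmag.mean(), gmag.std(), gray.mean(), gray.std()]]
    )
    tile._feature_cache = ((pool, hist_bins), feat)  # tiles are immutable in practice
    return feat


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class ReferenceTileClassifier:
    """L2-regularized logistic model on fixed features, trained with AdaMax.

    AdaMax keeps per-weight first-moment and infinity-norm accumulators, so
    each update is bounded by the learning rate; with standardized features
    and a separable problem the decision direction converges quickly even
    though the weight norm stays small.
    """

    def __init__(self, config: TrainingConfig | None = None) -> None:
        self.config = config or TrainingConfig()
        self._w: np.ndarray | None = None
        self._b: float = 0.0
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    # -- contract ----------------------------------------------------------
    def fit(self, cohort: Cohort, config: TrainingConfig | None = None) -> "ReferenceTileClassifier":
        if config is not None:
            self.config = config
        cfg = self.config
        if len(cohort) == 0:
            raise ValueError("cannot fit on an empty cohort")
        X = np.stack([tile_features(cohort.get_tile(r)) for r in cohort])
        y = cohort.labels().astype(float)
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) < 1e-9, 1.0, X.std(axis=0))
        Xs = (X - self._mu) / self._sd

        rng = np.random.default_rng(cfg.seed)
        n, d = Xs.shape
        w = np.zeros(d)
        b = 0.0
        m_w = np.zeros(d); u_w = np.zeros(d)
        m_b = 0.0; u_b = 0.0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _ in range(cfg.epochs):
            for idx in np.array_split(rng.permutation(n), max(1, n // cfg.batch_size)):
                if len(idx) == 0:
                    continue
                t += 1
                p = _sigmoid(Xs[idx] @ w + b)
                err = p - y[idx]
                g_w = Xs[idx].T @ err / len(idx) + cfg.l2 * w
                g_b = float(err.mean())
                m_w = beta1 * m_w + (1 - beta1) * g_w
                u_w = np.maximum(beta2 * u_w, np.abs(g_w))
                m_b = beta1 * m_b + (1 - beta1) * g_b
                u_b = max(beta2 * u_b, abs(g_b))
                step = cfg.learning_rate / (1 - beta1**t)
                w -= step * m_w / (u_w + eps)
                b -= step * m_b / (u_b + eps)
        self._w, self._b = w, b
        return self

    def predict_proba(self, cohort: Cohort) -> np.ndarray:
        if self._w is None:
            raise NotFittedError("classifier has not been fit")
        X = np.stack([tile_features(cohort.get_tile(r)) for r in cohort])
        Xs = (X - self._mu) / self._sd
        return _sigmoid(Xs @ self._w + self._b)


def reference_classifier(config: TrainingConfig | None = None) -> ReferenceTileClassifier:
    """Factory for the shipped reference classifier."""
    return ReferenceTileClassifier(config)


# ---------------------------------------------------------------------------
# Ensemble training and contract conformance
# ---------------------------------------------------------------------------

AugmentationFn = Callable[[RGBTile, np.random.Generator], RGBTile]


def _augment_cohort(
    cohort: Cohort,
    augmentations: Sequence[AugmentationFn],
    rng: np.random.Generator,
    replicates: int = 1,
) -> Cohort:
    """Apply an augmentation chain to every tile (training-time only).

    With ``replicates > 1`` each tile contributes several independently
    augmented copies, which is how a static-dataset learner sees augmentation
    diversity that an epoch-wise pipeline would provide.
    """
    from .cohort import TileRecord  # local import to avoid cycle noise

    if not augmentations:
        return cohort
    records = []
    for r in cohort:
        for k in range(replicates):
            tile = cohort.get_tile(r)
            for fn in augmentations:
                tile = fn(tile, rng)
            records.append(
                TileRecord(
                    f"{r.tile_ref}#aug{k}", r.patient_id, r.label, r.domain,
                    r.case_id, tile,
                )
            )
    return Cohort(records, f"{cohort.name}/augmented")


def train_with_plan(
    classifier_factory: Callable[[TrainingConfig], TileClassifier],
    cohort: Cohort,
    plan: EnsemblePlan,
    augmentations: Sequence[AugmentationFn] = (),
    config: TrainingConfig | None = None,
    augment_replicates: int = 1,
) -> list[TileClassifier]:
    """Train one classifier per member plan on its subset-and-flipped cohort.

    The augmentation chain (HSV jitter and/or artifact injectors) is applied
    to training tiles only. Member seeds derive from the config seed and the
    member index, so the whole ensemble is reproducible.
    """
    cfg = config or TrainingConfig()
    trained: list[TileClassifier] = []
    for member in plan.members:
        member_cohort = apply_member_plan(cohort, member)
        ss = np.random.SeedSequence((cfg.seed, plan.seed, member.member_index))
        rng = np.random.default_rng(ss)
        member_cohort = _augment_cohort(
            member_cohort, augmentations, rng, augment_replicates
        )
        member_cfg = TrainingConfig(
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            optimizer_name=cfg.optimizer_name,
            loss_name=cfg.loss_name,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            batch_size=cfg.batch_size,
            l2=cfg.l2,
        )
        clf = classifier_factory(member_cfg)
        try:
            clf.fit(member_cohort, member_cfg)
        except Exception as exc:  # re-raise with the member attached
            raise RuntimeError(f"member {member.member_index} failed to train") from exc
        trained.append(clf)
    return trained


def check_classifier_contract(
    classifier_factory: Callable[[TrainingConfig], TileClassifier],
    train_cohort: Cohort,
    test_cohort: Cohort,
    config: TrainingConfig | None = None,
) -> None:
    """Verify a classifier satisfies the TileClassifier contract.

    Checks: predict-before-fit raises; probability vector length and bounds;
    determinism under an identical seed. Raises ContractViolation on the
    first failure; returns None when the contract holds.
    """
    cfg = config or TrainingConfig()

    fresh = classifier_factory(cfg)
    try:
        fresh.predict_proba(test_cohort)
    except Exception:
        pass
    else:
        raise ContractViolation("predict_proba before fit must raise")

    probs = []
    for _ in range(2):
        clf = classifier_factory(cfg)
        clf.fit(train_cohort, cfg)
        p = np.asarray(clf.predict_proba(test_cohort), dtype=float)
        if p.shape != (len(test_cohort),):
            raise ContractViolation(
                f"predict_proba must return one probability per tile; "
                f"got shape {p.shape} for {len(test_cohort)} tiles"
            )
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ContractViolation("probabilities must be finite and within [0, 1]")
        probs.append(p)
    if not np.array_equal(probs[0], probs[1]):
        raise ContractViolation("same data and seed must give identical predictions")
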