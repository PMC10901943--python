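"""Scanner/processing artifact injectors: blur, JPEG, brightness, contrast.

Each family emulates an institute-level image property: defocus (Gaussian
blur), on-disk compression (JPEG re-encoding), and slide/scanner illumination
(additive brightness, linear contrast about mid-gray). Injectors are
deterministic, shape-preserving and composable with stain normalization
(applied after it when both are configured).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.metrics import peak_signal_noise_ratio

from .image import RGBTile

FAMILIES = ("blur", "jpeg", "brightness", "contrast")

#: Sentinel PSNR reported when compression is lossless on a tile (PSNR -> inf).
PSNR_CAP = 100.0


class ArtifactConfigError(ValueError):
    """Unknown family or strength outside the family's valid range."""


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact at one strength.

    Strength semantics per family: ``blur`` — Gaussian sigma in pixels;
    ``jpeg`` — codec quality, integer in [1, 100]; ``brightness`` — additive
    offset in intensity levels; ``contrast`` — multiplicative factor about
    mid-gray 128.
    """

    family: str
    strength: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ArtifactConfigError(
                f"unknown artifact family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "blur" and self.strength < 0:
            raise ArtifactConfigError("blur sigma must be >= 0")
        if self.family == "jpeg":
            q = self.strength
            if q != int(q) or not 1 <= q <= 100:
                raise ArtifactConfigError(
                    f"jpeg quality must be an integer in [1, 100], got {q}"
                )
        if self.family == "contrast" and self.strength <= 0:
            raise ArtifactConfigError("contrast factor must be > 0")


def _blur(px: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return px.copy()
    out = np.empty_like(px, dtype=float)
    for ch in range(3):
        # truncate=3 gives kernel radius ceil(3*sigma); reflective border
        out[..., ch] = gaussian_filter(
            px[..., ch].astype(float), sigma=sigma, mode="reflect", truncate=3.0
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _jpeg(px: np.ndarray, quality: int) -> np.ndarray:
    buf = io.BytesIO()
    # chroma subsampling off at near-lossless quality so 100 ~ identity
    kwargs = {"subsampling": 0} if quality >= 95 else {}
    Image.fromarray(px, mode="RGB").save(buf, format="JPEG", quality=quality, **kwargs)
    buf.seek(0)
    with Image.open(buf) as img:
        return np.asarray(img.convert("RGB")).copy()


def apply_artifact(tile: RGBTile, spec: ArtifactSpec) -> RGBTile:
    """Apply one artifact; output has the tile's shape, dtype and metadata."""
    px = tile.pixels
    if spec.family == "blur":
        out = _blur(px, spec.strength)
    elif spec.family == "jpeg":
        out = _jpeg(px, int(spec.strength))
    elif spec.family == "brightness":
        out = np.clip(px.astype(float) + spec.strength, 0, 255).astype(np.uint8)
    elif spec.family == "contrast":
        out = np.clip(
            spec.strength * (px.astype(float) - 128.0) + 128.0, 0, 255
        ).astype(np.uint8)
    else:  # pragma: no cover - blocked by ArtifactSpec validation
        raise ArtifactConfigError(spec.family)
    return RGBTile(out, tile.microns_per_pixel)


def jpeg_roundtrip_distortion(tile: RGBTile, quality: int) -> float:
    """PSNR (dB) between a tile and its JPEG encode/decode at `quality`.

    Lossless round trips (e.g. constant-color tiles) would give infinite
    PSNR; those are reported as the cap ``PSNR_CAP``.
    """
    if not 1 <= quality <= 100:
        raise ArtifactConfigError(f"jpeg quality must be in [1, 100], got {quality}")
    decoded = _jpeg(tile.pixels, int(quality))
    if np.array_equal(decoded, tile.pixels):
        return PSNR_CAP
    psnr = peak_signal_noise_ratio(tile.pixels, decoded, data_range=255)
    return float(min(psnr, PSNR_CAP))


def artifact_sweep(family: str, strengths: list[float]) -> list[ArtifactSpec]:
    """Build an ordered list of specs, one per strength (validated)."""
    if len(strengths) == 0:
        raise ArtifactConfigError("strength sweep must be nonempty")
    return [ArtifactSpec(family, s) for s in strengths]


def neutral_strength(family: str) -> float:
    """The strength at which a family is the identity (codec tolerance for jpeg)."""
    return {"blur": 0.0, "jpeg": 100.0, "brightness": 0.0, "contrast": 1.0}[family]


def injector(spec: ArtifactSpec):
    """Adapt a spec to the ``(tile, rng) -> tile`` augmentation-chain signature."""

    def _apply(tile: RGBTile, rng: np.random.Generator | None = None) -> RGBTile:
        return apply_artifact(tile, spec)

    return _apply
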