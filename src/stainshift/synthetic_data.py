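"""Synthetic H&E-like two-stain tiles with a controlled class/domain split.

The generator is built so the two signals a transfer experiment cares about
are *orthogonal by construction*:

* the class signal is purely morphological — nucleus-like hematoxylin disks
  whose density and size differ between class 0 and class 1;
* the domain signal is purely colorimetric — each institute renders the same
  kind of concentration fields through its own stain matrix, background,
  brightness/contrast offset and pixel noise.

That separation is what makes stain normalization demonstrable: a color
transform can close the domain gap without touching the class signal. Tiles
render through the same Beer-Lambert model the stain module inverts, so the
generator doubles as a construction oracle for stain-vector recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .cohort import Cohort, TileRecord
from .image import RGBTile
from .stain import RUIFROK_EOSIN, RUIFROK_HEMATOXYLIN


@dataclass
class DomainStyle:
    """Everything colorimetric about one institute's rendering."""

    stain_matrix: np.ndarray                 # (3, 2) unit-norm nonnegative columns
    background: tuple[float, float, float] = (245.0, 245.0, 245.0)
    brightness_offset: float = 0.0
    contrast_factor: float = 1.0
    pixel_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        W = np.asarray(self.stain_matrix, dtype=float)
        if W.shape != (3, 2) or W.min() < 0:
            raise ValueError("stain_matrix must be 3x2 with nonnegative entries")
        norms = np.linalg.norm(W, axis=0)
        if np.any(np.abs(norms - 1) > 1e-6):
            raise ValueError("stain_matrix columns must be unit norm")
        bg = np.asarray(self.background, dtype=float)
        if np.any(bg < 200) or np.any(bg > 255):
            raise ValueError("background must lie in [200, 255] per channel")
        self.stain_matrix = W


@dataclass
class ClassMorphology:
    """The morphological knobs that carry the class signal."""

    nucleus_density: float          # expected disks per px^2
    nucleus_radius_range: tuple[float, float]  # px
    eosin_texture_scale: float = 0.15

    def __post_init__(self) -> None:
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        lo, hi = self.nucleus_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("nucleus radii must be positive with min <= max")


def _unit_columns(W: np.ndarray) -> np.ndarray:
    W = np.clip(np.asarray(W, dtype=float), 0.0, None)
    return W / np.linalg.norm(W, axis=0, keepdims=True)


def _rotate_about(v: np.ndarray, axis: np.ndarray, degrees: float) -> np.ndarray:
    """Rodrigues rotation of a 3-vector about a unit axis."""
    th = np.deg2rad(degrees)
    k = axis / np.linalg.norm(axis)
    return (
        v * np.cos(th) + np.cross(k, v) * np.sin(th) + k * (k @ v) * (1 - np.cos(th))
    )


def classic_stain_matrix() -> np.ndarray:
    """The canonical H&E stain matrix (unit columns, hematoxylin first)."""
    return _unit_columns(
        np.stack(
            [np.asarray(RUIFROK_HEMATOXYLIN, float), np.asarray(RUIFROK_EOSIN, float)],
            axis=1,
        )
    )


def shifted_stain_matrix(degrees: float = 15.0) -> np.ndarray:
    """The classic matrix with both stain vectors rotated in RGB-OD space.

    Rotation is about the axis normal to the hematoxylin-eosin plane, then
    clipped to the nonnegative orthant and renormalized — a compact model of
    a different scanner/lab color response.
    """
    W = classic_stain_matrix()
    axis = np.cross(W[:, 0], W[:, 1])
    return _unit_columns(
        np.stack(
            [_rotate_about(W[:, 0], axis, degrees),
             _rotate_about(W[:, 1], axis, degrees)],
            axis=1,
        )
    )


def default_styles() -> dict[str, DomainStyle]:
    """Two institutes: A (classic rendering) and B (rotated stains, warmer scanner)."""
    return {
        "A": DomainStyle(classic_stain_matrix()),
        "B": DomainStyle(
            shifted_stain_matrix(15.0),
            brightness_offset=10.0,
            contrast_factor=1.1,
        ),
    }


def default_morphologies() -> dict[int, ClassMorphology]:
    """Class 0: sparse large nuclei; class 1: dense smaller nuclei."""
    return {
        0: ClassMorphology(nucleus_density=0.0015, nucleus_radius_range=(3.0, 6.0)),
        1: ClassMorphology(nucleus_density=0.0045, nucleus_radius_range=(2.0, 5.0)),
    }


# ---------------------------------------------------------------------------
# Two-stage rendering: concentrations then color
# ---------------------------------------------------------------------------

def sample_concentrations(
    label: int,
    morph: ClassMorphology,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an ``(H, W, 2)`` concentration field for one tile.

    Hematoxylin: a Poisson number of disks (nuclei) at the class's density
    and radius range, each with its own absorption amplitude, over a faint
    diffuse floor. Eosin: a smooth Gaussian-filtered random texture
    (cytoplasm/stroma), identical in distribution across classes and
    suppressed inside nuclei (chromatin displaces cytoplasm, which is also
    what makes the two stain directions identifiable from pixels).
    """
    yy, xx = np.mgrid[0:size, 0:size]
    hema = np.full((size, size), 0.05)
    n_disks = rng.poisson(morph.nucleus_density * size * size)
    for _ in range(n_disks):
        cy, cx = rng.uniform(0, size, size=2)
        r = rng.uniform(*morph.nucleus_radius_range)
        amp = rng.uniform(0.7, 1.1)
        hema[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] += amp
    hema = np.clip(hema, 0.0, 1.6)

    noise = rng.normal(0.0, 1.0, (size, size))
    smooth = gaussian_filter(noise, sigma=8.0, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    eosin = np.clip(0.4 + morph.eosin_texture_scale * smooth, 0.0, None)
    eosin = eosin * np.where(hema > 0.3, 0.12, 1.0)  # nuclei displace cytoplasm
    return np.stack([hema, eosin], axis=2)


def render_tile(
    concentrations: np.ndarray,
    style: DomainStyle,
    rng: np.random.Generator,
) -> RGBTile:
    """Render a concentration field through a domain's color pipeline."""
    od = concentrations @ style.stain_matrix.T          # (H, W, 3)
    px = np.asarray(style.background) * np.power(10.0, -od)
    px = style.contrast_factor * (px - 128.0) + 128.0
    px = px + style.brightness_offset
    if style.pixel_noise_sd > 0:
        px = px + rng.normal(0.0, style.pixel_noise_sd, px.shape)
    return RGBTile(np.clip(np.rint(px), 0, 255).astype(np.uint8))


def disk_pixel_fraction(concentrations: np.ndarray, threshold: float = 0.3) -> float:
    """Fraction of pixels inside a nucleus disk (hematoxylin above threshold)."""
    return float((concentrations[..., 0] > threshold).mean())


def generate_tile(
    label: int,
    style: DomainStyle,
    morph_by_class: dict[int, ClassMorphology] | None = None,
    size: int = 96,
    rng: np.random.Generator | None = None,
) -> RGBTile:
    """Draw one labeled tile in one domain's style. Deterministic given rng."""
    morph_by_class = morph_by_class or default_morphologies()
    if morph_by_class[0] == morph_by_class[1]:
        warnings.warn(
            "class morphologies are identical; classes will be unlearnable",
            stacklevel=2,
        )
    rng = rng or np.random.default_rng()
    conc = sample_concentrations(label, morph_by_class[label], size, rng)
    return render_tile(conc, style, rng)


def _perturb(morph: ClassMorphology, rng: np.random.Generator, sd: float) -> ClassMorphology:
    """Per-patient morphological jitter (color untouched, so domain stays pure)."""
    dens = morph.nucleus_density * float(np.exp(rng.normal(0.0, sd)))
    rscale = float(np.exp(rng.normal(0.0, sd / 2)))
    lo, hi = morph.nucleus_radius_range
    return ClassMorphology(dens, (lo * rscale, hi * rscale), morph.eosin_texture_scale)


def generate_cohort(
    n_patients: int = 20,
    tiles_per_patient_per_class: int = 4,
    styles: dict[str, DomainStyle] | None = None,
    patient_effect_sd: float = 0.1,
    seed: int = 0,
    size: int = 96,
    morphologies: dict[int, ClassMorphology] | None = None,
    name: str | None = None,
) -> Cohort:
    """Generate a multi-institute cohort: ``n_patients`` per domain, balanced labels.

    Every patient belongs to exactly one domain and carries a small random
    morphology perturbation (the patient effect); all of a patient's tiles
    come from one synthetic slide (case). Fully deterministic under ``seed``.
    """
    if tiles_per_patient_per_class < 1:
        raise ValueError("tiles_per_patient_per_class must be >= 1")
    if n_patients < 2:
        raise ValueError("need at least 2 patients per domain")
    styles = styles or default_styles()
    morphologies = morphologies or default_morphologies()

    records: list[TileRecord] = []
    root = np.random.SeedSequence(seed)
    domain_seqs = root.spawn(len(styles))
    for (domain, style), dseq in zip(sorted(styles.items()), domain_seqs):
        for p, pseq in enumerate(dseq.spawn(n_patients)):
            rng = np.random.default_rng(pseq)
            patient = f"{domain}-P{p:03d}"
            morphs = {c: _perturb(m, rng, patient_effect_sd) for c, m in morphologies.items()}
            for label in (0, 1):
                for k in range(tiles_per_patient_per_class):
                    tile = generate_tile(label, style, morphs, size, rng)
                    records.append(
                        TileRecord(
                            tile_ref=f"{patient}/c{label}_t{k}.png",
                            patient_id=patient,
                            label=label,
                            domain=domain,
                            case_id=f"{patient}-S1",
                            tile=tile,
                        )
                    )
    return Cohort(records, name or f"synthetic-{'-'.join(sorted(styles))}")


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write tiles as PNGs plus a manifest.csv into ``out_dir``."""
    from pathlib import Path

    from .cohort import write_manifest
    from .image import write_tile

    out = Path(out_dir)
    new_records = []
    for r in cohort:
        path = out / r.tile_ref
        path.parent.mkdir(parents=True, exist_ok=True)
        write_tile(cohort.get_tile(r), path)
        new_records.append(
            TileRecord(str(path), r.patient_id, r.label, r.domain, r.case_id, split=r.split)
        )
    write_manifest(Cohort(new_records, cohort.name), out / "manifest.csv")
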