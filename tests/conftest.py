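import numpy as np
import pytest

from stainshift.cohort import Cohort, TileRecord
from stainshift.image import RGBTile
from stainshift.synthetic_data import (
    default_morphologies,
    default_styles,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def checker_tile():
    """A small deterministic non-constant tile (checkerboard + gradient)."""
    size = 64
    yy, xx = np.mgrid[0:size, 0:size]
    px = np.zeros((size, size, 3))
    px[..., 0] = 255 * ((yy // 8 + xx // 8) % 2)
    px[..., 1] = np.linspace(0, 255, size)[None, :]
    px[..., 2] = 128
    return RGBTile(px.astype(np.uint8))


@pytest.fixture
def he_tile():
    """A synthetic H&E-like tile rendered in the classic (domain A) style."""
    from stainshift.synthetic_data import generate_tile

    return generate_tile(1, default_styles()["A"], rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def planner_cohort():
    """20 patients x 10 tiles x 2 classes = 400 records, no pixels needed."""
    records = [
        TileRecord(
            tile_ref=f"P{p:02d}/c{c}_t{t}.png",
            patient_id=f"P{p:02d}",
            label=c,
            domain="A",
            case_id=f"P{p:02d}-S1",
        )
        for p in range(20)
        for c in (0, 1)
        for t in range(10)
    ]
    return Cohort(records, "planner-fixture")


@pytest.fixture(scope="session")
def small_two_domain():
    """Small paired cohorts (one per institute) for unit-scale experiments."""
    styles = default_styles()
    internal = generate_cohort(6, 2, {"A": styles["A"]}, seed=21, size=64)
    external = generate_cohort(6, 2, {"B": styles["B"]}, seed=22, size=64)
    return internal, external
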