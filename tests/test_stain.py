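import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stainshift.image import RGBTile, ShapeError
from stainshift.stain import (
    ConcentrationMap,
    DegenerateStainMatrixError,
    InsufficientTissueError,
    ODImage,
    SparseFactorizationConfig,
    StainProfile,
    channel_histogram_distance,
    compute_concentrations,
    estimate_stain_profile,
    hsv_augment,
    normalize_to_reference,
    od_to_rgb,
    rgb_to_od,
)
from stainshift.synthetic_data import (
    DomainStyle,
    classic_stain_matrix,
    default_morphologies,
    render_tile,
    sample_concentrations,
    shifted_stain_matrix,
)


def _pure_style(W, noise=0.0):
    return DomainStyle(W, background=(255.0, 255.0, 255.0), pixel_noise_sd=noise)


def _he_pixels(W, seed, noise=0.0, label=1, size=96):
    rng = np.random.default_rng(seed)
    conc = sample_concentrations(label, default_morphologies()[label], size, rng)
    return conc, render_tile(conc, _pure_style(W, noise), rng)


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------

class TestOpticalDensity:
    def test_background_pixel_maps_to_zero_density(self):
        tile = RGBTile(np.full((2, 2, 3), 255, dtype=np.uint8))
        od = rgb_to_od(tile)
        assert np.allclose(od.values, 0.0)

    def test_black_pixel_clamps_at_one_before_log(self):
        tile = RGBTile(np.zeros((1, 1, 3), dtype=np.uint8))
        od = rgb_to_od(tile)
        assert np.allclose(od.values, np.log10(255.0), atol=1e-6)

    def test_unit_density_renders_to_26(self):
        od = ODImage(np.ones((1, 1, 3)), np.full(3, 255.0))
        tile = od_to_rgb(od)
        assert np.all(tile.pixels == 26)  # round(255 * 10**-1)

    def test_zero_density_renders_background(self):
        od = ODImage(np.zeros((2, 2, 3)), np.full(3, 255.0))
        assert np.all(od_to_rgb(od).pixels == 255)

    def test_negative_density_rejected(self):
        od = ODImage(np.zeros((1, 1, 3)), np.full(3, 255.0))
        od.values = od.values - 0.5  # bypass constructor check
        with pytest.raises(ValueError):
            od_to_rgb(od)

    def test_invalid_background_rejected(self):
        tile = RGBTile(np.full((1, 1, 3), 100, dtype=np.uint8))
        with pytest.raises(ValueError):
            rgb_to_od(tile, background=(0.5, 255, 255))

    def test_non_rgb_input_rejected(self):
        with pytest.raises(ShapeError):
            ODImage(np.zeros((3, 3)), np.full(3, 255.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(
            np.uint8,
            st.tuples(st.integers(1, 6), st.integers(1, 6), st.just(3)),
            elements=st.integers(1, 255),
        )
    )
    def test_roundtrip_within_one_level_for_nonzero_pixels(self, px):
        tile = RGBTile(px)
        back = od_to_rgb(rgb_to_od(tile))
        assert np.max(np.abs(back.pixels.astype(int) - tile.pixels.astype(int))) <= 1


# ---------------------------------------------------------------------------
# Stain-matrix estimation
# ---------------------------------------------------------------------------

class TestStainEstimation:
    @pytest.mark.parametrize(
        "W_true", [classic_stain_matrix(), shifted_stain_matrix(15.0)],
        ids=["classic", "rotated15"],
    )
    def test_recovers_known_stain_vectors(self, W_true):
        """Construction oracle: tiles rendered from known unit vectors with
        pixel noise of 2 levels must give back both columns at cosine >= 0.99."""
        _, tile = _he_pixels(W_true, seed=5, noise=2.0)
        profile = estimate_stain_profile(tile, SparseFactorizationConfig(seed=0))
        for j in range(2):
            cos = abs(profile.stain_matrix[:, j] @ W_true[:, j])
            assert cos >= 0.99, f"column {j} cosine {cos:.4f}"

    def test_all_white_tile_raises_insufficient_tissue(self):
        tile = RGBTile(np.full((64, 64, 3), 255, dtype=np.uint8))
        with pytest.raises(InsufficientTissueError):
            estimate_stain_profile(tile)

    def test_same_tile_same_seed_identical_profile(self):
        _, tile = _he_pixels(classic_stain_matrix(), seed=9, noise=2.0)
        cfg = SparseFactorizationConfig(seed=3)
        p1 = estimate_stain_profile(tile, cfg)
        p2 = estimate_stain_profile(tile, cfg)
        assert np.array_equal(p1.stain_matrix, p2.stain_matrix)
        assert np.array_equal(p1.concentration_scale, p2.concentration_scale)

    def test_hematoxylin_column_is_first(self):
        _, tile = _he_pixels(classic_stain_matrix(), seed=5)
        W = estimate_stain_profile(tile).stain_matrix
        # hematoxylin-like column absorbs more red+blue (relative)
        assert W[0, 0] + W[2, 0] > W[0, 1] + W[2, 1]

    def test_profile_invariants(self):
        _, tile = _he_pixels(shifted_stain_matrix(15.0), seed=6, noise=2.0)
        p = estimate_stain_profile(tile)
        assert np.allclose(np.linalg.norm(p.stain_matrix, axis=0), 1.0, atol=1e-6)
        assert p.stain_matrix.min() >= 0
        assert np.all(p.concentration_scale > 0)

    def test_agrees_with_sklearn_dictionary_learning(self):
        """Independent cross-check: sklearn's sparse dictionary learning on the
        same pixel cloud finds the same stain directions (after matching)."""
        from sklearn.decomposition import DictionaryLearning

        W_true = classic_stain_matrix()
        _, tile = _he_pixels(W_true, seed=11, noise=1.0, size=64)
        cfg = SparseFactorizationConfig(seed=0, max_pixels_for_fit=1500)
        ours = estimate_stain_profile(tile, cfg).stain_matrix

        od = rgb_to_od(tile)
        mask = od.values.max(axis=2) > cfg.od_tissue_threshold
        X = od.values[mask]
        X = X[np.sort(np.random.default_rng(0).choice(len(X), 1500, replace=False))]
        dl = DictionaryLearning(
            n_components=2, alpha=0.1, fit_algorithm="cd",
            transform_algorithm="lasso_cd", positive_code=True,
            positive_dict=True, max_iter=30, random_state=0,
        ).fit(X)
        theirs = dl.components_.T
        theirs = theirs / np.linalg.norm(theirs, axis=0, keepdims=True)
        # match columns by best cosine, then require agreement
        cos = np.abs(ours.T @ theirs)
        best = cos.max(axis=1)
        assert np.all(best >= 0.97), f"cross-check cosines {best}"


# ---------------------------------------------------------------------------
# Concentrations
# ---------------------------------------------------------------------------

class TestConcentrations:
    def test_exact_recovery_without_regularization(self):
        rng = np.random.default_rng(0)
        W = classic_stain_matrix()
        C = rng.gamma(2.0, 0.4, (16, 16, 2))
        od = ODImage(C @ W.T, np.full(3, 255.0))
        got = compute_concentrations(od, W, regularization=0.0)
        assert np.abs(got.values - C).max() <= 1e-6

    def test_zero_density_gives_zero_concentration(self):
        W = classic_stain_matrix()
        od = ODImage(np.zeros((4, 4, 3)), np.full(3, 255.0))
        assert np.all(compute_concentrations(od, W).values == 0)

    def test_nonnegative_for_arbitrary_valid_input(self, rng):
        W = shifted_stain_matrix(10.0)
        od = ODImage(rng.uniform(0, 1.5, (8, 8, 3)), np.full(3, 255.0))
        for reg in (0.0, 0.05):
            assert compute_concentrations(od, W, reg).values.min() >= 0

    def test_parallel_columns_raise_degeneracy_error(self):
        v = np.array([0.6, 0.7, 0.39])
        v = v / np.linalg.norm(v)
        W = np.stack([v, v], axis=1)
        od = ODImage(np.ones((2, 2, 3)) * 0.5, np.full(3, 255.0))
        with pytest.raises(DegenerateStainMatrixError):
            compute_concentrations(od, W)

    def test_regularization_shrinks_total_concentration(self, rng):
        W = classic_stain_matrix()
        od = ODImage(rng.uniform(0, 1.0, (8, 8, 3)), np.full(3, 255.0))
        loose = compute_concentrations(od, W, 0.0).values.sum()
        tight = compute_concentrations(od, W, 0.2).values.sum()
        assert tight < loose


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_reference_normalized_to_itself_is_nearly_unchanged(self):
        _, tile = _he_pixels(classic_stain_matrix(), seed=5, noise=2.0)
        cfg = SparseFactorizationConfig(seed=0)
        ref = estimate_stain_profile(tile, cfg)
        out = normalize_to_reference(tile, ref, cfg)
        diff = np.abs(out.pixels.astype(float) - tile.pixels.astype(float)).mean()
        assert diff <= 2.0

    def test_two_renderings_converge_under_shared_reference(self):
        """One concentration field rendered under two stain matrices must land
        on (nearly) the same image after normalization to a common reference."""
        rng = np.random.default_rng(5)
        conc = sample_concentrations(1, default_morphologies()[1], 96, rng)
        tA = render_tile(conc, _pure_style(classic_stain_matrix()), np.random.default_rng(1))
        tB = render_tile(conc, _pure_style(shifted_stain_matrix(15.0)), np.random.default_rng(2))
        cfg = SparseFactorizationConfig(seed=0)
        ref = estimate_stain_profile(tA, cfg)
        nA = normalize_to_reference(tA, ref, cfg)
        nB = normalize_to_reference(tB, ref, cfg)
        diff = np.abs(nA.pixels.astype(float) - nB.pixels.astype(float)).mean()
        assert diff <= 2.0

    def test_near_idempotence(self):
        _, tA = _he_pixels(classic_stain_matrix(), seed=5)
        _, tB = _he_pixels(shifted_stain_matrix(15.0), seed=6)
        cfg = SparseFactorizationConfig(seed=0)
        ref = estimate_stain_profile(tA, cfg)
        once = normalize_to_reference(tB, ref, cfg)
        twice = normalize_to_reference(once, ref, cfg)
        diff = np.abs(twice.pixels.astype(float) - once.pixels.astype(float)).mean()
        assert diff <= 2.0

    def test_normalization_reduces_domain_color_distance(self):
        """For domains differing only in stain matrix, the channel-histogram
        distance between institutes strictly decreases after normalization."""
        cfg = SparseFactorizationConfig(seed=0)
        tilesA, tilesB = [], []
        for s in range(3):
            _, tA = _he_pixels(classic_stain_matrix(), seed=30 + s, label=s % 2)
            _, tB = _he_pixels(shifted_stain_matrix(15.0), seed=60 + s, label=s % 2)
            tilesA.append(tA)
            tilesB.append(tB)
        ref = estimate_stain_profile(tilesA[0], cfg)
        nA = [normalize_to_reference(t, ref, cfg) for t in tilesA]
        nB = [normalize_to_reference(t, ref, cfg) for t in tilesB]
        before = channel_histogram_distance(tilesA, tilesB)
        after = channel_histogram_distance(nA, nB)
        assert after < before

    def test_output_matches_input_shape_and_dtype(self, he_tile):
        cfg = SparseFactorizationConfig(seed=0)
        ref = estimate_stain_profile(he_tile, cfg)
        out = normalize_to_reference(he_tile, ref, cfg)
        assert out.pixels.shape == he_tile.pixels.shape
        assert out.pixels.dtype == he_tile.pixels.dtype

    def test_tissue_free_tile_raises_or_passes_through(self, he_tile):
        ref = estimate_stain_profile(he_tile)
        blank = RGBTile(np.full((64, 64, 3), 255, dtype=np.uint8))
        with pytest.raises(InsufficientTissueError):
            normalize_to_reference(blank, ref)
        with pytest.warns(UserWarning):
            out = normalize_to_reference(
                blank, ref, pass_through_on_insufficient_tissue=True
            )
        assert np.array_equal(out.pixels, blank.pixels)


# ---------------------------------------------------------------------------
# HSV augmentation
# ---------------------------------------------------------------------------

class TestHSVAugment:
    def test_identity_ranges_reproduce_input(self, he_tile):
        out = hsv_augment(
            he_tile, hue_shift=(0, 0), sat_factor=(1, 1), val_factor=(1, 1),
            rng=np.random.default_rng(0),
        )
        assert np.max(np.abs(out.pixels.astype(int) - he_tile.pixels.astype(int))) <= 1

    def test_deterministic_under_seed(self, he_tile):
        a = hsv_augment(he_tile, rng=np.random.default_rng(5))
        b = hsv_augment(he_tile, rng=np.random.default_rng(5))
        assert np.array_equal(a.pixels, b.pixels)

    def test_half_circle_shift_turns_red_into_cyan(self):
        red = RGBTile(np.tile(np.array([200, 0, 0], dtype=np.uint8), (4, 4, 1)))
        out = hsv_augment(
            red, hue_shift=(0.5, 0.5), sat_factor=(1, 1), val_factor=(1, 1),
            rng=np.random.default_rng(0),
        )
        from skimage.color import rgb2hsv

        hue = rgb2hsv(out.pixels.astype(float) / 255.0)[..., 0]
        assert np.allclose(hue, 0.5, atol=0.01)


def test_stain_profile_json_roundtrip():
    p = StainProfile(classic_stain_matrix(), np.array([1.2, 0.8]))
    q = StainProfile.from_dict(p.to_dict())
    assert np.allclose(p.stain_matrix, q.stain_matrix)
    assert np.allclose(p.concentration_scale, q.concentration_scale)
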