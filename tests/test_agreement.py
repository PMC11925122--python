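import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sozdensity import agreement, synthetic
from sozdensity.agreement import (
    AgreementError,
    AnnotationMask,
    UndefinedKappaError,
    cohen_kappa,
    intra_rater_kappa,
    kappa_matrix,
    overlaps_clinical,
    pairwise_kappa,
    rasterize_polygons,
    scorer_mean_kappa,
)


def _mask(px, **kw):
    return AnnotationMask(np.asarray(px, dtype=np.uint8), **kw)


class TestRasterize:
    def test_square_covers_exact_pixel_block(self):
        ring = np.array([[5, 5], [15, 5], [15, 15], [5, 15]], float)
        m = rasterize_polygons([ring], (30, 30))
        assert m.area_px == 100
        assert m.pixels[5:15, 5:15].all()

    def test_empty_polygon_list_all_zero(self):
        m = rasterize_polygons([], (20, 20))
        assert m.area_px == 0

    def test_multiple_rings_are_ored(self):
        r1 = np.array([[1, 1], [5, 1], [5, 5], [1, 5]], float)
        r2 = np.array([[10, 10], [14, 10], [14, 14], [10, 14]], float)
        m = rasterize_polygons([r1, r2], (20, 20))
        assert m.area_px == 32

    def test_random_polygon_matches_shapely_oracle(self):
        from shapely.geometry import Point, Polygon

        rng = np.random.default_rng(12)
        # star-shaped random simple polygon around (15, 15)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 11))
        radii = rng.uniform(4, 13, 11)
        ring = np.column_stack(
            [15 + radii * np.cos(angles), 15 + radii * np.sin(angles)]
        )
        m = rasterize_polygons([ring], (30, 30))
        poly = Polygon(ring)
        for r in range(30):
            for c in range(30):
                expected = poly.contains(Point(c + 0.5, r + 0.5))
                assert bool(m.pixels[r, c]) == expected, (r, c)

    def test_self_intersecting_ring_warns_even_odd(self):
        bowtie = np.array([[2, 2], [10, 10], [10, 2], [2, 10]], float)
        with pytest.warns(UserWarning):
            m = rasterize_polygons([bowtie], (12, 12))
        assert m.area_px > 0

    def test_out_of_bounds_vertices_clipped(self):
        ring = np.array([[-5, -5], [40, -5], [40, 40], [-5, 40]], float)
        m = rasterize_polygons([ring], (20, 20))
        assert m.area_px == 400  # whole raster

    def test_degenerate_ring_rejected(self):
        with pytest.raises(AgreementError):
            rasterize_polygons([np.array([[0, 0], [1, 1]], float)], (5, 5))


class TestCohenKappa:
    def test_identical_masks_kappa_one(self):
        m = _mask(np.pad(np.ones((3, 3), np.uint8), 2))
        assert cohen_kappa(m, m) == pytest.approx(1.0)

    def test_complementary_halves_kappa_minus_one(self):
        a = np.zeros((4, 10), np.uint8)
        b = np.zeros((4, 10), np.uint8)
        a[:, :5] = 1
        b[:, 5:] = 1
        assert cohen_kappa(_mask(a), _mask(b)) == pytest.approx(-1.0)

    def test_contingency_arithmetic(self):
        # N=100: n11=20, n10=10, n01=10, n00=60 -> kappa = 0.22/0.42
        a = np.zeros(100, np.uint8)
        b = np.zeros(100, np.uint8)
        a[:30] = 1  # 20 shared + 10 a-only
        b[:20] = 1
        b[30:40] = 1
        k = cohen_kappa(_mask(a.reshape(10, 10)), _mask(b.reshape(10, 10)))
        assert k == pytest.approx(0.22 / 0.42)

    def test_both_empty_undefined(self):
        z = np.zeros((5, 5), np.uint8)
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(_mask(z), _mask(z))

    def test_both_full_undefined(self):
        o = np.ones((5, 5), np.uint8)
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(_mask(o), _mask(o))

    def test_mismatched_rasters_rejected(self):
        with pytest.raises(AgreementError):
            cohen_kappa(_mask(np.zeros((4, 4))), _mask(np.zeros((5, 5))))

    def test_exhaustive_small_masks_match_sklearn(self):
        """Closed-form contingency kappa vs sklearn on all 2x2 mask pairs."""
        from sklearn.metrics import cohen_kappa_score

        patterns = list(itertools.product([0, 1], repeat=4))
        for pa, pb in itertools.product(patterns, repeat=2):
            a = np.array(pa, np.uint8).reshape(2, 2)
            b = np.array(pb, np.uint8).reshape(2, 2)
            try:
                k = cohen_kappa(_mask(a), _mask(b))
            except UndefinedKappaError:
                continue
            ref = cohen_kappa_score(a.ravel(), b.ravel())
            assert k == pytest.approx(ref, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = _mask(rng.integers(0, 2, (6, 6)))
        b = _mask(rng.integers(0, 2, (6, 6)))
        try:
            kab = cohen_kappa(a, b)
        except UndefinedKappaError:
            return
        assert kab == cohen_kappa(b, a)
        assert -1.0 - 1e-12 <= kab <= 1.0 + 1e-12

    def test_padding_changes_kappa(self):
        """Chance correction depends on the raster: padding with shared
        negatives shifts p_e, so kappa is NOT padding-invariant."""
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[:2, :2] = 1
        b[1:3, 1:3] = 1
        k_small = cohen_kappa(_mask(a), _mask(b))
        k_padded = cohen_kappa(_mask(np.pad(a, 8)), _mask(np.pad(b, 8)))
        assert k_small != pytest.approx(k_padded)


class TestPairwiseAndIntra:
    def _scorer_masks(self, n, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for s in range(n):
            px = np.zeros((8, 8), np.uint8)
            px[rng.integers(0, 4):rng.integers(5, 8),
               rng.integers(0, 4):rng.integers(5, 8)] = 1
            out.append(_mask(px, scorer_id=f"s{s}", seizure_id="sz0",
                             condition="HD"))
        return out

    def test_six_scorers_fifteen_pairs(self):
        res = pairwise_kappa(self._scorer_masks(6))
        assert len(res) == 15

    def test_two_scorers_one_pair(self):
        assert len(pairwise_kappa(self._scorer_masks(2))) == 1

    def test_single_scorer_rejected(self):
        with pytest.raises(AgreementError):
            pairwise_kappa(self._scorer_masks(1))

    def test_matrix_symmetric_unit_diagonal(self):
        mat = kappa_matrix(self._scorer_masks(5))
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T, equal_nan=True)

    def test_undefined_propagates_as_missing(self):
        masks = self._scorer_masks(2)
        empty_a = _mask(np.zeros((8, 8)), scorer_id="e1")
        empty_b = _mask(np.zeros((8, 8)), scorer_id="e2")
        res = pairwise_kappa([empty_a, empty_b])
        assert res[0].kappa is None

    def test_intra_rater_identical_is_one(self):
        hd = _mask(np.pad(np.ones((3, 3), np.uint8), 2),
                   scorer_id="s0", condition="HD")
        ld = _mask(np.pad(np.ones((3, 3), np.uint8), 2),
                   scorer_id="s0", condition="LD")
        assert intra_rater_kappa(hd, ld).kappa == pytest.approx(1.0)

    def test_nested_double_area_kappa_below_one(self):
        big = np.zeros((20, 20), np.uint8)
        small = np.zeros((20, 20), np.uint8)
        big[5:13, 5:15] = 1    # 80 px
        small[5:13, 5:10] = 1  # 40 px, strictly inside
        k = intra_rater_kappa(
            _mask(big, scorer_id="s0"), _mask(small, scorer_id="s0")
        ).kappa
        assert k is not None and 0 < k < 1

    def test_different_scorers_rejected(self):
        a = _mask(np.ones((2, 2)), scorer_id="s0")
        b = _mask(np.ones((2, 2)), scorer_id="s1")
        with pytest.raises(AgreementError):
            intra_rater_kappa(a, b)

    def test_zero_jitter_simulated_scorers_intra_kappa_one(self, true_disc_mask):
        cfg = synthetic.ScorerSimConfig(
            boundary_jitter_px=0.0, area_log_multiplier_hd=0.0,
            scorer_bias_sd=0.0, seed=5,
        )
        hd = synthetic.simulate_scorer_annotations(true_disc_mask, "HD", cfg)
        ld = synthetic.simulate_scorer_annotations(true_disc_mask, "LD", cfg)
        for mh, ml in zip(hd, ld):
            assert intra_rater_kappa(mh, ml).kappa == pytest.approx(1.0)


class TestOverlapAndMeans:
    def test_disjoint_masks_false(self):
        a = np.zeros((6, 6), np.uint8)
        b = np.zeros((6, 6), np.uint8)
        a[0, 0] = 1
        b[5, 5] = 1
        assert overlaps_clinical(_mask(a), _mask(b)) is False

    def test_single_shared_pixel_true(self):
        a = np.zeros((6, 6), np.uint8)
        b = np.zeros((6, 6), np.uint8)
        a[2, 2] = 1
        b[2, 2] = 1
        b[3, 3] = 1
        assert overlaps_clinical(_mask(a), _mask(b)) is True

    def test_simulated_cohort_overlap_rate_high(self, true_disc_mask):
        """Jittered scorers nearly always hit the true SOZ region."""
        hits = total = 0
        for seed in range(12):
            cfg = synthetic.ScorerSimConfig(seed=seed, n_scorers=3)
            for m in synthetic.simulate_scorer_annotations(
                true_disc_mask, "HD", cfg
            ):
                hits += overlaps_clinical(m, true_disc_mask)
                total += 1
        assert hits / total > 0.9

    def test_mean_kappa_constant_case(self):
        res = [
            agreement.KappaResult("a", "b", "sz", "HD", 0.4),
            agreement.KappaResult("a", "c", "sz", "HD", 0.4),
        ]
        assert scorer_mean_kappa(res, "a") == pytest.approx(0.4)

    def test_mean_kappa_matches_matrix_row_average(self):
        rng = np.random.default_rng(21)
        masks = []
        for s in range(6):
            px = np.zeros((10, 10), np.uint8)
            px[rng.integers(0, 5):rng.integers(6, 10),
               rng.integers(0, 5):rng.integers(6, 10)] = 1
            masks.append(_mask(px, scorer_id=f"s{s}"))
        res = pairwise_kappa(masks)
        mat = kappa_matrix(masks)
        for i in range(6):
            per_scorer = [
                r.kappa for r in res if f"s{i}" in (r.scorer_a, r.scorer_b)
            ]
            assert len(per_scorer) == 5
            row = np.delete(mat[i], i)
            assert scorer_mean_kappa(res, f"s{i}") == pytest.approx(
                np.nanmean(row)
            )


class TestMaskIO:
    def test_png_json_roundtrip(self, tmp_path):
        px = np.zeros((10, 12), np.uint8)
        px[2:5, 3:8] = 1
        m = _mask(px, scorer_id="s1", seizure_id="sz3", condition="LD",
                  confidence=4, multifocal=True)
        agreement.save_mask(m, tmp_path / "m.png")
        back = agreement.load_mask(tmp_path / "m.png")
        assert np.array_equal(back.pixels, m.pixels)
        assert back.scorer_id == "s1" and back.condition == "LD"
        assert back.confidence == 4 and back.multifocal is True
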