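"""Probability fusion, contour extraction and planimetry."""

import math

import numpy as np
import pytest

from annuseg.core import (
    AnnulusContour,
    Measurement,
    NoAnnulusDetectedError,
    OpenContourError,
    ProbabilityMap,
    StageError,
    ValidationError,
)
from annuseg.detect import detect, extract_contour, fuse_probability_maps, measure_contour
from annuseg.model import ModelConfig, build_model, train
from annuseg.phantom import PhantomSpec, ellipse_contour, ellipse_perimeter, generate_phantom

from conftest import disc_probability_map, regular_polygon


def const_map(value, n=128, spacing=0.5, origin=(0.0, 0.0)):
    return ProbabilityMap(np.full((n, n), value, dtype=float), (spacing, spacing), origin)


class TestFusion:
    def test_identical_maps_identity(self):
        m = disc_probability_map(10)
        fused = fuse_probability_maps(m, m)
        np.testing.assert_allclose(fused.values, m.values, atol=1e-12)

    def test_mean_of_extremes(self):
        # fine all ones, coarse all zeros, concentric grids
        coarse = const_map(0.0, n=128, spacing=1.0, origin=(0.0, 0.0))
        fine = const_map(1.0, n=128, spacing=0.5, origin=(31.75, 31.75))
        fused = fuse_probability_maps(coarse, fine)
        np.testing.assert_allclose(fused.values, 0.5, atol=1e-12)
        assert fused.spacing == fine.spacing

    @pytest.mark.parametrize("c, d", [(0.2, 0.6), (0.9, 0.1), (0.5, 0.5)])
    def test_constants_fuse_to_midpoint(self, c, d):
        coarse = const_map(c, n=128, spacing=1.0, origin=(0.0, 0.0))
        fine = const_map(d, n=128, spacing=0.5, origin=(31.75, 31.75))
        fused = fuse_probability_maps(coarse, fine)
        np.testing.assert_allclose(fused.values, (c + d) / 2.0, atol=1e-12)

    def test_non_concentric_rejected(self):
        coarse = const_map(0.5, n=128, spacing=1.0, origin=(0.0, 0.0))
        fine = const_map(0.5, n=128, spacing=0.5, origin=(0.0, 0.0))
        with pytest.raises(ValidationError, match="concentric"):
            fuse_probability_maps(coarse, fine)

    def test_symmetry_on_shared_grid(self):
        rng = np.random.default_rng(0)
        a = ProbabilityMap(rng.uniform(size=(64, 64)), (0.5, 0.5), (0.0, 0.0))
        b = ProbabilityMap(rng.uniform(size=(64, 64)), (0.5, 0.5), (0.0, 0.0))
        ab = fuse_probability_maps(a, b)
        ba = fuse_probability_maps(b, a)
        np.testing.assert_allclose(ab.values, ba.values, atol=1e-12)

    def test_minmax_mode_rescales(self):
        coarse = const_map(0.0, n=128, spacing=1.0, origin=(0.0, 0.0))
        vals = np.zeros((128, 128))
        vals[40:60, 40:60] = 0.4  # peak below 0.5
        fine = ProbabilityMap(vals, (0.5, 0.5), (31.75, 31.75))
        fused = fuse_probability_maps(coarse, fine, mode="minmax")
        assert fused.values.max() == pytest.approx(0.5)  # 0.4 rescaled to 1, then averaged


class TestExtractContour:
    def test_disc_area_within_2_percent(self):
        prob = disc_probability_map(10.0)
        contour = extract_contour(prob)
        assert contour.area() == pytest.approx(math.pi * 100, rel=0.02)
        assert contour.signed_area() > 0  # counterclockwise

    def test_largest_loop_wins(self):
        big = disc_probability_map(10.0, center=(20.0, 20.0)).values
        small = disc_probability_map(3.0, center=(48.0, 48.0)).values
        prob = ProbabilityMap(np.maximum(big, small), (0.5, 0.5), (0.0, 0.0))
        contour = extract_contour(prob)
        assert contour.area() == pytest.approx(math.pi * 100, rel=0.05)

    def test_empty_map_raises_no_annulus(self):
        with pytest.raises(NoAnnulusDetectedError):
            extract_contour(const_map(0.0))
        with pytest.raises(NoAnnulusDetectedError):
            extract_contour(const_map(0.49))

    def test_open_structure_raises(self):
        vals = np.zeros((128, 128))
        vals[:, 60:68] = 1.0  # bright band crossing the image: no closed loop
        with pytest.raises(OpenContourError):
            extract_contour(ProbabilityMap(vals, (0.5, 0.5), (0.0, 0.0)))

    def test_soft_edged_disc(self):
        from scipy.ndimage import gaussian_filter

        vals = gaussian_filter(disc_probability_map(10.0).values, 2.0)
        contour = extract_contour(ProbabilityMap(vals, (0.5, 0.5), (0.0, 0.0)))
        assert contour.area() == pytest.approx(math.pi * 100, rel=0.03)


class TestMeasureContour:
    def test_unit_square(self):
        m = measure_contour(AnnulusContour(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])))
        assert m.area == pytest.approx(1.0)
        assert m.perimeter == pytest.approx(4.0)

    def test_regular_360gon_closed_forms(self):
        n, r = 360, 10.0
        m = measure_contour(AnnulusContour(regular_polygon(n, r)))
        assert m.area == pytest.approx(0.5 * n * r**2 * math.sin(2 * math.pi / n), rel=1e-12)
        assert m.perimeter == pytest.approx(2 * n * r * math.sin(math.pi / n), rel=1e-12)
        assert m.area == pytest.approx(314.143, abs=5e-4)
        assert m.perimeter == pytest.approx(62.831, abs=5e-4)

    def test_ellipse_720_vertices(self):
        m = measure_contour(ellipse_contour(12, 9, rotation=0.3, n_vertices=720))
        assert m.area == pytest.approx(math.pi * 12 * 9, rel=1e-4)

    def test_degenerate_polygon_rejected(self):
        collinear = AnnulusContour(np.array([[0, 0], [1, 1], [2, 2.0]]))
        with pytest.raises(ValidationError):
            measure_contour(collinear)

    def test_isoperimetric_inequality_enforced(self):
        with pytest.raises(ValidationError, match="isoperimetric"):
            Measurement(area=100.0, perimeter=10.0)

    def test_pixel_counting_oracle_convex_shapes(self):
        # contour measurement agrees with count * spacing^2 on rasterised shapes
        from annuseg.preprocess import rasterize_mask
        from conftest import make_plane

        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.uniform(8, 13)
            b = rng.uniform(6, a)
            rot = rng.uniform(0, math.pi)
            truth = ellipse_contour(a, b, rot, center=(32, 32))
            grid = make_plane(np.zeros((128, 128)), spacing=0.5, origin=(0.0, 0.0))
            mask = rasterize_mask(truth, grid)
            prob = ProbabilityMap(mask.values.astype(float), grid.spacing, grid.origin)
            m = measure_contour(extract_contour(prob))
            assert m.area == pytest.approx(mask.area_mm2(), rel=0.02)


@pytest.fixture(scope="module")
def tiny_models():
    """Deliberately under-trained models: exercise the error contract."""
    cfg = ModelConfig(epochs=1, seed=0)
    samples = [generate_phantom(PhantomSpec(), seed=s) for s in range(3)]
    from annuseg.preprocess import prepare_sample

    prepped = [prepare_sample(s.plane, s.truth_contour) for s in samples]
    m1 = train(
        build_model(cfg),
        [(p.plane_1mm, p.mask_1mm) for p in prepped[:2]],
        [(p.plane_1mm, p.mask_1mm) for p in prepped[2:]],
        cfg,
    )
    m05 = train(
        build_model(cfg),
        [(p.plane_05mm, p.mask_05mm) for p in prepped[:2]],
        [(p.plane_05mm, p.mask_05mm) for p in prepped[2:]],
        cfg,
    )
    return m1, m05


class TestEndToEnd:
    def test_detect_audit_trail_or_staged_error(self, tiny_models):
        m1, m05 = tiny_models
        sample = generate_phantom(PhantomSpec(), seed=100)
        try:
            result = detect(sample.plane, m1, m05)
        except StageError as exc:
            assert exc.stage in {
                "prepare", "predict_1mm", "predict_05mm", "fuse", "extract_contour", "measure",
            }
        else:
            # if it succeeds, every intermediate must be present and consistent
            assert result.fused.shape == (128, 128)
            assert result.measurement.area > 0
            assert result.measurement.perimeter**2 >= 4 * math.pi * result.measurement.area * (1 - 1e-9)

    def test_detect_deterministic(self, tiny_models):
        m1, m05 = tiny_models
        sample = generate_phantom(PhantomSpec(noise_sd=0), seed=101)
        def run():
            try:
                r = detect(sample.plane, m1, m05)
                return ("ok", r.measurement.area, r.measurement.perimeter)
            except StageError as exc:
                return ("err", exc.stage)
        assert run() == run()
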