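"""Detection contracts: spot recovery, separation, and circle counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eduquant.detection import DetectionParams, count_in_circle, detect_positive_cells
from eduquant.errors import ValidationError
from eduquant.synthetic import NoiseModel, SimulationScenario, render_section
from eduquant.types import CircularRoi, FluorescenceSection


def _render(points, shape=(128, 128), noise=0.0, seed=0, psf=1.5):
    from eduquant.synthetic import RegionGeometry

    scen = SimulationScenario(
        image_height_px=shape[0],
        image_width_px=shape[1],
        region_geometry=RegionGeometry(blob_radius_range_px=(20.0, 40.0)),
        psf_sigma_px=psf,
        noise_model=NoiseModel(gaussian_sigma=noise),
        seed=seed,
    )
    return render_section(
        None, np.asarray(points, float).reshape(-1, 2), np.empty((0, 2)),
        scen, np.random.default_rng(seed), sample_id="det",
    )


class TestDetectPositiveCells:
    def test_empty_noiseless_scene_gives_no_detections(self):
        det = detect_positive_cells(_render(np.empty((0, 2))), "edu")
        assert len(det) == 0

    def test_flat_channel_gives_empty_set_not_error(self):
        sec = FluorescenceSection("f", {"edu": np.full((64, 64), 5.0)}, 4.0)
        assert len(detect_positive_cells(sec, "edu")) == 0

    def test_missing_channel_is_validation_error(self):
        sec = FluorescenceSection("f", {"edu": np.zeros((64, 64))}, 4.0)
        with pytest.raises(ValidationError):
            detect_positive_cells(sec, "protein")

    def test_single_spot_located_within_one_pixel(self):
        det = detect_positive_cells(_render([[60.0, 70.0]]), "edu")
        assert len(det) == 1
        assert np.hypot(*(det.centroids[0] - [60.0, 70.0])) <= 1.0

    def test_well_separated_spots_all_recovered(self):
        rng = np.random.default_rng(4)
        pts = np.array([[r, c] for r in range(15, 120, 15) for c in range(15, 120, 15)], float)
        pts += rng.uniform(-2, 2, pts.shape)
        det = detect_positive_cells(_render(pts, noise=50.0), "edu")
        assert len(det) == len(pts)
        # every truth point matched within 3 px
        from scipy.spatial import cKDTree

        d, _ = cKDTree(det.centroids).query(pts)
        assert d.max() <= 3.0

    def test_min_separation_invariant(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(10, 118, (120, 2))
        det = detect_positive_cells(_render(pts, noise=30.0), "edu")
        if len(det) > 1:
            from scipy.spatial.distance import pdist

            assert pdist(det.centroids).min() >= det.detection_params["min_separation_px"]

    def test_translation_equivariance_on_noiseless_input(self):
        pts = np.array([[40.0, 40.0], [60.0, 80.0], [90.0, 30.0]])
        shift = (7, 11)
        a = detect_positive_cells(_render(pts), "edu")
        b = detect_positive_cells(_render(pts + shift), "edu")
        assert len(a) == len(b) == 3
        moved = a.centroids + shift
        order_a = np.lexsort((moved[:, 1], moved[:, 0]))
        order_b = np.lexsort((b.centroids[:, 1], b.centroids[:, 0]))
        assert np.allclose(moved[order_a], b.centroids[order_b], atol=0.2)

    def test_detection_deterministic(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(10, 118, (60, 2))
        sec = _render(pts, noise=40.0)
        a = detect_positive_cells(sec, "edu")
        b = detect_positive_cells(sec, "edu")
        assert np.array_equal(a.centroids, b.centroids)


class TestCountInCircle:
    def test_empty_detection_set_counts_zero(self):
        roi = CircularRoi("r", (10.0, 10.0), 5.0, "proliferating")
        assert count_in_circle(np.empty((0, 2)), roi) == 0

    def test_boundary_point_is_counted(self):
        roi = CircularRoi("r", (0.0, 0.0), 5.0, "proliferating")
        assert count_in_circle(np.array([[0.0, 5.0]]), roi) == 1
        assert count_in_circle(np.array([[0.0, 5.0 + 1e-9]]), roi) == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_membership_scan(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (200, 2))
        center = rng.uniform(0, 100, 2)
        radius = rng.uniform(1, 40)
        roi = CircularRoi("r", tuple(center), radius, "proliferating")
        brute = sum(
            1
            for p in pts
            if (p[0] - center[0]) ** 2 + (p[1] - center[1]) ** 2 <= radius**2
        )
        assert count_in_circle(pts, roi) == brute

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_radius_and_additive_over_partitions(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, (120, 2))
        center = (25.0, 25.0)
        r1, r2 = sorted(rng.uniform(1, 30, 2))
        small = CircularRoi("a", center, r1, "proliferating")
        big = CircularRoi("b", center, r2, "proliferating")
        assert count_in_circle(pts, small) <= count_in_circle(pts, big)
        # additivity over a disjoint split of the point set
        split = rng.random(len(pts)) < 0.5
        assert count_in_circle(pts, big) == count_in_circle(
            pts[split], big
        ) + count_in_circle(pts[~split], big)
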