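"""Simulator contracts: geometry, Poisson statistics, rendering,
reproducibility."""

import numpy as np
import pytest

from eduquant.errors import GeometryError, ValidationError
from eduquant.synthetic import (
    NoiseModel,
    RegionGeometry,
    SimulationScenario,
    generate_experiment,
    mask_to_rle,
    render_section,
    rle_to_mask,
    sample_cells,
    sample_region_mask,
    scenario_from_yaml,
    scenario_to_yaml,
    section_rng,
    thin_min_separation,
    treated_from_control,
)


class TestRegionMask:
    def test_single_centered_disk_geometry(self):
        # one blob whose radius is half the short side has no placement
        # freedom: the mask is that disk, area pi r^2 (up to smoothing)
        r = 64.0
        scen = SimulationScenario(
            image_height_px=128,
            image_width_px=128,
            region_geometry=RegionGeometry(
                n_blobs=1, blob_radius_range_px=(r, r), smoothing_sigma_px=2.0
            ),
        )
        mask = sample_region_mask(
            scen, np.random.default_rng(0), max_fraction=0.99
        )
        area = mask.area_px
        assert area == pytest.approx(np.pi * r * r, rel=0.01)
        rows, cols = np.nonzero(mask.grid)
        assert rows.mean() == pytest.approx(63.5, abs=1.0)
        assert cols.mean() == pytest.approx(63.5, abs=1.0)

    def test_mask_deterministic_for_seed(self, small_scenario):
        m1 = sample_region_mask(small_scenario, np.random.default_rng(17))
        m2 = sample_region_mask(small_scenario, np.random.default_rng(17))
        assert np.array_equal(m1.grid, m2.grid)

    def test_area_fraction_and_connectivity_over_many_draws(self, small_scenario):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(0)
        for _ in range(200):
            mask = sample_region_mask(small_scenario, rng)
            frac = mask.grid.mean()
            assert 0.05 <= frac <= 0.80
            _, n = ndi.label(mask.grid)
            assert n == 1

    def test_oversized_blob_raises(self):
        with pytest.raises(GeometryError):
            SimulationScenario(
                image_height_px=64,
                image_width_px=64,
                region_geometry=RegionGeometry(
                    n_blobs=1, blob_radius_range_px=(64.0, 64.0)
                ),
            )


class TestSampleCells:
    def test_zero_intensity_gives_empty_list(self, small_scenario):
        rng = np.random.default_rng(0)
        mask = sample_region_mask(small_scenario, rng)
        pts = sample_cells(mask, 0.0, 0.0, 4.0, rng)
        assert pts.shape == (0, 2)

    def test_negative_intensity_rejected(self, small_scenario):
        rng = np.random.default_rng(0)
        mask = sample_region_mask(small_scenario, rng)
        with pytest.raises(ValidationError):
            sample_cells(mask, -1.0, 0.0, 4.0, rng)

    def test_poisson_mean_and_variance(self):
        # fixed square mask of known area: counts must follow Poisson law
        mask = np.zeros((200, 200), dtype=bool)
        mask[:100, :200] = True  # 20000 px * (4 um)^2 = 0.32 mm^2
        lam = 1000.0
        expected = lam * 20000 * (4.0 / 1000.0) ** 2  # 320
        counts = []
        rng = np.random.default_rng(123)
        for _ in range(500):
            pts = sample_cells(mask, lam, 0.0, 4.0, rng)
            counts.append(len(pts))
        counts = np.asarray(counts, dtype=float)
        assert counts.mean() == pytest.approx(expected, rel=0.02)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.15)

    def test_positions_uniform_within_mask(self):
        # KS check of the x-coordinate against uniformity on a rectangle
        from scipy import stats

        mask = np.zeros((128, 128), dtype=bool)
        mask[20:100, 30:110] = True
        rng = np.random.default_rng(5)
        pts = np.concatenate(
            [sample_cells(mask, 2000.0, 0.0, 4.0, rng) for _ in range(20)]
        )
        rows = (pts[:, 0] - 19.5) / 80.0
        cols = (pts[:, 1] - 29.5) / 80.0
        assert stats.kstest(rows, "uniform").pvalue > 0.01
        assert stats.kstest(cols, "uniform").pvalue > 0.01
        # all points inside the rectangle's pixel union
        assert rows.min() >= 0 and rows.max() <= 1
        assert cols.min() >= 0 and cols.max() <= 1

    def test_thinning_enforces_min_separation(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (400, 2))
        thinned = thin_min_separation(pts, 6.0)
        from scipy.spatial.distance import pdist

        assert len(thinned) > 0
        assert pdist(thinned).min() >= 6.0


class TestRenderSection:
    def test_empty_scene_is_flat_background(self, noiseless_scenario):
        empty = np.empty((0, 2))
        sec = render_section(None, empty, empty, noiseless_scenario)
        for role in ("edu", "protein"):
            assert np.all(sec.channel(role) == noiseless_scenario.background_level)

    def test_single_spot_peak_value_and_location(self, noiseless_scenario):
        pts = np.array([[64.0, 64.0]])
        sec = render_section(None, pts, np.empty((0, 2)), noiseless_scenario)
        img = sec.channel("edu")
        expected = noiseless_scenario.background_level + noiseless_scenario.spot_amplitude
        assert img.max() == pytest.approx(expected, rel=0.005)
        assert np.unravel_index(img.argmax(), img.shape) == (64, 64)

    def test_rendering_deterministic_for_seed(self, small_scenario):
        rng = np.random.default_rng(1)
        mask = sample_region_mask(small_scenario, rng)
        pts = sample_cells(mask, 200.0, 0.0, 4.0, rng)
        a = render_section(mask, pts, pts, small_scenario, np.random.default_rng(9))
        b = render_section(mask, pts, pts, small_scenario, np.random.default_rng(9))
        for role in ("edu", "protein"):
            assert np.array_equal(a.channel(role), b.channel(role))

    def test_intensities_clipped_non_negative(self, small_scenario):
        sec = render_section(
            None, np.empty((0, 2)), np.empty((0, 2)),
            small_scenario, np.random.default_rng(0),
        )
        assert sec.channel("edu").min() >= 0


class TestGenerateExperiment:
    def _tiny(self, **kw):
        base = SimulationScenario(
            image_height_px=128,
            image_width_px=128,
            region_geometry=RegionGeometry(
                n_blobs=1, blob_radius_range_px=(30.0, 45.0), smoothing_sigma_px=6.0
            ),
            lambda_edu_in=300.0,
            lambda_prot_in=300.0,
        )
        from dataclasses import replace

        return replace(base, **kw)

    def test_true_percent_change_bookkeeping(self):
        control = self._tiny()
        treated = treated_from_control(control, 75.0)
        exp = generate_experiment(control, treated, 2, seed=11)
        assert exp.true_percent_change[("edu", "in")] == pytest.approx(75.0)
        assert exp.true_percent_change[("protein", "in")] == pytest.approx(75.0)
        assert exp.true_percent_change[("edu", "out")] == pytest.approx(0.0)
        assert len(exp.sections) == 4
        groups = [s.group_label for s in exp.sections]
        assert groups == ["control", "control", "treated", "treated"]

    def test_no_effect_records_zero_change(self):
        control = self._tiny()
        exp = generate_experiment(control, control, 1, seed=1)
        assert all(v == 0.0 for v in exp.true_percent_change.values())

    def test_zero_control_intensity_change_is_undefined(self):
        control = self._tiny(lambda_edu_out=0.0)
        treated = self._tiny(lambda_edu_out=3.0)
        exp = generate_experiment(control, treated, 1, seed=1)
        assert exp.true_percent_change[("edu", "out")] is None

    def test_dataset_reproducible_from_master_seed(self):
        control = self._tiny()
        treated = treated_from_control(control, 50.0)
        a = generate_experiment(control, treated, 2, seed=42)
        b = generate_experiment(control, treated, 2, seed=42)
        for sa, sb in zip(a.sections, b.sections):
            for role in ("edu", "protein"):
                assert np.array_equal(sa.channel(role), sb.channel(role))
        for ta, tb in zip(a.truths, b.truths):
            assert np.array_equal(ta.region_mask, tb.region_mask)
            assert np.array_equal(ta.edu_cells, tb.edu_cells)

    def test_ground_truth_counts_match_cell_lists(self):
        control = self._tiny()
        exp = generate_experiment(control, control, 1, seed=3)
        t = exp.truths[0]
        assert t.counts["edu"]["in"] + t.counts["edu"]["out"] == len(t.edu_cells)

    def test_section_rng_distinct_per_index(self):
        a = section_rng(5, 0).integers(0, 2**31)
        b = section_rng(5, 1).integers(0, 2**31)
        assert a != b


class TestSerialization:
    def test_scenario_yaml_round_trip(self, tmp_path, small_scenario):
        path = tmp_path / "scen.yaml"
        scenario_to_yaml(small_scenario, path)
        back = scenario_from_yaml(path)
        assert back == small_scenario

    @pytest.mark.parametrize("shape", [(1, 1), (5, 7), (16, 16)])
    def test_rle_round_trip(self, shape):
        rng = np.random.default_rng(0)
        mask = rng.random(shape) > 0.5
        assert np.array_equal(rle_to_mask(mask_to_rle(mask), shape), mask)
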