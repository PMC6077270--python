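"""Density estimation and group-comparison contracts."""

import numpy as np
import pytest

from eduquant.errors import UndefinedComparisonError, ValidationError
from eduquant.quantify import compare_groups, estimate_density, summarize_experiment
from eduquant.localization import classify_compartment
from eduquant.types import CircularRoi, DensityEstimate


def _rois(radii, centers=None):
    centers = centers or [(50.0 + 10 * i, 50.0) for i in range(len(radii))]
    return [
        CircularRoi(f"roi_{i+1:02d}", c, r, "proliferating")
        for i, (c, r) in enumerate(zip(centers, radii))
    ]


def _estimate(sample_id, density, channel="edu", compartment="proliferating"):
    # one circle of area 10 mm² encodes densities to 0.1 cells/mm²
    return DensityEstimate(
        sample_id=sample_id,
        compartment=compartment,
        channel_role=channel,
        counts=[int(round(density * 10))],
        circle_area_mm2=10.0,
    )


class TestEstimateDensity:
    def test_zero_detections_gives_zero_density(self):
        d = estimate_density(
            np.empty((0, 2)), _rois([10.0] * 3), 4.0,
            sample_id="s", channel_role="edu",
        )
        assert d.mean_density == 0.0
        assert d.counts == [0, 0, 0]

    def test_hand_computed_example(self):
        # counts 10, 12, 14 in circles of radius 0.2 mm: area = pi 0.04
        # ≈ 0.12566 mm², mean density = 12 / 0.12566 ≈ 95.49 cells/mm²
        pixel = 10.0  # 0.2 mm = 20 px
        rois = _rois([20.0] * 3, centers=[(100.0, 100.0), (300.0, 100.0), (100.0, 300.0)])
        pts = []
        for roi, n in zip(rois, (10, 12, 14)):
            for k in range(n):
                pts.append([roi.center[0] + 0.1 * k, roi.center[1]])
        d = estimate_density(np.array(pts), rois, pixel, sample_id="s", channel_role="edu")
        assert d.counts == [10, 12, 14]
        assert d.circle_area_mm2 == pytest.approx(0.12566, rel=1e-3)
        assert d.mean_density == pytest.approx(95.49, rel=1e-3)

    def test_mixed_radii_rejected(self):
        with pytest.raises(ValidationError):
            estimate_density(np.empty((0, 2)), _rois([5.0, 6.0]), 4.0, sample_id="s")

    def test_unbiased_against_known_intensity(self, small_scenario):
        """With ground-truth centers as detections the estimator must
        recover the generating intensity (Poisson unbiasedness)."""
        from eduquant.roi import sample_circles
        from eduquant.synthetic import sample_cells, sample_region_mask

        lam = 500.0  # dense enough for a 2% standard error over 80 seeds
        vals = []
        for seed in range(80):
            rng = np.random.default_rng(seed)
            mask = sample_region_mask(small_scenario, rng)
            pts = sample_cells(mask, lam, 0.0, small_scenario.pixel_size_um, rng)
            rois = sample_circles(mask, k=3, rng=rng)
            d = estimate_density(
                pts, rois, small_scenario.pixel_size_um,
                sample_id="s", channel_role="edu",
            )
            vals.append(d.mean_density)
        assert np.mean(vals) == pytest.approx(lam, rel=0.06)

    def test_variance_shrinks_with_more_circles(self, small_scenario):
        from eduquant.roi import sample_circles
        from eduquant.synthetic import sample_cells, sample_region_mask

        by_k = {}
        for k in (3, 12):
            vals = []
            for seed in range(60):
                rng = np.random.default_rng(seed)
                mask = sample_region_mask(small_scenario, rng)
                pts = sample_cells(mask, 200.0, 0.0, 4.0, rng)
                rois = sample_circles(mask, k=k, radius_px=15.0, rng=rng)
                vals.append(
                    estimate_density(pts, rois, 4.0, sample_id="s").mean_density
                )
            by_k[k] = np.var(vals)
        assert by_k[12] < by_k[3]


class TestCompareGroups:
    def test_hand_computed_percent_change(self):
        comp = compare_groups([_estimate("c1", 100)], [_estimate("t1", 21.6)])
        assert comp.percent_change == pytest.approx(78.4)

    def test_identical_groups_give_zero_change(self):
        comp = compare_groups(
            [_estimate("c1", 50), _estimate("c2", 70)],
            [_estimate("t1", 50), _estimate("t2", 70)],
        )
        assert comp.percent_change == pytest.approx(0.0)

    def test_treated_increase_gives_negative_change(self):
        comp = compare_groups([_estimate("c", 50)], [_estimate("t", 100)])
        assert comp.percent_change == pytest.approx(-100.0)

    def test_zero_control_mean_is_undefined(self):
        with pytest.raises(UndefinedComparisonError):
            compare_groups([_estimate("c", 0)], [_estimate("t", 10)])

    def test_mixed_channels_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(
                [_estimate("c", 10, channel="edu")],
                [_estimate("t", 5, channel="protein")],
            )

    @pytest.mark.parametrize("p", [0.0, 50.0])
    def test_swap_antisymmetry(self, p):
        """Swapping groups maps p -> 100 * (1 - 1 / (1 - p/100))."""
        control = [_estimate("c1", 100), _estimate("c2", 100)]
        treated = [_estimate("t1", 100 - p), _estimate("t2", 100 - p)]
        fwd = compare_groups(control, treated).percent_change
        rev = compare_groups(treated, control).percent_change
        assert fwd == pytest.approx(p)
        assert rev == pytest.approx(100 * (1 - 1 / (1 - p / 100)))

    def test_bootstrap_interval_brackets_estimate(self):
        rng = np.random.default_rng(0)
        control = [_estimate(f"c{i}", v) for i, v in enumerate(rng.normal(100, 10, 8))]
        treated = [_estimate(f"t{i}", v) for i, v in enumerate(rng.normal(25, 5, 8))]
        comp = compare_groups(control, treated, n_boot=500, seed=1)
        assert comp.ci_low < comp.percent_change < comp.ci_high
        again = compare_groups(control, treated, n_boot=500, seed=1)
        assert (comp.ci_low, comp.ci_high) == (again.ci_low, again.ci_high)


class TestSummarizeExperiment:
    def _one_pair(self):
        densities = [
            _estimate("c1", 100, channel="edu"),
            _estimate("c1", 80, channel="protein"),
            _estimate("t1", 25, channel="edu"),
            _estimate("t1", 10, channel="protein"),
        ]
        comparisons = [
            compare_groups(
                [d for d in densities if d.sample_id == "c1" and d.channel_role == ch],
                [d for d in densities if d.sample_id == "t1" and d.channel_role == ch],
            )
            for ch in ("edu", "protein")
        ]
        calls = [classify_compartment(0.9, target_name="p-Akt", n_cells=80)]
        return calls, densities, comparisons

    def test_single_pair_cardinality(self):
        calls, densities, comparisons = self._one_pair()
        report = summarize_experiment(
            calls, densities, comparisons, groups={"c1": "control", "t1": "treated"}
        )
        assert len(report.samples) == 2
        assert len(report.comparisons) == 2
        assert set(report.comparisons["channel"]) == {"edu", "protein"}
        assert report.calls.iloc[0]["call"] == "proliferating"

    def test_empty_input_gives_empty_tables_with_headers(self):
        report = summarize_experiment([], [], [])
        assert len(report.samples) == 0 and "sample_id" in report.samples.columns
        assert len(report.comparisons) == 0 and "percent_change" in report.comparisons.columns

    def test_mismatched_sample_channels_rejected(self):
        densities = [
            _estimate("c1", 10, channel="edu"),
            _estimate("c1", 10, channel="protein"),
            _estimate("t1", 5, channel="edu"),  # t1 missing protein
        ]
        with pytest.raises(ValidationError):
            summarize_experiment([], densities, [])

    def test_csv_round_trip_is_stable(self, tmp_path):
        calls, densities, comparisons = self._one_pair()
        report = summarize_experiment(
            calls, densities, comparisons, groups={"c1": "control", "t1": "treated"}
        )
        paths = report.to_csv(tmp_path)
        first = {k: open(p, "rb").read() for k, p in paths.items()}
        paths = report.to_csv(tmp_path)
        second = {k: open(p, "rb").read() for k, p in paths.items()}
        assert first == second
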