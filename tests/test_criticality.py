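import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftflow import fixtures as fx
from graftflow.criticality import (
    CriticalityError,
    ThresholdRule,
    critical_mask,
    criticality_report,
    percentile_threshold,
    roi_area_fraction,
    similarity_index,
)


def brute_force_weighted_percentile(values, weights, pct):
    """Independent oracle: walk the weighted CDF and interpolate between the
    bracketing sorted values."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    target = pct / 100.0 * w.sum()
    cum = 0.0
    for i in range(len(v)):
        nxt = cum + w[i]
        if nxt >= target:
            if i == 0:
                return v[0]
            return v[i - 1] + (v[i] - v[i - 1]) * (target - cum) / w[i]
        cum = nxt
    return v[-1]


class TestPercentileThreshold:
    def test_uniform_field_returns_the_value(self):
        v = np.full(10, 3.3)
        for pct in (10, 33, 66, 90):
            assert percentile_threshold(v, np.ones(10), pct) == 3.3

    def test_equal_area_1_to_100_matches_oracle(self):
        v = np.arange(1.0, 101.0)
        w = np.ones(100)
        assert percentile_threshold(v, w, 66) == pytest.approx(
            brute_force_weighted_percentile(v, w, 66), rel=1e-12
        )

    def test_dominant_large_element(self):
        # areas (9, 1), values (1, 10): half the total area is reached well
        # inside the large element, so the threshold stays at its value
        assert percentile_threshold([1.0, 10.0], [9.0, 1.0], 50) == 1.0

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(200):
            n = rng.integers(1, 40)
            v = rng.normal(size=n)
            w = rng.uniform(0.1, 5.0, size=n)
            pct = rng.uniform(1, 99)
            assert percentile_threshold(v, w, pct) == pytest.approx(
                brute_force_weighted_percentile(v, w, pct), rel=1e-9, abs=1e-12
            )

    def test_empty_input_rejected(self):
        with pytest.raises(CriticalityError):
            percentile_threshold([], [], 50)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=30, unique=True),
        st.floats(5, 45),
    )
    def test_raising_percentile_never_grows_high_mask(self, vals, pct):
        v = np.array(vals)
        w = np.ones(len(v))
        lo = percentile_threshold(v, w, pct)
        hi = percentile_threshold(v, w, pct + 50)
        assert (v > hi).sum() <= (v > lo).sum()


class TestMaskAndFractions:
    def test_strict_inequality_partition(self):
        v = np.array([1.0, 2.0, 3.0])
        low = critical_mask(v, 2.0, "low").mask
        high = critical_mask(v, 2.0, "high").mask
        assert list(low) == [True, False, False]
        assert list(high) == [False, False, True]
        assert not np.any(low & high)

    def test_high_rule_example(self):
        m = critical_mask(np.array([1.0, 2.0, 3.0]), 2.0, "high")
        assert list(m.mask) == [False, False, True]

    def test_roi_fraction_extremes_and_half(self):
        areas = np.array([1.0, 1.0, 2.0, 2.0])
        roi = np.array([2, 3])
        all_true = critical_mask(np.ones(4), 0.0, "high")
        assert roi_area_fraction(all_true, roi, areas) == 100.0
        none = critical_mask(np.ones(4), 2.0, "high")
        assert roi_area_fraction(none, roi, areas) == 0.0
        half = critical_mask(np.array([0.0, 0.0, 1.0, -1.0]), 0.5, "high")
        assert roi_area_fraction(half, roi, areas) == 50.0

    def test_empty_roi_rejected(self):
        m = critical_mask(np.ones(3), 0.0, "high")
        with pytest.raises(CriticalityError):
            roi_area_fraction(m, [], np.ones(3))

    def test_fractions_invariant_to_area_rescaling(self, rng):
        v = rng.normal(size=30)
        areas = rng.uniform(0.5, 2.0, size=30)
        roi = np.arange(10, 25)
        m = critical_mask(v, 0.0, "high")
        f1 = roi_area_fraction(m, roi, areas)
        f2 = roi_area_fraction(m, roi, areas * 7.5)
        assert f1 == pytest.approx(f2, rel=1e-12)


class TestSimilarityIndex:
    def test_identity_disjoint_and_subset(self):
        areas = np.ones(4)
        a = critical_mask(np.array([1, 1, 0, 0.0]), 0.5, "high")
        b = critical_mask(np.array([0, 0, 1, 1.0]), 0.5, "high")
        assert similarity_index(a, a, areas) == 100.0
        assert similarity_index(a, b, areas) == 0.0
        # A subset of B with half its area: Dice = 2*(1/2)/(3/2) = 66.67
        sub = critical_mask(np.array([1, 0, 0, 0.0]), 0.5, "high")
        sup = critical_mask(np.array([1, 1, 0, 0.0]), 0.5, "high")
        assert similarity_index(sub, sup, areas) == pytest.approx(200.0 / 3.0)

    def test_symmetry_and_bounds(self, rng):
        areas = rng.uniform(0.5, 2.0, size=50)
        for _ in range(20):
            a = critical_mask(rng.normal(size=50), 0.0, "high")
            b = critical_mask(rng.normal(size=50), 0.0, "high")
            d1 = similarity_index(a, b, areas)
            assert d1 == similarity_index(b, a, areas)
            assert 0.0 <= d1 <= 100.0

    def test_both_empty_masks_are_identical(self):
        a = critical_mask(np.zeros(3), 1.0, "high")
        assert similarity_index(a, a, np.ones(3)) == 100.0


class TestReport:
    def test_uniform_descriptor_gives_zero_fractions(self):
        fields = {"tawss": np.full(20, 2.0)}
        rois = {"all": np.arange(20)}
        rep = criticality_report(fields, [ThresholdRule("tawss", "low")], rois, np.ones(20))
        assert rep.area_fractions["tawss"]["all"] == 0.0

    def test_report_composes_from_individual_operations(self, rng):
        n = 200
        areas = rng.uniform(0.5, 2.0, size=n)
        fields = {
            "tawss": rng.uniform(0, 5, size=n),
            "osi": rng.uniform(0, 0.5, size=n),
        }
        rois = {"left": np.arange(n // 2), "right": np.arange(n // 2, n)}
        rules = [ThresholdRule("tawss", "low"), ThresholdRule("osi", "high")]
        rep = criticality_report(fields, rules, rois, areas)
        for rule in rules:
            thr = percentile_threshold(fields[rule.descriptor], areas, rule.percentile)
            assert rep.thresholds[rule.descriptor] == thr
            mask = critical_mask(fields[rule.descriptor], thr, rule.direction)
            for roi, idx in rois.items():
                assert rep.area_fractions[rule.descriptor][roi] == roi_area_fraction(
                    mask, idx, areas
                )

    def test_missing_descriptor_rejected(self):
        with pytest.raises(CriticalityError, match="missing"):
            criticality_report({}, [ThresholdRule("tawss", "low")], {}, np.ones(1))

    def test_whole_domain_fraction_tracks_percentile(self, rng):
        # distinct equal-area values: high-rule fraction ~ (100 - pct)
        n = 500
        v = rng.permutation(n).astype(float)
        rep = criticality_report(
            {"tsvi": v},
            [ThresholdRule("tsvi", "high", percentile=66)],
            {"all": np.arange(n)},
            np.ones(n),
        )
        assert rep.area_fractions["tsvi"]["all"] == pytest.approx(34.0, abs=0.5)

    def test_constructed_band_fraction_recovered(self):
        # uniform base field with a high band painted over ~30% of one ROI:
        # the whole-domain 66th percentile sits at the base value, so the
        # strict high-mask is exactly the band
        spec = fx.CylinderFixtureSpec(n_radial=2, n_theta=32, n_axial=9)
        L = spec.length
        _, wall = fx.make_cylinder_mesh(
            spec, roi_bands={"vein": (2 * L / 3, L), "rest": (0, 2 * L / 3)}
        )
        values = np.ones(wall.n_cells)
        cent = wall.cell_centroids()
        theta = np.arctan2(cent[:, 1], cent[:, 0]) % (2 * np.pi)
        band = wall.rois["vein"][theta[wall.rois["vein"]] < 0.3 * 2 * np.pi]
        values[band] = 10.0
        rep = criticality_report(
            {"transwss": values},
            [ThresholdRule("transwss", "high")],
            dict(wall.rois),
            wall.cell_areas,
        )
        frac = rep.area_fractions["transwss"]["vein"]
        exact = 100.0 * wall.cell_areas[band].sum() / wall.cell_areas[wall.rois["vein"]].sum()
        assert frac == pytest.approx(exact, rel=1e-12)
        assert frac == pytest.approx(30.0, abs=100.0 / 32 + 0.1)
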