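"""Empirical CDF, L1 threshold estimation and edge selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnboot import (
    build_averaged_network,
    cdf_quantile,
    empirical_cdf,
    estimate_threshold,
    l1_distance,
    l2_distance,
    select_significant,
)
from bnboot.averaging import EdgeConfidenceSet
from bnboot.threshold import linf_distance

from conftest import EXAMPLE_CONFIDENCES


def grid_minimum(distance, cdf, step=1e-5):
    """Independent oracle: evaluate the norm on a uniform t-grid.

    Exploits only that the objective is a weighted sum of |F_i - t| terms:
    prefix sums over the sorted segment values give every grid evaluation.
    """
    vals, widths = cdf.segments()
    ts = np.arange(0.0, 1.0 + step / 2, step)
    order = np.argsort(vals)
    v, w = vals[order], widths[order]
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cvw = np.concatenate([[0.0], np.cumsum(v * w)])
    idx = np.searchsorted(v, ts, side="right")
    if distance == "l1":
        below = ts * cw[idx] - cvw[idx]
        above = (cvw[-1] - cvw[idx]) - ts * (cw[-1] - cw[idx])
        out = below + above
    elif distance == "l2":
        cv2w = np.concatenate([[0.0], np.cumsum(v ** 2 * w)])
        out = cv2w[-1] - 2 * ts * cvw[-1] + ts ** 2 * cw[-1]
    else:
        raise ValueError(distance)
    return ts, out


def riemann_l1(t, cdf, points=1_000_000):
    """10^6-point midpoint Riemann sum of the defining integral on [0, 1]."""
    xs = (np.arange(points) + 0.5) / points
    F = cdf.evaluate(xs)
    ideal = np.full(points, t)
    return float(np.mean(np.abs(F - ideal)))


class TestEmpiricalCdf:
    def test_worked_example_jumps_and_plateaus(self, example_vector):
        cdf = empirical_cdf(example_vector)
        np.testing.assert_allclose(
            cdf.jump_points, [0.0460, 0.2242, 0.3921, 0.7689, 0.8935, 0.9439])
        np.testing.assert_allclose(
            cdf.plateau_values, np.arange(1, 7) / 6)

    def test_identical_values_deduplicate_to_single_jump(self):
        cdf = empirical_cdf([0.4, 0.4, 0.4])
        np.testing.assert_allclose(cdf.jump_points, [0.4])
        np.testing.assert_allclose(cdf.plateau_values, [1.0])

    def test_zero_one_vector(self):
        cdf = empirical_cdf([0.0, 1.0])
        np.testing.assert_allclose(cdf.jump_points, [0.0, 1.0])
        np.testing.assert_allclose(cdf.plateau_values, [0.5, 1.0])

    def test_right_continuity(self, example_vector):
        cdf = empirical_cdf(example_vector)
        assert cdf.evaluate(0.3921) == pytest.approx(0.5)
        assert cdf.evaluate(0.3920999) == pytest.approx(2 / 6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            empirical_cdf([0.5, 1.2])
        with pytest.raises(ValueError):
            empirical_cdf([])


class TestL1Distance:
    def test_at_zero_equals_integral_of_cdf(self, example_vector):
        cdf = empirical_cdf(example_vector)
        # integral of F = 1 - mean(p)
        assert l1_distance(0.0, cdf) == pytest.approx(1 - example_vector.mean(),
                                                      abs=1e-12)
        assert l1_distance(0.0, cdf) == pytest.approx(0.4552333, abs=1e-6)

    def test_worked_example_at_half(self, example_vector):
        cdf = empirical_cdf(example_vector)
        assert l1_distance(0.5, cdf) == pytest.approx(0.1760, abs=1e-4)

    def test_matches_riemann_integration(self, example_vector):
        cdf = empirical_cdf(example_vector)
        for t in (0.0, 0.3, 0.5, 0.9, 1.0):
            assert l1_distance(t, cdf) == pytest.approx(
                riemann_l1(t, cdf), abs=1e-6)

    def test_t_out_of_range_rejected(self, example_vector):
        cdf = empirical_cdf(example_vector)
        with pytest.raises(ValueError):
            l1_distance(1.5, cdf)


class TestQuantile:
    def test_worked_example_at_optimum(self, example_vector):
        cdf = empirical_cdf(example_vector)
        assert cdf_quantile(cdf, 0.4999816) == 0.3921
        assert cdf_quantile(cdf, 0.5) == 0.3921

    def test_boundaries(self, example_vector):
        cdf = empirical_cdf(example_vector)
        assert cdf_quantile(cdf, 0.0) == 0.0
        assert cdf_quantile(cdf, 1.0) == 0.9439


class TestEstimateThreshold:
    def test_worked_example_l1_optimum(self, example_vector):
        result = estimate_threshold(example_vector)
        assert result.t_hat == pytest.approx(0.4999816, abs=2e-5)
        assert result.cutoff == 0.3921

    def test_all_ones_selects_everything(self):
        result = estimate_threshold([1.0, 1.0, 1.0])
        assert result.t_hat == 0.0
        assert result.significant_indices == [0, 1, 2]

    def test_all_zeros_selects_nothing(self):
        result = estimate_threshold([0.0, 0.0, 0.0])
        assert result.t_hat == 1.0
        assert result.significant_indices == []

    def test_l2_is_width_weighted_mean(self, example_vector):
        cdf = empirical_cdf(example_vector)
        vals, widths = cdf.segments()
        expected = np.average(vals[widths > 0], weights=widths[widths > 0])
        assert estimate_threshold(example_vector, norm="l2").t_hat == \
            pytest.approx(expected, abs=1e-12)

    def test_unknown_norm_rejected(self):
        with pytest.raises(ValueError):
            estimate_threshold([0.5], norm="l7")

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_l1_closed_form_beats_grid_search(self, values):
        cdf = empirical_cdf(values)
        result = estimate_threshold(values)
        _, grid = grid_minimum("l1", cdf, step=1e-4)
        assert result.l1_at_optimum <= grid.min() + 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_l2_closed_form_beats_grid_search(self, values):
        cdf = empirical_cdf(values)
        t2 = estimate_threshold(values, norm="l2").t_hat
        _, grid = grid_minimum("l2", cdf, step=1e-4)
        assert l2_distance(t2, cdf) <= grid.min() + 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_l1_objective_is_convex_on_the_grid(self, values):
        cdf = empirical_cdf(values)
        ts, grid = grid_minimum("l1", cdf, step=1e-3)
        second_diff = np.diff(grid, 2)
        assert np.all(second_diff >= -1e-12)

    def test_linf_minimises_max_deviation(self, example_vector):
        cdf = empirical_cdf(example_vector)
        t = estimate_threshold(example_vector, norm="linf").t_hat
        for other in np.linspace(0, 1, 101):
            assert linf_distance(t, cdf) <= linf_distance(float(other), cdf) + 1e-12


class TestSelection:
    def _conf(self):
        return EdgeConfidenceSet.from_confidences(EXAMPLE_CONFIDENCES, m=500)

    def test_worked_example_significant_set(self):
        conf = self._conf()
        result = estimate_threshold(conf.vector())
        assert select_significant(conf, result) == \
            {("A", "D"), ("B", "D"), ("C", "D")}
        assert result.min_significant_confidence == 0.7689

    def test_mismatched_sizes_rejected(self):
        conf = self._conf()
        result = estimate_threshold([0.1, 0.9])
        with pytest.raises(ValueError):
            select_significant(conf, result)

    def test_selection_monotone_in_confidence(self):
        """Raising one confidence never removes that pair at fixed cutoff."""
        conf = self._conf()
        result = estimate_threshold(conf.vector())
        base = select_significant(conf, result)
        bumped = dict(EXAMPLE_CONFIDENCES)
        bumped[("B", "C")] = 0.80  # raise past the cutoff
        conf2 = EdgeConfidenceSet.from_confidences(bumped, m=500)
        sel2 = {p for p in conf2.pairs if conf2.confidence[p] > result.cutoff}
        assert base <= sel2

    def test_pipeline_fixed_point_on_indicator_vector(self):
        """Re-running on the ideal 0/1 configuration reselects the same set."""
        conf = self._conf()
        result = estimate_threshold(conf.vector())
        selected = select_significant(conf, result)
        indicator = {p: (1.0 if p in selected else 0.0) for p in conf.pairs}
        conf2 = EdgeConfidenceSet.from_confidences(indicator, m=500)
        result2 = estimate_threshold(conf2.vector())
        assert select_significant(conf2, result2) == selected


class TestAveragedNetwork:
    def test_majority_direction_wins(self):
        conf = EdgeConfidenceSet(
            pairs=[("A", "B")], confidence={("A", "B"): 1.0},
            direction_counts={("A", "B"): (160, 40)}, m=200)
        g = build_averaged_network(conf, {("A", "B")})
        assert list(g.edges) == [("A", "B")]
        assert not g.edges["A", "B"]["undirected"]

    def test_exact_tie_is_flagged_undirected(self):
        conf = EdgeConfidenceSet(
            pairs=[("A", "B")], confidence={("A", "B"): 1.0},
            direction_counts={("A", "B"): (100, 100)}, m=200)
        g = build_averaged_network(conf, {("A", "B")})
        assert g.edges["A", "B"]["undirected"]

    def test_empty_selection_gives_empty_graph(self):
        conf = EdgeConfidenceSet.from_confidences(EXAMPLE_CONFIDENCES, m=10)
        g = build_averaged_network(conf, set())
        assert set(g.edges) == set() and set(g.nodes) == {"A", "B", "C", "D"}
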