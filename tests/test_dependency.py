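import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betimed.dependency import (
    DependencyConfig,
    aggregate_gene_scores,
    call_essentials,
    compute_guide_lfc,
    dependency_probability,
    derive_pan_essential,
    fit_dependency_model,
)
from betimed.io import CountTable


class TestGuideLfc:
    def test_equal_abundance_gives_zero(self):
        table = CountTable(["g1"], ["a", "b"], np.array([[100, 100]]))
        lfc = compute_guide_lfc(table, ["b"], ["a"], pseudocount=1)
        assert lfc["g1"] == pytest.approx(0.0)

    def test_hand_computed_rpm_example(self):
        # reference: 5 of 1e6 reads -> RPM 5; final: 40 of 2e6 -> RPM 20
        counts = np.array([[5, 40], [1_000_000 - 5, 2_000_000 - 40]])
        table = CountTable(["g", "rest"], ["ref", "fin"], counts)
        lfc = compute_guide_lfc(table, ["fin"], ["ref"], pseudocount=1)
        assert lfc["g"] == pytest.approx(np.log2(21 / 6), abs=1e-9)

    def test_depth_rescaling_leaves_lfc_unchanged(self, rng):
        counts = rng.integers(1, 1000, size=(20, 4))
        t1 = CountTable([f"g{i}" for i in range(20)], list("abcd"), counts)
        t2 = CountTable(t1.feature_ids, t1.sample_ids, counts * 2)
        l1 = compute_guide_lfc(t1, ["c", "d"], ["a", "b"])
        l2 = compute_guide_lfc(t2, ["c", "d"], ["a", "b"])
        pd.testing.assert_series_equal(l1, l2)

    def test_zero_total_sample_rejected(self):
        table = CountTable(["g"], ["a", "b"], np.array([[0, 5]]))
        with pytest.raises(ValueError, match="zero total"):
            compute_guide_lfc(table, ["b"], ["a"])


class TestGeneAggregation:
    def test_median_is_robust_to_one_outlier_guide(self):
        lfc = pd.Series({"s1": -1.0, "s2": -1.0, "s3": -1.0, "s4": 3.0})
        gmap = {g: ("gene", False) for g in lfc.index}
        assert aggregate_gene_scores(lfc, gmap)["gene"] == -1.0

    def test_single_guide_gene_passes_through(self):
        lfc = pd.Series({"s1": -0.7})
        assert aggregate_gene_scores(lfc, {"s1": ("g", False)})["g"] == -0.7

    def test_matches_bruteforce_median_on_random_instance(self, rng):
        genes = [f"g{i}" for i in range(50)]
        gmap, values = {}, {}
        for g in genes:
            for j in range(rng.integers(1, 6)):
                guide = f"{g}_{j}"
                gmap[guide] = (g, False)
                values[guide] = rng.normal()
        lfc = pd.Series(values)
        result = aggregate_gene_scores(lfc, gmap)
        for g in genes:
            expected = float(np.median([v for k, v in values.items() if gmap[k][0] == g]))
            assert result[g] == pytest.approx(expected)

    def test_controls_excluded_and_unmapped_rejected(self):
        lfc = pd.Series({"s1": 0.5, "ctrl": 1.0})
        result = aggregate_gene_scores(lfc, {"s1": ("g", False), "ctrl": ("NT", True)})
        assert list(result.index) == ["g"]
        with pytest.raises(KeyError):
            aggregate_gene_scores(lfc, {"s1": ("g", False)})


class TestPanEssential:
    def _panel(self):
        # 10 genes x 3 lines; gene g0 always lowest, g9 always highest
        data = {f"line{j}": np.arange(10) + 0.01 * j for j in range(3)}
        return pd.DataFrame(data, index=[f"g{i}" for i in range(10)])

    def test_gene_in_bottom_quantile_of_all_lines_included(self):
        pan = derive_pan_essential(self._panel(), pan_quantile=0.26, pan_fraction=0.9)
        assert "g0" in pan and "g9" not in pan

    def test_two_of_three_lines_is_below_ninety_percent(self):
        panel = self._panel()
        panel.loc["g0", "line2"] = 100.0  # drop out of bottom quantile in one line
        pan = derive_pan_essential(panel, pan_quantile=0.26, pan_fraction=0.9)
        assert "g0" not in pan

    def test_single_line_requires_explicit_list(self):
        with pytest.raises(ValueError, match="explicit"):
            derive_pan_essential(self._panel()[["line0"]])

    def test_recovers_planted_always_depleted_genes(self, rng):
        genes = [f"g{i}" for i in range(200)]
        planted = set(genes[:20])
        panel = pd.DataFrame(
            rng.normal(0, 0.3, size=(200, 20)),
            index=genes,
            columns=[f"line{j}" for j in range(20)],
        )
        panel.loc[sorted(planted)] -= 2.0
        pan = derive_pan_essential(panel)
        assert pan == planted


def _two_component_scores(rng, n=1000, sep=-1.0, sd=0.2):
    genes = [f"g{i}" for i in range(n)]
    dep = set(genes[:150])
    non = set(genes[-300:])
    scores = pd.Series(rng.normal(0, sd, size=n), index=genes)
    scores[sorted(dep)] += sep
    return scores, dep, non


class TestMixtureModel:
    def test_identical_anchors_fixed_pi_gives_half_between_clamps(self, rng):
        scores = pd.Series(rng.normal(0, 0.3, size=500), index=[f"g{i}" for i in range(500)])
        anchors = set(scores.index[:100])
        cfg = DependencyConfig(fixed_pi=0.5)
        model = fit_dependency_model(scores, anchors, anchors, cfg)
        interior = (model.grid > cfg.clamp_low + 5 * cfg.smooth_sigma) & (
            model.grid < cfg.clamp_high - 5 * cfg.smooth_sigma
        )
        assert np.allclose(model.prob_curve[interior], 0.5, atol=1e-4)

    def test_curve_monotone_for_separated_components(self, rng):
        scores, dep, non = _two_component_scores(rng)
        model = fit_dependency_model(scores, dep, non)
        inside = (model.grid >= -1.5) & (model.grid <= 0.25)
        diffs = np.diff(model.prob_curve[inside])
        assert np.all(diffs <= 1e-12)

    def test_clamps_exact_beyond_boundaries(self, rng):
        scores, dep, non = _two_component_scores(rng)
        model = fit_dependency_model(scores, dep, non)
        assert np.all(model.prob_curve[model.grid < -1.5] == 1.0)
        assert np.all(model.prob_curve[model.grid > 0.25] == 0.0)

    def test_smoothed_step_matches_gaussian_convolution_oracle(self, rng):
        # identical flat components => raw curve is a step only at the clamps;
        # the smoothed transition must match the Gaussian CDF profile.
        from scipy.stats import norm

        scores = pd.Series(rng.normal(-0.5, 0.4, size=500), index=[f"g{i}" for i in range(500)])
        anchors = set(scores.index[:100])
        cfg = DependencyConfig(fixed_pi=0.5, enforce_monotone=False)
        model = fit_dependency_model(scores, anchors, anchors, cfg)
        near_low = (model.grid > -1.5 + 1e-9) & (model.grid < -1.5 + 2 * cfg.smooth_sigma)
        # expected: 0.5 + 0.5 * P(N(0, sigma) < clamp_low - x)
        expected = 0.5 + 0.5 * norm.cdf((-1.5 - model.grid[near_low]) / cfg.smooth_sigma)
        assert np.allclose(model.prob_curve[near_low], expected, atol=0.02)

    def test_probability_lookup_honors_clamps(self, rng):
        scores, dep, non = _two_component_scores(rng)
        model = fit_dependency_model(scores, dep, non)
        assert dependency_probability(model, -2.0) == 1.0
        assert dependency_probability(model, 0.5) == 0.0
        mid = dependency_probability(model, -0.5)
        assert 0.0 < mid < 1.0

    def test_lowering_score_never_decreases_probability(self, rng):
        scores, dep, non = _two_component_scores(rng)
        model = fit_dependency_model(scores, dep, non)
        grid = np.linspace(-3, 1.5, 400)
        probs = dependency_probability(model, grid)
        assert np.all(np.diff(probs) <= 1e-12)

    def test_small_anchor_set_rejected_with_advice(self, rng):
        scores = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        with pytest.raises(ValueError, match="anchor"):
            fit_dependency_model(scores, {"g1"}, set(scores.index[:50]))

    def test_density_normalization_invariant(self, rng):
        scores, dep, non = _two_component_scores(rng)
        model = fit_dependency_model(scores, dep, non)
        dx = model.grid[1] - model.grid[0]
        assert np.sum(model.f_dep) * dx == pytest.approx(1.0, abs=1e-6)
        assert np.sum(model.f_non) * dx == pytest.approx(1.0, abs=1e-6)


class TestEssentialCalls:
    def test_cumulative_mean_q_worked_example(self):
        p = pd.Series({"a": 1.0, "b": 1.0, "c": 0.8, "d": 0.1})
        calls = call_essentials(p)
        assert calls.loc["c", "q"] == pytest.approx(0.2 / 3)
        assert calls.loc["c", "essential"]
        assert not calls.loc["d", "essential"]

    def test_probability_below_threshold_never_essential(self):
        p = pd.Series({"a": 0.34, "b": 1.0})
        calls = call_essentials(p)
        assert not calls.loc["a", "essential"]

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_q_monotone_down_probability_ranking(self, probs):
        p = pd.Series(probs, index=[f"g{i}" for i in range(len(probs))])
        calls = call_essentials(p).sort_values("probability", ascending=False)
        assert np.all(np.diff(calls["q"].to_numpy()) >= -1e-12)

    def test_tied_probabilities_share_q(self):
        p = pd.Series({"a": 0.9, "b": 0.9, "c": 0.5})
        calls = call_essentials(p)
        assert calls.loc["a", "q"] == calls.loc["b", "q"]
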