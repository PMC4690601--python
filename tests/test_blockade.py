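"""Mixture fitting, population labeling, dwell histograms, trend lines."""

import numpy as np
import pytest

from osmotrace.blockade import (
    COLLISION,
    TRANSLOCATION,
    BlockadeMixture,
    GaussianComponent,
    BlockadeMixtureResults,
    dwell_histogram,
    fit_blockade_mixture,
    fit_osmylation_trend,
    label_populations,
    most_probable_blockade,
)


def draw_mixture(rng, n, weights, means, sds):
    comp = rng.choice(len(weights), size=n, p=weights)
    return np.clip(rng.normal(np.array(means)[comp], np.array(sds)[comp]), 1e-4, 1.0)


class TestMixtureFit:
    def test_two_component_recovery(self, rng):
        """EM recovers a 0.3 N(0.44,0.04) + 0.7 N(0.63,0.03) blend at n=1000."""
        x = draw_mixture(rng, 1000, [0.3, 0.7], [0.44, 0.63], [0.04, 0.03])
        res = fit_blockade_mixture(x, n_components=2, seed=0)
        coll, trans = res.components
        assert coll.mean == pytest.approx(0.44, abs=0.01)
        assert trans.mean == pytest.approx(0.63, abs=0.01)
        assert coll.weight == pytest.approx(0.3, abs=0.05)
        assert trans.weight == pytest.approx(0.7, abs=0.05)

    def test_agrees_with_sklearn(self, rng):
        """Independent EM implementation (scikit-learn) lands on the same fit."""
        from sklearn.mixture import GaussianMixture

        x = draw_mixture(rng, 1000, [0.3, 0.7], [0.44, 0.63], [0.04, 0.03])
        ours = fit_blockade_mixture(x, n_components=2, seed=0)
        gm = GaussianMixture(2, n_init=10, random_state=0).fit(x[:, None])
        ref = np.sort(gm.means_.ravel())
        assert ours.components[0].mean == pytest.approx(ref[0], abs=0.005)
        assert ours.components[1].mean == pytest.approx(ref[1], abs=0.005)

    def test_auto_selects_one_on_single_gaussian(self, rng):
        x = np.clip(rng.normal(0.57, 0.03, 1000), 1e-4, 1.0)
        res = fit_blockade_mixture(x, n_components="auto", seed=0)
        assert res.n_components == 1
        assert res.components[0].label == TRANSLOCATION
        assert res.components[0].mean == pytest.approx(0.57, abs=0.01)

    def test_auto_selects_two_on_bimodal(self, rng):
        x = draw_mixture(rng, 1000, [0.3, 0.7], [0.44, 0.63], [0.04, 0.03])
        res = fit_blockade_mixture(x, n_components="auto", seed=0)
        assert res.n_components == 2

    def test_loglik_non_decreasing(self, rng):
        x = draw_mixture(rng, 600, [0.5, 0.5], [0.4, 0.6], [0.05, 0.05])
        res = fit_blockade_mixture(x, n_components=2, seed=0)
        traj = np.array(res.ll_trajectory)
        assert np.all(np.diff(traj) >= -1e-8)

    def test_weights_sum_and_means_in_range(self, rng):
        x = draw_mixture(rng, 800, [0.3, 0.7], [0.44, 0.63], [0.04, 0.03])
        res = fit_blockade_mixture(x, n_components=2, seed=0)
        assert sum(c.weight for c in res.components) == pytest.approx(1.0)
        for c in res.components:
            assert x.min() <= c.mean <= x.max()

    def test_seed_determinism(self, rng):
        x = draw_mixture(rng, 500, [0.3, 0.7], [0.44, 0.63], [0.04, 0.03])
        r1 = fit_blockade_mixture(x, n_components=2, seed=3)
        r2 = fit_blockade_mixture(x, n_components=2, seed=3)
        assert r1.components == r2.components

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="50"):
            fit_blockade_mixture(np.full(20, 0.5))

    def test_out_of_range_values(self, rng):
        with pytest.raises(ValueError):
            fit_blockade_mixture(rng.normal(0.5, 0.5, 200))  # some outside (0, 1]

    def test_binned_method_agrees_on_separated_peaks(self, rng):
        x = draw_mixture(rng, 2000, [0.4, 0.6], [0.3, 0.7], [0.03, 0.03])
        em = fit_blockade_mixture(x, n_components=2, seed=0)
        binned = BlockadeMixture(x).fit(n_components=2, seed=0, method="binned")
        for a, b in zip(em.components, binned.components):
            assert b.mean == pytest.approx(a.mean, abs=0.01)

    def test_summary_reports_components(self, rng):
        x = draw_mixture(rng, 500, [0.3, 0.7], [0.44, 0.63], [0.04, 0.03])
        s = fit_blockade_mixture(x, n_components=2, seed=0).summary()
        assert "collision" in s and "translocation" in s


def _results_from(components):
    return BlockadeMixtureResults(
        components=tuple(components),
        n_events=100,
        loglik=0.0,
        bic={},
        n_components=len(components),
        method="em",
    )


class TestLabelsAndPeaks:
    def test_two_components_lower_is_collision(self):
        res = label_populations(
            _results_from(
                [GaussianComponent(0.67, 0.03, 0.6), GaussianComponent(0.44, 0.04, 0.4)]
            )
        )
        assert res.components[0].label == COLLISION
        assert res.components[0].mean == 0.44
        assert res.components[1].label == TRANSLOCATION

    def test_single_component_is_translocation(self):
        res = label_populations(_results_from([GaussianComponent(0.583, 0.03, 1.0)]))
        assert res.components[0].label == TRANSLOCATION

    def test_equal_means_tie_broken_by_weight(self):
        res = label_populations(
            _results_from(
                [GaussianComponent(0.5, 0.03, 0.7), GaussianComponent(0.5, 0.05, 0.3)]
            )
        )
        assert res.component(TRANSLOCATION).weight == 0.7
        assert res.component(COLLISION).weight == 0.3

    def test_most_probable_single_value(self):
        res = label_populations(_results_from([GaussianComponent(0.583, 0.03, 1.0)]))
        assert most_probable_blockade(res) == (0.583,)

    def test_most_probable_collision_first(self):
        res = label_populations(
            _results_from(
                [GaussianComponent(0.57, 0.03, 0.7), GaussianComponent(0.42, 0.04, 0.3)]
            )
        )
        assert most_probable_blockade(res) == (0.42, 0.57)


class TestDwellHistogram:
    def test_two_decades_one_bin_each(self):
        dwells = [1e-5] * 10 + [1e-3] * 10
        counts, edges = dwell_histogram(dwells, bins_per_decade=1)
        assert counts.sum() == 20
        occupied = counts[counts > 0]
        assert list(occupied) == [10, 10]

    def test_empty_input(self):
        counts, edges = dwell_histogram([])
        assert counts.size == 0 and edges.size == 0

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            dwell_histogram([1e-4, 0.0])

    def test_total_count_preserved(self, rng):
        dwells = 10.0 ** rng.normal(-3.7, 0.3, 500)
        counts, edges = dwell_histogram(dwells, bins_per_decade=5)
        assert counts.sum() == 500
        assert edges.size == counts.size + 1

    def test_mode_recovers_configured_dwell_scale(self, rng):
        """The histogram mode sits within one bin of the log-normal center."""
        dwells = 10.0 ** rng.normal(-3.7, 0.25, 2000)
        counts, edges = dwell_histogram(dwells, bins_per_decade=4)
        mode = np.argmax(counts)
        log_centers = (np.log10(edges[:-1]) + np.log10(edges[1:])) / 2
        assert abs(log_centers[mode] - (-3.7)) <= 1.0 / 4 + 1e-9


class TestOsmylationTrend:
    def test_80mer_series_slope(self):
        """Translocation peaks of the 80-mer series rise ~0.32 per unit fraction."""
        fit = fit_osmylation_trend([(0, 0.57), (0.30, 0.63), (0.5125, 0.74)])
        x = np.array([0, 0.30, 0.5125])
        y = np.array([0.57, 0.63, 0.74])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.slope == pytest.approx(0.323, abs=0.001)
        assert fit.slope_sign == 1

    def test_20mer_series_positive(self):
        fit = fit_osmylation_trend(
            [(0, 0.583), (0.10, 0.582), (0.15, 0.624), (0.30, 0.667), (0.50, 0.69)]
        )
        assert fit.slope > 0

    def test_flat_points_zero_slope(self):
        fit = fit_osmylation_trend([(0.0, 0.5), (1.0, 0.5)])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            fit_osmylation_trend([(0.1, 0.5)])
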