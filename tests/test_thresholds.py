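import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annosom import (
    GaussianMixture1D,
    ThresholdConfig,
    bimodality_coefficient,
    estimate_threshold,
    estimate_thresholds,
    gmm2_fit,
    kmeans1d_exact,
    set_manual_threshold,
    silhouette_binary,
    threshold_from_gmm,
)
from annosom.errors import DegenerateMarkerError, RangeError, UndefinedSilhouetteError


def brute_force_two_means(x):
    """Independent oracle: score every contiguous split of the sorted
    vector with plain numpy means/SSE."""
    xs = np.sort(np.asarray(x, float))
    best_sse, best_split = np.inf, None
    for k in range(1, len(xs)):
        left, right = xs[:k], xs[k:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best_sse - 1e-12:
            best_sse = sse
            best_split = 0.5 * (left.mean() + right.mean())
    return best_split, best_sse


class TestKmeans1dExact:
    def test_two_point_masses(self):
        split, labels, centers = kmeans1d_exact([0, 0, 0, 1, 1, 1])
        assert centers == (0.0, 1.0)
        assert split == 0.5
        assert list(labels) == [0, 0, 0, 1, 1, 1]

    def test_hand_enumerated_three_points(self):
        # splits: {0}|{0.1,0.9} SSE 0.32 vs {0,0.1}|{0.9} SSE 0.005
        split, labels, centers = kmeans1d_exact([0, 0.1, 0.9])
        assert split == pytest.approx((0.05 + 0.9) / 2)
        assert list(labels) == [0, 0, 1]

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateMarkerError):
            kmeans1d_exact([0.3, 0.3, 0.3])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 500))
        x = np.clip(
            np.where(
                rng.random(n) < 0.5,
                rng.normal(0.2, 0.05, n),
                rng.normal(0.8, 0.05, n),
            ),
            0,
            1,
        )
        split, _, _ = kmeans1d_exact(x)
        oracle_split, _ = brute_force_two_means(x)
        assert split == pytest.approx(oracle_split, abs=1e-12)

    @given(
        st.lists(
            st.integers(min_value=0, max_value=9), min_size=2, max_size=40
        ).filter(lambda v: len(set(v)) > 1)
    )
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_with_heavy_ties(self, values):
        x = np.asarray(values, float) / 9.0
        split, labels, _ = kmeans1d_exact(x)
        _, oracle_sse = brute_force_two_means(x)
        sse = sum(
            ((x[labels == g] - x[labels == g].mean()) ** 2).sum() for g in (0, 1)
        )
        assert sse == pytest.approx(oracle_sse, abs=1e-9)


class TestGmm:
    def test_recovers_well_separated_means(self):
        rng = np.random.default_rng(11)
        x = np.concatenate(
            [rng.normal(0.2, 0.05, 1000), rng.normal(0.8, 0.05, 1000)]
        )
        g = gmm2_fit(x)
        assert g.means[0] == pytest.approx(0.2, abs=0.02)
        assert g.means[1] == pytest.approx(0.8, abs=0.02)
        assert 0.4 < g.weights[0] < 0.6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglikelihood_trace_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.beta(0.4, 0.4, size=300)
        g = gmm2_fit(x)
        trace = np.asarray(g.trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_two_point_masses_hit_variance_floor(self):
        x = np.r_[np.zeros(100), np.ones(100), 0.01, 0.99]  # 4 distinct values
        g = gmm2_fit(x)
        assert g.means[0] == pytest.approx(0.0, abs=0.01)
        assert g.means[1] == pytest.approx(1.0, abs=0.01)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(DegenerateMarkerError):
            gmm2_fit([0, 0, 1, 1, 0, 1])


class TestThresholdFromGmm:
    def test_symmetric_mixture_gives_midpoint(self):
        g = GaussianMixture1D((0.5, 0.5), (0.2, 0.8), (0.05, 0.05), 0.0, 1)
        assert threshold_from_gmm(g) == pytest.approx(0.5, abs=1e-12)

    def test_unequal_weights_match_grid_search(self):
        g = GaussianMixture1D((0.9, 0.1), (0.2, 0.8), (0.05, 0.05), 0.0, 1)
        t = threshold_from_gmm(g)
        assert t > 0.5  # heavier low component pushes the boundary up
        grid = np.linspace(0.2, 0.8, 600001)

        def logdens(w, mu, sd):
            return math.log(w) - np.log(sd) - (grid - mu) ** 2 / (2 * sd * sd)

        diff = logdens(0.9, 0.2, 0.05) - logdens(0.1, 0.8, 0.05)
        crossing = grid[np.argmin(np.abs(diff))]
        assert t == pytest.approx(crossing, abs=1e-5)

    def test_midpoint_fallback_when_roots_outside(self):
        # dominant broad low component wins everywhere between the means
        # (the narrow component's peak density stays below it), so no
        # crossing exists inside (mu1, mu2)
        g = GaussianMixture1D((0.999, 0.001), (0.2, 0.8), (0.5, 0.01), 0.0, 1)
        roots_free = threshold_from_gmm(g)
        assert roots_free == pytest.approx(0.5 * (0.2 + 0.8))

    def test_equal_means_rejected(self):
        g = GaussianMixture1D((0.5, 0.5), (0.5, 0.5), (0.1, 0.1), 0.0, 1)
        with pytest.raises(DegenerateMarkerError):
            threshold_from_gmm(g)


def per_point_silhouette(x, labels):
    """Direct per-point evaluation of the silhouette formula."""
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    out = []
    for i in range(len(x)):
        own = x[(labels == labels[i])]
        other = x[(labels != labels[i])]
        if len(own) == 1:
            out.append(0.0)
            continue
        a = np.abs(own - x[i]).sum() / (len(own) - 1)
        b = np.abs(other - x[i]).mean()
        out.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(out))


class TestSilhouette:
    def test_perfectly_separated_masses(self):
        assert silhouette_binary([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_two_singletons_convention(self):
        assert silhouette_binary([0, 1], [0, 1]) == 0.0

    def test_one_group_empty_rejected(self):
        with pytest.raises(UndefinedSilhouetteError):
            silhouette_binary([0, 1, 2], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_point_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        x = rng.random(n)
        labels = (x > rng.uniform(0.2, 0.8)).astype(int)
        if len(np.unique(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert silhouette_binary(x, labels) == pytest.approx(
            per_point_silhouette(x, labels), abs=1e-12
        )


class TestBimodalityCoefficient:
    def test_normal_sample_near_one_third(self):
        rng = np.random.default_rng(3)
        assert bimodality_coefficient(rng.normal(size=100_000)) == pytest.approx(
            1 / 3, abs=0.01
        )

    def test_uniform_sample_near_five_ninths(self):
        rng = np.random.default_rng(3)
        assert bimodality_coefficient(rng.random(100_000)) == pytest.approx(
            5 / 9, abs=0.01
        )

    def test_balanced_two_point_mass_near_one(self):
        x = np.r_[np.zeros(5000), np.ones(5000)]
        assert bimodality_coefficient(x) == pytest.approx(1.0, abs=0.01)

    def test_small_or_constant_sample_rejected(self):
        with pytest.raises(DegenerateMarkerError):
            bimodality_coefficient([0.1, 0.9, 0.5])
        with pytest.raises(DegenerateMarkerError):
            bimodality_coefficient([0.5] * 10)

    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-10, max_value=10),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(derandomize=True, max_examples=50)
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).random(50)
        assert bimodality_coefficient(a * x + b) == pytest.approx(
            bimodality_coefficient(x), rel=1e-6
        )


class TestEstimateThreshold:
    def test_clean_bimodal_marker(self):
        rng = np.random.default_rng(5)
        x = np.clip(
            np.where(
                rng.random(500) < 0.5,
                rng.normal(0.2, 0.05, 500),
                rng.normal(0.8, 0.05, 500),
            ),
            0,
            1,
        )
        t = estimate_threshold(x, marker="CD3")
        assert t.threshold == pytest.approx(0.5, abs=0.05)
        assert t.is_bimodal
        assert t.method in ("kmeans", "gmm")
        assert not t.manual

    def test_unimodal_marker_flagged_non_bimodal(self):
        rng = np.random.default_rng(5)
        x = np.clip(rng.normal(0.5, 0.1, 500), 0, 1)
        t = estimate_threshold(x)
        assert not t.is_bimodal
        assert t.bimodality_coefficient < 5 / 9

    def test_bimodality_direction_switch(self):
        rng = np.random.default_rng(5)
        x = np.clip(rng.normal(0.5, 0.1, 500), 0, 1)
        t = estimate_threshold(x, config=ThresholdConfig(bimodality_direction="lt"))
        assert t.is_bimodal  # literal "below cutoff" reading inverts the flag

    def test_two_point_masses_choose_perfect_split(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        t = estimate_threshold(x)
        assert t.threshold == pytest.approx(0.5)
        assert max(t.silhouette_kmeans, t.silhouette_gmm or 0) == 1.0

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        x = rng.beta(0.3, 0.3, 400)
        assert estimate_threshold(x) == estimate_threshold(x.copy())


class TestManualAndTableLevel:
    def test_set_manual_threshold(self, sim_expression):
        table = estimate_thresholds(sim_expression)
        set_manual_threshold(table, "CD3", 0.6)
        e = table["CD3"]
        assert (e.threshold, e.method, e.manual) == (0.6, "manual", True)
        assert not math.isnan(e.bimodality_coefficient)  # diagnostics kept

    def test_manual_survives_re_estimation(self, sim_expression):
        table = estimate_thresholds(sim_expression)
        set_manual_threshold(table, "CD3", 0.6)
        again = estimate_thresholds(sim_expression, existing=table)
        assert again["CD3"].threshold == 0.6
        forced = estimate_thresholds(
            sim_expression, existing=table, overwrite_manual=True
        )
        assert not forced["CD3"].manual

    def test_manual_out_of_range_rejected(self, sim_expression):
        table = estimate_thresholds(sim_expression)
        with pytest.raises(RangeError):
            set_manual_threshold(table, "CD3", 1.5)

    def test_manual_unknown_marker_rejected(self, sim_expression):
        table = estimate_thresholds(sim_expression)
        with pytest.raises(KeyError):
            set_manual_threshold(table, "CD99", 0.5)

    def test_constant_marker_excluded_with_warning(self):
        import pandas as pd

        from annosom import ClusterExpressionMatrix

        rng = np.random.default_rng(2)
        values = pd.DataFrame(
            {"flat": np.full(20, 3.0), "ok": rng.random(20)},
            index=[f"c{i}" for i in range(20)],
        )
        expr = ClusterExpressionMatrix.from_values(values)
        with pytest.warns(UserWarning, match="constant"):
            table = estimate_thresholds(expr)
        assert "flat" not in table and "ok" in table
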