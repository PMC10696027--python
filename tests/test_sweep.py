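import numpy as np
import pytest

from csncrit.sweep import (
    NoTransitionError,
    SweepResult,
    detect_critical_point,
    default_grid,
    scale_unit,
    threshold_sweep,
)
from csncrit.synth import generate_planted_store


class TestScaleUnit:
    def test_linear_series(self):
        assert scale_unit([2, 4, 6]) == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_series_maps_to_zero(self):
        assert scale_unit([5, 5, 5]) == pytest.approx([0.0, 0.0, 0.0])

    def test_descending(self):
        assert scale_unit([1, 0]) == pytest.approx([1.0, 0.0])

    def test_nan_preserved(self):
        out = scale_unit([np.nan, 1.0, 3.0])
        assert np.isnan(out[0]) and out[1:] == pytest.approx([0.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scale_unit([])


@pytest.fixture(scope="module")
def planted_sweep():
    store = generate_planted_store(
        n_families=3, family_size=20,
        within_sim=(0.75, 0.95), between_sim=(0.30, 0.45), seed=2,
    )
    grid = default_grid(0.3, 1.0, 0.05)
    return store, threshold_sweep(store, grid=grid, n_er=10, seed=9)


class TestThresholdSweep:
    def test_edge_count_decreasing_across_gap(self, planted_sweep):
        _, sweep = planted_sweep
        e = sweep.csn["E"]
        assert all(a >= b for a, b in zip(e, e[1:]))
        # strictly decreasing through the within-range (0.75..0.95)
        inside = (sweep.thresholds >= 0.75) & (sweep.thresholds <= 0.9)
        vals = e[inside]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_threshold_one_is_empty(self, planted_sweep):
        _, sweep = planted_sweep
        k = np.argmin(np.abs(sweep.thresholds - 1.0))
        assert sweep.csn["E"][k] == 0
        assert sweep.csn["mean_degree"][k] == 0
        assert sweep.csn["mean_betweenness"][k] == 0

    def test_er_degree_parity_exact(self, planted_sweep):
        """G(N, E) has the CSN's edge count, so mean degrees match exactly."""
        _, sweep = planted_sweep
        assert sweep.er_mean["mean_degree"] == pytest.approx(sweep.csn["mean_degree"])
        assert sweep.er_sd["mean_degree"] == pytest.approx(np.zeros_like(sweep.thresholds))

    def test_deterministic_under_seed(self, planted_sweep):
        store, sweep = planted_sweep
        again = threshold_sweep(store, grid=sweep.thresholds, n_er=10, seed=9)
        for m in sweep.er_mean:
            np.testing.assert_allclose(
                sweep.er_mean[m], again.er_mean[m], equal_nan=True
            )

    def test_scaled_curves_span_unit_interval(self, planted_sweep):
        _, sweep = planted_sweep
        for m, curve in sweep.scaled_csn.items():
            finite = curve[np.isfinite(curve)]
            if finite.size and finite.max() > finite.min():
                assert finite.min() == pytest.approx(0.0)
                assert finite.max() == pytest.approx(1.0)

    def test_empty_grid_rejected(self, planted_sweep):
        store, _ = planted_sweep
        with pytest.raises(ValueError):
            threshold_sweep(store, grid=[], n_er=2, seed=0)


class TestDetectCriticalPoint:
    def _result(self, thresholds, betweenness, p=None, giant=None, assort=None):
        n = len(thresholds)
        csn = {
            "E": np.zeros(n),
            "p": np.asarray(p if p is not None else np.linspace(1, 0, n)),
            "mean_degree": np.zeros(n),
            "mean_betweenness": np.asarray(betweenness, dtype=float),
            "mean_eigenvector": np.zeros(n),
            "giant_fraction": np.asarray(giant if giant is not None else np.zeros(n), dtype=float),
            "assortativity": np.asarray(assort if assort is not None else np.zeros(n), dtype=float),
        }
        return SweepResult(
            thresholds=np.asarray(thresholds, dtype=float), n_nodes=10, n_er=1,
            csn=csn, er_mean={}, er_sd={},
        )

    def test_betweenness_argmax(self):
        sweep = self._result([0.6, 0.65, 0.7, 0.75], [0.1, 0.4, 1.0, 0.2])
        cp = detect_critical_point(sweep, "betweenness_peak")
        assert cp.t_crit == 0.7
        assert cp.p_crit == sweep.csn["p"][2]

    def test_tie_breaks_toward_larger_threshold(self):
        sweep = self._result([0.5, 0.6, 0.7, 0.8], [0.1, 1.0, 1.0, 0.3])
        assert detect_critical_point(sweep, "betweenness_peak").t_crit == 0.7

    def test_giant_onset_largest_threshold_above_fraction(self):
        sweep = self._result(
            [0.5, 0.6, 0.7, 0.8], [0, 0, 0, 0], giant=[0.9, 0.5, 0.08, 0.01]
        )
        assert detect_critical_point(sweep, "giant_onset").t_crit == 0.7

    def test_assortativity_peak(self):
        sweep = self._result(
            [0.5, 0.6, 0.7, 0.8], [0, 0, 0, 0], assort=[0.0, 0.4, 0.2, np.nan]
        )
        assert detect_critical_point(sweep, "assortativity_peak").t_crit == 0.6

    def test_flat_curve_is_no_transition(self):
        sweep = self._result([0.5, 0.6, 0.7], [1.0, 1.0, 1.0])
        with pytest.raises(NoTransitionError):
            detect_critical_point(sweep, "betweenness_peak")

    def test_too_few_points_rejected(self):
        sweep = self._result([0.5, 0.6], [0.0, 1.0])
        with pytest.raises(ValueError):
            detect_critical_point(sweep, "betweenness_peak")


def _transitive_store(n=100, floor=0.3, seed=7):
    """Similarity with latent 1D geometry, so neighbours of a node are
    themselves similar — the transitivity that makes real chemical space
    networks assortative."""
    from csncrit.mcs import SimilarityStore

    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, 1, n))
    store = SimilarityStore(ids=[str(i) for i in range(n)], floor=floor)
    for i in range(n):
        for j in range(i + 1, n):
            s = max(0.0, 1.0 - 2.0 * abs(pos[i] - pos[j]))
            if s > floor:
                store.entries[(i, j)] = s
    return store


class TestPlantedStoreCriticality:
    def test_betweenness_peak_between_typical_cross_and_within_similarity(
        self, planted_sweep
    ):
        """The phase transition separates the cross-family similarity band
        from the within-family one.

        In the strict gap between the bands every family is a complete
        clique (betweenness exactly zero), so the peak sits where the last
        cross-family bridges vanish or where families fragment — between
        the two bands' midpoints."""
        _, sweep = planted_sweep
        cp = detect_critical_point(sweep, "betweenness_peak")
        assert 0.375 <= cp.t_crit <= 0.85

    def test_transitive_similarity_is_assortative_at_criticality(self):
        """Similarity transitivity makes the CSN non-random: its assortativity
        at the critical point exceeds the paired ER ensemble mean by > 3 sd."""
        store = _transitive_store()
        sweep = threshold_sweep(
            store, grid=default_grid(0.3, 1.0, 0.05), n_er=20, seed=4
        )
        cp = detect_critical_point(sweep, "betweenness_peak")
        k = int(np.argmin(np.abs(sweep.thresholds - cp.t_crit)))
        csn_r = sweep.csn["assortativity"][k]
        er_r, er_sd = sweep.er_mean["assortativity"][k], sweep.er_sd["assortativity"][k]
        assert np.isfinite(csn_r) and np.isfinite(er_r)
        assert csn_r > er_r + 3 * er_sd
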