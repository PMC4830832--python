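"""Smoothing, filtering, MDS embedding, uniqueness and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from boolfate.expression import (DegenerateSeriesWarning, MdsEmbedding,
                                 SmoothingConfig, cast_cluster,
                                 detect_anticorrelated, fit_skew_gaussian,
                                 hitmds_embed, select_top_regulated,
                                 smooth_polynomial, uniqueness_pvalue)
from boolfate.synth import planted_cluster_matrix

TIMES = np.array([1, 2, 3, 4, 5, 6, 8, 12, 24], dtype=float)


class TestSmoothing:
    def test_exact_polynomial_recovered(self):
        coeffs = np.array([0.3, -1.2, 0.5, 0.01, -0.002, 0.0001])
        times = np.linspace(0, 10, 10)
        values = np.polynomial.polynomial.polyval(times, coeffs)
        out = smooth_polynomial(times, values)
        assert np.allclose(out, values, atol=1e-8)

    def test_constant_series_stays_constant(self):
        out = smooth_polynomial(TIMES, np.full(TIMES.size, 2.5))
        assert np.allclose(out, 2.5)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            smooth_polynomial([1, 2, 3], [0, 1, 0])

    def test_noise_reduction_on_average(self):
        """Smoothing moves a noisy polynomial series toward the truth."""
        rng = np.random.default_rng(0)
        times = np.linspace(0, 10, 12)
        truth = 0.1 * times ** 2 - times
        wins = 0
        for _ in range(100):
            noisy = truth + rng.normal(0, 0.1, size=times.size)
            sm = smooth_polynomial(times, noisy)
            if np.sqrt(np.mean((sm - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2)):
                wins += 1
        assert wins > 50


class TestTopRegulated:
    def _matrix(self, rows):
        m = pd.DataFrame.from_dict(rows, orient="index")
        m.columns = TIMES[: m.shape[1]]
        return m

    def test_two_consecutive_exceedances_selected(self):
        m = self._matrix({"g": [0, 2.0, 2.1, 0, 0, 0, 0, 0, 0]})
        assert select_top_regulated(m) == ["g"]

    def test_single_spike_not_selected(self):
        m = self._matrix({"g": [0, 3.0, 0, 0, 0, 0, 0, 0, 0]})
        assert select_top_regulated(m) == []

    def test_opposite_sign_consecutive_not_selected(self):
        m = self._matrix({"g": [0, 2.0, -2.0, 0, 0, 0, 0, 0, 0]})
        assert select_top_regulated(m) == []

    def test_down_regulation_selected(self):
        m = self._matrix({"g": [0, -2.0, -1.8, 0, 0, 0, 0, 0, 0]})
        assert select_top_regulated(m) == ["g"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(0, 2, size=(40, 9)), columns=TIMES)
        previous = None
        for thr in (1.0, 1.7, 2.5, 3.5):
            selected = set(select_top_regulated(m, thr))
            if previous is not None:
                assert selected <= previous
            previous = selected


class TestHitMds:
    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = hitmds_embed(D, seed=0)
        d = pdist(emb.coordinates[["x", "y"]].to_numpy())
        assert np.allclose(d, d[0], atol=1e-6)

    def test_planar_self_recovery(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((40, 2))
        D = squareform(pdist(pts))
        emb = hitmds_embed(D, seed=1)
        d_emb = pdist(emb.coordinates[["x", "y"]].to_numpy())
        r = np.corrcoef(squareform(D), d_emb)[0, 1]
        assert r >= 0.999

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(4)
        D = squareform(pdist(rng.standard_normal((20, 3))))
        emb = hitmds_embed(D, seed=0)
        assert all(b <= a + 1e-9 for a, b in
                   zip(emb.stress_trace, emb.stress_trace[1:]))

    def test_stress_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        D = squareform(pdist(rng.standard_normal((15, 2))))
        perm = rng.permutation(15)
        s1 = hitmds_embed(D, seed=7).stress
        s2 = hitmds_embed(D[np.ix_(perm, perm)], seed=7).stress
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            hitmds_embed(np.zeros((5, 5)))


class TestUniqueness:
    @staticmethod
    def _embedding(points):
        return MdsEmbedding(
            coordinates=pd.DataFrame(points, columns=["x", "y"]), stress=0.0)

    def test_far_outlier_attains_minimum_p(self):
        rng = np.random.default_rng(0)
        cloud = rng.standard_normal((500, 2))
        cloud[0] = [10.0, 10.0]
        p = uniqueness_pvalue(self._embedding(cloud), seed=0)
        assert p.idxmin() == 0
        assert p.iloc[0] < 0.01

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError):
            fit_skew_gaussian(np.zeros((20, 2)))

    def test_planted_outliers_recovered_with_high_sensitivity(self):
        rng = np.random.default_rng(1)
        n, n_out = 400, 20
        cloud = rng.standard_normal((n, 2))
        angles = rng.uniform(0, 2 * np.pi, n_out)
        cloud[:n_out] = 7.0 * np.c_[np.cos(angles), np.sin(angles)]
        p = uniqueness_pvalue(self._embedding(cloud), seed=2)
        sensitivity = float((p.iloc[:n_out] < 0.01).mean())
        assert sensitivity >= 0.9

    def test_pvalues_invariant_under_rotation(self):
        rng = np.random.default_rng(6)
        cloud = rng.standard_normal((200, 2)) @ np.array([[2.0, 0.3], [0.0, 1.0]])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        p1 = uniqueness_pvalue(self._embedding(cloud), seed=3)
        p2 = uniqueness_pvalue(self._embedding(cloud @ R.T), seed=3)
        # identical ranking and close values after rigid rotation
        assert (p1.rank() - p2.rank()).abs().max() <= 12
        assert np.allclose(p1, p2, atol=0.02)

    def test_pvalues_within_unit_interval(self):
        rng = np.random.default_rng(7)
        p = uniqueness_pvalue(self._embedding(rng.standard_normal((100, 2))),
                              seed=0)
        assert ((p > 0) & (p <= 1)).all()


class TestCast:
    def test_identical_profiles_form_one_cluster(self):
        m = pd.DataFrame(np.tile(np.sin(TIMES / 3), (10, 1)), columns=TIMES,
                         index=[f"g{i}" for i in range(10)])
        cs = cast_cluster(m)
        assert len(cs.clusters) == 1
        assert len(cs.clusters[0]) == 10

    def test_sign_flipped_groups_split_perfectly(self):
        rng = np.random.default_rng(2)
        base = np.sin(TIMES / 4)
        rows, labels = [], []
        for i in range(12):
            sign = 1 if i < 6 else -1
            rows.append(sign * base + rng.normal(0, 0.05, TIMES.size))
            labels.append(int(i >= 6))
        m = pd.DataFrame(rows, columns=TIMES, index=[f"g{i}" for i in range(12)])
        cs = cast_cluster(m)
        assert len(cs.clusters) == 2
        pred = cs.labels()
        assert adjusted_rand_score(labels, [pred[g] for g in m.index]) == 1.0

    def test_output_is_partition(self):
        m, _ = planted_cluster_matrix(3, 8, noise_sd=0.2, seed=5)
        cs = cast_cluster(m)
        flat = [g for c in cs.clusters for g in c]
        assert len(flat) == len(set(flat)) == len(m)

    def test_constant_series_excluded_with_warning(self):
        m, _ = planted_cluster_matrix(2, 5, noise_sd=0.1, seed=0)
        m.loc["flat"] = 1.0
        with pytest.warns(DegenerateSeriesWarning):
            cs = cast_cluster(m)
        assert cs.excluded == ["flat"]
        assert all("flat" not in c for c in cs.clusters)

    def test_cluster_count_monotone_in_threshold(self):
        m, _ = planted_cluster_matrix(4, 6, noise_sd=0.3, seed=9)
        previous = None
        for t in (0.5, 0.7, 0.8, 0.9, 0.97):
            count = len(cast_cluster(m, t).clusters)
            if previous is not None:
                assert count >= previous
            previous = count


class TestAnticorrelated:
    def test_perfect_opposite_lines(self):
        assert detect_anticorrelated(TIMES, 2 * TIMES, -2 * TIMES)

    def test_same_direction_lines_rejected(self):
        assert not detect_anticorrelated(TIMES, 2 * TIMES, 3 * TIMES + 1)

    def test_r2_boundary_is_strict(self):
        """A series built to have r^2 just below 0.7 fails; just above passes."""
        rng = np.random.default_rng(8)
        t = np.linspace(0, 10, 60)
        down = -t
        noise = rng.standard_normal(t.size)
        noise -= np.polynomial.polynomial.polyval(
            t, np.polynomial.polynomial.polyfit(t, noise, 1))  # de-trend

        def with_r2(target):
            # slope 1 line plus scaled orthogonal noise tuned to hit r^2
            var_line = np.var(t)
            var_noise = var_line * (1 - target) / target
            return t + noise * np.sqrt(var_noise / np.var(noise))

        from scipy.stats import linregress
        below, above = with_r2(0.68), with_r2(0.72)
        assert linregress(t, below).rvalue ** 2 < 0.7
        assert linregress(t, above).rvalue ** 2 > 0.7
        assert not detect_anticorrelated(t, below, down)
        assert detect_anticorrelated(t, above, down)
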