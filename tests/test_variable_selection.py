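"""The selection cascade: interval elimination, the CARS schedule and
sampling dynamics, SPA projection chains, and stage containment."""

import itertools

import numpy as np
import pytest

import teaspec as t
from teaspec.variable_selection import (
    _projection_chain,
    split_intervals,
)


class TestSplitIntervals:
    def test_2800_into_20_equal_intervals(self):
        parts = split_intervals(2800, 20)
        assert len(parts) == 20
        assert all(p.size == 140 for p in parts)

    def test_remainder_spread_over_leading_intervals(self):
        parts = split_intervals(10, 3)
        assert [p.size for p in parts] == [4, 3, 3]
        np.testing.assert_array_equal(np.concatenate(parts), np.arange(10))

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            split_intervals(10, 1)


class TestEDFRatio:
    @pytest.mark.parametrize("n_runs, p", [(50, 2800), (10, 100)])
    def test_boundary_conditions_exact(self, n_runs, p):
        assert t.edf_ratio(1, n_runs, p) == pytest.approx(1.0)
        assert t.edf_ratio(n_runs, n_runs, p) == pytest.approx(2.0 / p)

    def test_closed_form_value(self):
        assert t.edf_ratio(5, 10, 100) == pytest.approx(
            np.exp(-4.0 * np.log(50.0) / 9.0), rel=1e-12
        )
        assert t.edf_ratio(5, 10, 100) == pytest.approx(0.17575, abs=1e-5)

    def test_strictly_decreasing(self):
        vals = [t.edf_ratio(i, 50, 2800) for i in range(1, 51)]
        assert np.all(np.diff(vals) < 0)

    def test_final_enforced_count_is_two(self):
        assert int(np.ceil(2800 * t.edf_ratio(50, 50, 2800))) == 2


def _interval_toy(rng, n=20, informative=(3, 4, 5)):
    """9 variables in 3 intervals; y depends only on interval 2 (noiseless)."""
    X = rng.normal(size=(n, 9))
    beta = np.zeros(9)
    beta[list(informative)] = [1.0, -0.5, 0.25]
    return X, X @ beta


class TestBiPLS:
    def test_informative_interval_survives_and_matches_exhaustive(self, rng):
        X, y = _interval_toy(rng)
        grid = np.arange(9.0)
        res = t.bipls(X, y, grid, n_intervals=3, max_components=3)
        assert {3, 4, 5} <= set(res.selected_indices)
        # exhaustive oracle over all nonempty interval subsets
        intervals = split_intervals(9, 3)
        best = None
        for r in range(1, 4):
            for combo in itertools.combinations(range(3), r):
                cols = np.concatenate([intervals[i] for i in combo])
                score = t.loo_cv(X[:, cols], y, 3).rmsecv
                if best is None or score < best[0]:
                    best = (score, combo)
        assert 1 in best[1]  # oracle also keeps interval 2
        assert res.rmsecv_trace.min() == pytest.approx(best[0], rel=1e-6)

    def test_one_variable_per_interval_equals_greedy_backward(self, rng):
        X = rng.normal(size=(15, 6))
        y = X[:, 1] - 0.5 * X[:, 4] + rng.normal(scale=0.05, size=15)
        res = t.bipls(X, y, np.arange(6.0), n_intervals=6, max_components=3)

        # independent greedy backward elimination oracle
        surviving = list(range(6))
        trace = [t.loo_cv(X, y, 3).rmsecv]
        best = (trace[0], list(surviving))
        while len(surviving) > 1:
            scored = []
            for v in surviving:
                cols = [u for u in surviving if u != v]
                scored.append((t.loo_cv(X[:, cols], y, 3).rmsecv, v))
            s, v = min(scored)
            surviving.remove(v)
            if s < best[0]:
                best = (s, list(surviving))
        assert sorted(res.selected_indices) == sorted(best[1])

    def test_single_interval_rejected(self, rng):
        X, y = _interval_toy(rng)
        with pytest.raises(ValueError):
            t.bipls(X, y, np.arange(9.0), n_intervals=1)


class TestCARS:
    def test_degenerate_two_variable_boundary(self, rng):
        X = rng.normal(size=(12, 2))
        y = X @ np.array([1.0, 0.5])
        cfg = t.CARSConfig(n_runs=2, calibration_fraction=1.0, seed=0)
        res = t.cars(X, y, np.arange(2.0), cfg)
        assert sorted(res.selected_indices) == [0, 1]

    def test_recovers_informative_variables_across_seeds(self, rng):
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(100 + seed)
            X = local.normal(size=(40, 12))
            y = 2.0 * X[:, 2] - 1.5 * X[:, 9]  # noiseless linear truth
            cfg = t.CARSConfig(n_runs=30, calibration_fraction=0.8, seed=seed)
            res = t.cars(X, y, np.arange(12.0), cfg)
            if {2, 9} <= set(res.selected_indices):
                hits += 1
        assert hits >= 18

    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(25, 15))
        y = X[:, 3] + rng.normal(scale=0.1, size=25)
        cfg = t.CARSConfig(n_runs=20, seed=5)
        a = t.cars(X, y, np.arange(15.0), cfg)
        b = t.cars(X, y, np.arange(15.0), cfg)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
        np.testing.assert_array_equal(a.rmsecv_trace, b.rmsecv_trace)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            t.CARSConfig(n_runs=1)
        with pytest.raises(ValueError):
            t.CARSConfig(calibration_fraction=1.5)


def _pivoted_gram_schmidt(X, start, length):
    """Independent oracle: modified Gram-Schmidt with norm pivoting."""
    R = X.astype(float).copy()
    order = [start]
    q = R[:, start] / np.linalg.norm(R[:, start])
    remaining = set(range(X.shape[1])) - {start}
    for _ in range(length - 1):
        R = R - np.outer(q, q @ R)
        norms = {j: np.linalg.norm(R[:, j]) for j in remaining}
        nxt = max(sorted(norms), key=lambda j: norms[j])
        if norms[nxt] <= 1e-12:
            break
        order.append(nxt)
        remaining.discard(nxt)
        q = R[:, nxt] / norms[nxt]
    return order


class TestSPA:
    def test_hand_projection_example(self):
        X = np.array([[1.0, 0.5, 0.0], [0.0, 0.5, 2.0]])
        chain = _projection_chain(X, start=0, length=2)
        assert list(chain) == [0, 2]  # residual norms: 0.5 vs 2.0

    def test_orthogonal_residual(self):
        X = np.array([[1.0, 1.0], [0.0, 1.0]])
        # project column 1 on span{column 0}: residual must be [0, 1]
        q = X[:, 0] / np.linalg.norm(X[:, 0])
        resid = X[:, 1] - q * (q @ X[:, 1])
        np.testing.assert_allclose(resid, [0.0, 1.0])

    def test_chain_matches_pivoted_orthogonalization_oracle(self, rng):
        X = rng.normal(size=(5, 4))
        for start in range(4):
            chain = _projection_chain(X, start, 4)
            assert list(chain) == _pivoted_gram_schmidt(X, start, 4)

    def test_selects_informative_subset(self, rng):
        X = rng.normal(size=(30, 6))
        y = X[:, 1] + 0.5 * X[:, 4] + rng.normal(scale=0.01, size=30)
        res = t.spa(X, y, np.arange(6.0), max_vars=4)
        assert {1, 4} <= set(res.selected_indices)

    def test_invalid_max_vars(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            t.spa(X, X[:, 0], np.arange(3.0), max_vars=0)


class TestCascade:
    def test_all_disabled_passes_everything_through(self, rng):
        X = rng.normal(size=(12, 8))
        y = X[:, 0]
        res = t.cascade(X, y, np.arange(8.0), None, None, None)
        assert len(res) == 1
        np.testing.assert_array_equal(res[0].selected_indices, np.arange(8))

    def test_stage_containment_and_grid_coordinates(self, small_data):
        sn = t.apply_method(small_data, t.PreprocessMethod("snv"))
        cal = sn.calibration()
        res = t.cascade(
            cal.absorbance, cal.dose, sn.wavenumbers,
            t.BiPLSConfig(n_intervals=10, max_components=5),
            t.CARSConfig(n_runs=15, seed=2, max_components=5),
            t.SPAConfig(max_vars=8),
        )
        assert [r.stage for r in res] == ["bipls", "cars", "spa"]
        sets = [set(r.selected_indices) for r in res]
        assert sets[2] <= sets[1] <= sets[0] <= set(range(sn.n_variables))
        assert len(sets[0]) > len(sets[1]) > len(sets[2])
        for r in res:
            np.testing.assert_allclose(
                r.selected_wavenumbers, sn.wavenumbers[r.selected_indices]
            )

    def test_deterministic_given_seed(self, small_data):
        sn = t.apply_method(small_data, t.PreprocessMethod("snv"))
        cal = sn.calibration()
        args = (cal.absorbance, cal.dose, sn.wavenumbers,
                t.BiPLSConfig(n_intervals=6, max_components=4),
                t.CARSConfig(n_runs=10, seed=9, max_components=4),
                t.SPAConfig(max_vars=5))
        a = t.cascade(*args)
        b = t.cascade(*args)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.selected_indices, rb.selected_indices)
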