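import numpy as np
import pytest

from vinispec import (spa_select, uve_select, cars_select,
                      cars_reduction_schedule)
from vinispec.wavelength_selection import spa_chain


def gram_schmidt_chain(X, start, max_vars):
    """Independent brute-force oracle: explicit Gram-Schmidt residuals.

    Keeps an explicit orthonormal basis of the selected columns and, at
    every step, recomputes each remaining column's residual against that
    basis from scratch.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    chain = [start]
    basis = [X[:, start] / np.linalg.norm(X[:, start])]
    while len(chain) < max_vars:
        best_norm, best_j = -1.0, None
        for j in range(p):
            if j in chain:
                continue
            r = X[:, j].copy()
            for q in basis:
                r = r - (q @ r) * q
            nr = np.linalg.norm(r)
            if nr > best_norm:
                best_norm, best_j = nr, j
        if best_j is None or best_norm < 1e-8:
            break
        chain.append(best_j)
        r = X[:, best_j].copy()
        for q in basis:
            r = r - (q @ r) * q
        basis.append(r / np.linalg.norm(r))
    return np.asarray(chain)


class TestSpaChain:
    def test_orthogonal_columns_selected_by_descending_norm(self):
        # orthogonal columns with norms 3 > 2 > 1: projections remove
        # nothing, so the chain follows the norms
        X = np.diag([3.0, 2.0, 1.0])
        np.testing.assert_array_equal(spa_chain(X, start=0, max_vars=3),
                                      [0, 1, 2])

    def test_duplicate_column_never_selected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 5))
        X[:, 3] = X[:, 0]  # exact duplicate of the start
        chain = spa_chain(X, start=0, max_vars=5)
        assert 3 not in chain

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_gram_schmidt_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 6))
        for start in range(6):
            np.testing.assert_array_equal(
                spa_chain(X, start, max_vars=6),
                gram_schmidt_chain(X, start, max_vars=6))


class TestSpaSelect:
    def test_returns_sorted_valid_subset(self, rng):
        X = rng.normal(size=(30, 15))
        y = X[:, 4] + 0.01 * rng.normal(size=30)
        res = spa_select(X, y, max_vars=8, wavelengths=np.arange(15.0) + 400)
        idx = res.selected_indices
        assert idx.size >= 1 and np.all(np.diff(idx) > 0)
        assert idx.max() < 15
        assert res.diagnostics["rmse_by_size"].size == 8
        np.testing.assert_array_equal(res.selected_nm, idx + 400.0)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            spa_select(rng.normal(size=(20, 5)), np.ones(20), max_vars=3)

    def test_max_vars_beyond_rank_bound_rejected(self, rng):
        with pytest.raises(ValueError, match="max_vars"):
            spa_select(rng.normal(size=(6, 4)), np.arange(6.0), max_vars=6)


class TestUve:
    @staticmethod
    def _planted(seed, n=40, p=25):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = 5.0 * X[:, 0] + 0.1 * rng.normal(size=n)
        return X, y

    def test_planted_signal_retained_noise_eliminated(self):
        kept_signal = 0
        noise_elimination = []
        for seed in range(20):
            X, y = self._planted(seed)
            res = uve_select(X, y, n_lv=3, seed=seed, min_keep=0)
            kept_signal += 0 in res.selected_indices
            pure_noise = set(range(1, X.shape[1]))
            survivors = pure_noise & set(res.selected_indices.tolist())
            noise_elimination.append(1 - len(survivors) / len(pure_noise))
        assert kept_signal == 20
        assert np.mean(noise_elimination) >= 0.90

    def test_null_response_retains_little(self):
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(30, 20))
            y = rng.normal(size=30)
            res = uve_select(X, y, n_lv=3, threshold_factor=1.0, seed=seed,
                             min_keep=0)
            fractions.append(res.n_selected / 20)
        assert np.mean(fractions) < 0.10

    def test_threshold_boundaries(self, rng):
        X, y = self._planted(0)
        nothing = uve_select(X, y, n_lv=3, threshold_factor=1e12, seed=0,
                             min_keep=0)
        assert nothing.n_selected == 0
        everything = uve_select(X, y, n_lv=3, threshold_factor=0.0, seed=0)
        assert everything.n_selected == X.shape[1]

    def test_degenerate_fallback_keeps_most_stable(self):
        X, y = self._planted(3)
        with pytest.warns(RuntimeWarning, match="retaining"):
            res = uve_select(X, y, n_lv=3, threshold_factor=1e12, seed=0,
                             min_keep=2)
        assert res.n_selected == 2
        assert 0 in res.selected_indices  # the planted column is most stable

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            uve_select(rng.normal(size=(4, 6)), np.arange(4.0))


class TestCars:
    def test_reduction_schedule_closed_form(self):
        r = cars_reduction_schedule(p=1401, n_runs=100)
        assert r[0] == pytest.approx(1.0)
        assert r[-1] == pytest.approx(2.0 / 1401)
        assert np.all(np.diff(r) < 0)

    def test_traces_and_monotone_counts(self, rng):
        X = rng.normal(size=(40, 60))
        y = X[:, 10] - X[:, 40] + 0.05 * rng.normal(size=40)
        res = cars_select(X, y, n_lv=5, n_runs=30, seed=1)
        d = res.diagnostics
        assert d["rmsecv"].size == 30 and d["n_retained"].size == 30
        assert np.all(np.diff(d["n_retained"]) <= 0)
        assert d["n_retained"].min() >= 2
        assert res.best_run == int(np.argmin(d["rmsecv"]))
        assert d["rmsecv"][res.best_run] == d["rmsecv"].min()

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 40))
        y = X[:, 5] + 0.1 * rng.normal(size=30)
        a = cars_select(X, y, n_lv=3, n_runs=20, seed=9)
        b = cars_select(X, y, n_lv=3, n_runs=20, seed=9)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
        np.testing.assert_array_equal(a.diagnostics["rmsecv"],
                                      b.diagnostics["rmsecv"])

    def test_planted_columns_survive(self, rng):
        X = rng.normal(size=(50, 80))
        y = 3.0 * X[:, 12] - 2.0 * X[:, 60] + 0.05 * rng.normal(size=50)
        res = cars_select(X, y, n_lv=5, n_runs=50, seed=4)
        assert {12, 60} <= set(res.selected_indices.tolist())

    def test_preconditions(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="3 variables"):
            cars_select(X, np.arange(20.0))
        with pytest.raises(ValueError, match="2 sampling"):
            cars_select(rng.normal(size=(20, 10)), np.arange(20.0), n_runs=1)


def test_selection_result_serializes(tmp_path, rng):
    X = rng.normal(size=(30, 20))
    y = X[:, 3] + 0.1 * rng.normal(size=30)
    res = cars_select(X, y, n_lv=3, n_runs=10, seed=0,
                      wavelengths=400 + np.arange(20.0))
    out = tmp_path / "sel.json"
    res.to_json(out)
    import json
    payload = json.loads(out.read_text())
    assert payload["method"] == "cars"
    assert payload["selected_indices"] == res.selected_indices.tolist()
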