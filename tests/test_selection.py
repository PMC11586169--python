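"""Binning arithmetic, BVS elimination vs greedy oracle, SA behavior, combined path."""

import itertools

import numpy as np
import pytest

from nirselect import SimulationConfig, generate, pls, selection, to_absorbance
from nirselect.containers import SpectrumSet
from nirselect.selection import (AnnealingConfig, RmsecvObjective, bin_matrix,
                                 bin_spectrum, bvs_pls, combined_select, sa_select)


def _sset(X):
    return SpectrumSet(np.arange(X.shape[1], dtype=float) + 500.0, X,
                       [f"s{i}" for i in range(X.shape[0])])


# -- binning --------------------------------------------------------------

class TestBinning:
    @pytest.mark.parametrize("width,expected", [(32, 64), (16, 128), (8, 256)])
    def test_2048_grid_bin_counts(self, width, expected):
        X = np.ones((2, 2048))
        assert bin_matrix(X, width).shape[1] == expected

    def test_constant_ones_width_16(self):
        out = bin_matrix(np.ones((3, 64)), 16)
        np.testing.assert_array_equal(out, np.full((3, 4), 16.0))

    def test_tiny_example(self):
        np.testing.assert_array_equal(bin_matrix(np.array([[1.0, 2, 3, 4]]), 2),
                                      [[3.0, 7.0]])

    def test_total_intensity_conserved(self, rng):
        X = rng.normal(size=(5, 96))
        for width in (2, 8, 32):
            np.testing.assert_allclose(bin_matrix(X, width).sum(axis=1),
                                       X.sum(axis=1), atol=1e-9)

    def test_nondivisible_width_rejected_with_hint(self):
        with pytest.raises(ValueError, match="valid widths"):
            bin_matrix(np.ones((1, 100)), 16)

    def test_binned_labels_are_range_midpoints(self, rng):
        sset = _sset(rng.normal(size=(3, 16)))
        binned, gmap = bin_spectrum(sset, 4)
        # wavelengths 500..515; first bin covers 500-503 -> midpoint 501.5
        np.testing.assert_allclose(binned.wavelengths, [501.5, 505.5, 509.5, 513.5])
        assert gmap.w == 16 and gmap.n == 4 and gmap.m == 4
        assert gmap.group_ranges[1] == (4, 8)


# -- BVS ------------------------------------------------------------------

def _grouped_problem(rng, n=36, informative=6, noise=1):
    """y is a sparse combination of informative columns; extra pure-noise columns."""
    p = informative + noise
    X = rng.normal(size=(n, p))
    coefs = rng.uniform(1.0, 2.0, size=informative)
    y = X[:, :informative] @ coefs  # noiseless signal
    return X, y


class TestBVS:
    def test_noise_group_eliminated_first(self, rng):
        X, y = _grouped_problem(rng, informative=6, noise=1)
        res = bvs_pls(X, y, cv="loo", max_lv=6)
        assert res.elimination_order[0] == 6  # the pure-noise column
        # oracle: exhaustively evaluate all single removals at the first step
        obj = RmsecvObjective(X, y, cv="loo", max_lv=6)
        vals = [obj([v for v in range(7) if v != g]) for g in range(7)]
        assert int(np.argmin(vals)) == 6

    def test_single_group_returned_unchanged(self, rng):
        X = rng.normal(size=(20, 1))
        y = X[:, 0] * 2
        res = bvs_pls(X, y)
        np.testing.assert_array_equal(res.selected, [0])
        assert res.rmsecv_trace == [] and res.elimination_order == []

    def test_min_groups_at_or_above_current_is_identity(self, rng):
        X, y = _grouped_problem(rng)
        res = bvs_pls(X, y, min_groups=7)
        np.testing.assert_array_equal(res.selected, np.arange(7))
        assert res.rmsecv_trace == []

    def test_trace_strictly_decreasing(self, rng):
        X, y = _grouped_problem(rng, n=30, informative=4, noise=4)
        res = bvs_pls(X, y, cv="loo", max_lv=4)
        trace = np.array(res.rmsecv_trace)
        assert np.all(np.diff(trace) < 0)

    def test_full_path_matches_bruteforce_greedy_oracle(self):
        """<=10 groups: the whole elimination path equals an independent greedy
        loop that re-evaluates every candidate removal with rmsecv directly."""
        for seed in (0, 1, 2):
            g = np.random.default_rng(seed)
            X = g.normal(size=(25, 8))
            beta = np.concatenate([g.uniform(0.5, 1.5, size=4), np.zeros(4)])
            y = X @ beta + 0.3 * g.normal(size=25)
            res = bvs_pls(X, y, cv="loo", max_lv=5, min_groups=2)

            # independent greedy oracle
            current = list(range(8))
            cap = 5

            def score(cols):
                cv = pls.rmsecv(X[:, cols], y, min(cap, len(cols)), cv="loo")
                return float(cv.rmsecv_by_lv[cv.chosen_lv - 1])

            order, trace = [], [score(current)]
            while len(current) > 2:
                candidates = [(score([v for v in current if v != g_]), g_)
                              for g_ in current]
                best_val, best_g = min(candidates, key=lambda t: (t[0], t[1]))
                if best_val >= trace[-1]:
                    break
                current = [v for v in current if v != best_g]
                order.append(best_g)
                trace.append(best_val)

            assert res.elimination_order == order, f"seed {seed}"
            np.testing.assert_allclose(res.rmsecv_trace, trace, atol=1e-10)
            np.testing.assert_array_equal(res.selected, sorted(current))


# -- SA -------------------------------------------------------------------

class TestSA:
    def test_k_equals_all_variables_returns_immediately(self, rng):
        X, y = _grouped_problem(rng, informative=3, noise=0)
        res = sa_select(X, y, AnnealingConfig(k=3, seed=0))
        np.testing.assert_array_equal(res.selected, [0, 1, 2])
        assert res.accepted_moves == []

    def test_zero_temperature_is_greedy(self, rng):
        """With T ~ 0 throughout, the accepted-state objective never increases."""
        X = rng.normal(size=(30, 10))
        y = X[:, 2] - X[:, 5] + 0.2 * rng.normal(size=30)
        res = sa_select(X, y, AnnealingConfig(k=3, T0=1e-12, Te=1e-13, seed=1, L=150))
        accepted = [m[3] for m in res.accepted_moves]
        start = res.rmsecv_trace[0]
        assert all(b <= a + 1e-12 for a, b in zip([start] + accepted, accepted))

    def test_best_ever_trace_non_increasing(self, rng):
        X, y = _grouped_problem(rng, informative=4, noise=4)
        res = sa_select(X, y, AnnealingConfig(k=3, seed=5, L=100))
        trace = np.array(res.rmsecv_trace)
        assert np.all(np.diff(trace) <= 1e-15)

    def test_final_objective_self_consistent(self, rng):
        X, y = _grouped_problem(rng, informative=4, noise=4)
        res = sa_select(X, y, AnnealingConfig(k=3, seed=5, L=100))
        fresh = RmsecvObjective(X, y)
        assert fresh(res.selected) == pytest.approx(res.objective_final, abs=1e-12)

    def test_finds_global_optimum_small_problem(self):
        g = np.random.default_rng(3)
        X = g.normal(size=(30, 8))
        y = X[:, 1] - 0.8 * X[:, 6] + 0.3 * g.normal(size=30)
        obj = RmsecvObjective(X, y, max_lv=4)
        best = min(itertools.combinations(range(8), 2), key=lambda s: obj(list(s)))
        res = sa_select(X, y, AnnealingConfig(k=2, seed=0), obj)
        assert tuple(res.selected) == tuple(sorted(best))

    def test_k_too_large_rejected(self, rng):
        X, y = _grouped_problem(rng)
        with pytest.raises(ValueError, match="k="):
            sa_select(X, y, AnnealingConfig(k=50))

    @pytest.mark.parametrize("kwargs", [
        dict(k=0), dict(k=2, T0=-1.0), dict(k=2, alpha=1.5),
        dict(k=2, cooling_rule="bogus"), dict(k=2, L=0),
    ])
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            AnnealingConfig(**kwargs)


# -- combined -------------------------------------------------------------

@pytest.fixture(scope="module")
def problem():
    cfg = SimulationConfig(n_samples=48, n_wavelengths=512, seed=31)
    sset, ref, gt = generate(cfg)
    return to_absorbance(sset), ref, gt


class TestCombined:
    def test_structural_contract(self, problem):
        sset, ref, _ = problem
        res = combined_select(sset, ref.ssc, bin_width=16, k=6, cv="kfold:5",
                              fast_lv=True,
                              sa_config=AnnealingConfig(k=6, seed=2, L=120))
        assert len(res.original_ranges) == 6
        assert all(hi - lo == 16 for lo, hi in res.original_ranges)
        assert res.original_indices.size == 96
        assert np.all(np.diff(res.selected_bins) > 0)

    def test_k_equal_to_survivors_makes_sa_identity(self, problem):
        sset, ref, _ = problem
        res = combined_select(sset, ref.ssc, bin_width=32, k=8, min_groups=8,
                              cv="kfold:5", fast_lv=True,
                              sa_config=AnnealingConfig(k=8, seed=0, L=50))
        assert res.bvs.selected.size == 8
        np.testing.assert_array_equal(res.selected_bins, res.bvs.selected)
        assert "single subset" in res.sa.provenance.get("note", "")

    def test_k_beyond_survivors_rejected(self, problem):
        sset, ref, _ = problem
        with pytest.raises(ValueError, match="survivors"):
            combined_select(sset, ref.ssc, bin_width=32, k=12, min_groups=4,
                            cv="kfold:5", fast_lv=True)

    def test_informative_bands_recovered(self, problem):
        """Most selected original-grid indices fall inside true band support."""
        sset, ref, gt = problem
        fracs = []
        for seed in (0, 1):
            res = combined_select(sset, ref.ssc, bin_width=16, k=6, cv="kfold:5",
                                  fast_lv=True,
                                  sa_config=AnnealingConfig(k=6, seed=seed))
            fracs.append(np.isin(res.original_indices, gt.informative_indices).mean())
        assert np.median(fracs) >= 0.6
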