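"""FNC screening: curve arithmetic, stopping rule, nesting, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fnclasso import (
    DegenerateSignalError,
    InvalidInputError,
    PValueVector,
    default_eps_grid,
    fnc_screen,
    fnp_curve,
    threshold_index,
)
from fnclasso.screening import ALL


def naive_screen(p_sorted, s_hat, eps):
    """Brute-force reference: evaluate the FNP estimate at every j by the
    definition and return the first index strictly below eps (else m)."""
    m = len(p_sorted)
    for j in range(1, m + 1):
        fnp = max(1 - j / s_hat + (m - s_hat) * p_sorted[j - 1] / s_hat, 0.0)
        if fnp < eps:
            return j
    return m


class TestFnpCurve:
    def test_all_signal_case_is_linear(self, rng):
        # s_hat = m kills the false-positive term: FNP(j) = 1 - j/m
        p = np.sort(rng.uniform(size=10))
        c = fnp_curve(PValueVector(p), 10)
        np.testing.assert_allclose(c.fnp_hat, 1 - np.arange(1, 11) / 10)
        assert c.fnp_hat[-1] == 0.0

    def test_direct_arithmetic(self):
        # m=100, s=10: at j=5 with p_(5)=0.001 the estimate is
        # 1 - 0.5 + 90*0.001/10 = 0.509
        p = np.concatenate([np.full(5, 0.001), np.linspace(0.2, 0.9, 95)])
        c = fnp_curve(PValueVector(p), 10)
        assert c.fnp_hat[4] == pytest.approx(0.509)

    def test_lower_clamp(self):
        # beyond j = s with p_(j) = 0 the raw value is negative -> clamp at 0
        p = np.concatenate([np.zeros(60), np.linspace(0.5, 0.99, 40)])
        c = fnp_curve(PValueVector(p), 50)
        assert c.fnp_hat[59] == 0.0

    def test_can_exceed_one_for_small_j(self):
        # no upper clamp: with many nulls at moderate p the estimate > 1
        p = np.full(100, 0.5)
        c = fnp_curve(PValueVector(p), 2)
        assert c.fnp_hat[0] > 1.0

    def test_zero_signal_estimate_rejected(self, rng):
        with pytest.raises(DegenerateSignalError):
            fnp_curve(PValueVector(rng.uniform(size=20)), 0)


class TestThresholdIndex:
    def test_first_strict_crossing(self):
        c = _curve_with([0.9, 0.6, 0.3, 0.1, 0.0])
        assert threshold_index(c, 0.35) == 3

    def test_linear_curve_crossing(self):
        # FNP(j) = 1 - j/10: first j with value < 0.25 is j = 8
        p = np.sort(np.random.default_rng(0).uniform(size=10))
        c = fnp_curve(PValueVector(p), 10)
        assert threshold_index(c, 0.25) == 8

    def test_equality_does_not_qualify(self):
        c = _curve_with([0.5, 0.2, 0.1])
        assert threshold_index(c, 0.2) == 3

    def test_sentinel_when_no_crossing(self):
        c = _curve_with([0.9, 0.8, 0.7])
        assert threshold_index(c, 0.5) == ALL

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.1, 1.5])
    def test_eps_out_of_range(self, eps):
        c = _curve_with([0.5, 0.1])
        with pytest.raises(InvalidInputError):
            threshold_index(c, eps)


def _curve_with(values):
    from fnclasso import FNPCurve

    v = np.asarray(values, dtype=float)
    ids = tuple(f"s{i}" for i in range(v.size))
    return FNPCurve(v, ids, np.linspace(0, 1, v.size), 1)


class TestFncScreen:
    def test_default_grid_is_k20(self):
        g = default_eps_grid()
        assert g.size == 20
        assert g[0] == pytest.approx(0.02)
        assert g[-1] == pytest.approx(0.40)
        np.testing.assert_allclose(np.diff(g), 0.02)

    def test_planted_signals_recovered(self):
        # 50 signals at p = 1e-12 among 4950 uniforms: at eps = 0.02 the
        # reduced set must contain essentially all of them and stay small
        recalls, sizes = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            p = np.concatenate([np.full(50, 1e-12), r.uniform(size=4950)])
            ids = tuple(f"v{i}" for i in range(p.size))
            res = fnc_screen(PValueVector(p, ids), [0.02], s_hat=50)
            got = set(res.reduced_sets[0])
            recalls.append(len(got & {f"v{i}" for i in range(50)}) / 50)
            sizes.append(len(got))
        assert min(recalls) >= 0.98
        assert max(sizes) <= 200

    def test_nesting_across_grid(self, rng):
        p = rng.uniform(size=400) ** 3
        res = fnc_screen(PValueVector(p))
        for a, b in zip(res.reduced_sets, res.reduced_sets[1:]):
            assert set(b) <= set(a)

    def test_matches_naive_enumeration(self, rng):
        for _ in range(50):
            m = int(rng.integers(5, 200))
            p = rng.uniform(size=m) ** rng.integers(1, 4)
            s = int(rng.integers(1, m + 1))
            eps_grid = np.sort(rng.uniform(0.01, 0.99, size=3))
            eps_grid = np.unique(np.round(eps_grid, 6))
            if eps_grid.size < 2 or np.any(np.diff(eps_grid) <= 0):
                continue
            res = fnc_screen(PValueVector(p), eps_grid, s_hat=s)
            p_sorted = np.sort(p)
            for k, eps in enumerate(eps_grid):
                assert res.cutoff_index[k] == naive_screen(p_sorted, s, eps)

    def test_tie_permutation_keeps_sizes(self, rng):
        p = np.round(rng.uniform(size=100), 1)  # heavy ties
        ids = [f"t{i}" for i in range(100)]
        res1 = fnc_screen(PValueVector(p, ids), s_hat=10)
        perm = rng.permutation(100)
        res2 = fnc_screen(PValueVector(p[perm], [ids[i] for i in perm]), s_hat=10)
        assert res1.cutoff_index == res2.cutoff_index
        # with the (p, id) tie-break, membership is identical too
        assert res1.reduced_sets == res2.reduced_sets

    def test_duplicate_sets_flagged(self):
        p = np.concatenate([np.full(10, 1e-9), np.linspace(0.3, 0.9, 90)])
        res = fnc_screen(PValueVector(p), s_hat=10)
        dup = np.asarray(res.duplicate_of)
        assert (dup >= 0).any()
        k = int(np.flatnonzero(dup >= 0)[0])
        assert res.reduced_sets[k] == res.reduced_sets[dup[k]]

    def test_bad_grids_rejected(self, rng):
        p = PValueVector(rng.uniform(size=10))
        for grid in ([], [0.4, 0.2], [0.0, 0.5], [0.5, 1.0]):
            with pytest.raises(InvalidInputError):
                fnc_screen(p, grid, s_hat=2)

    def test_degenerate_signal_propagates(self):
        p = np.full(100, 0.99)  # nothing resembling signal
        with pytest.raises(DegenerateSignalError):
            fnc_screen(PValueVector(p))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    data=st.data(),
    m=st.integers(min_value=5, max_value=80),
)
def test_screen_prefix_property(data, m):
    """Every reduced set is a prefix of the p-sorted SNP list and sizes
    match the stopping rule computed by brute force."""
    p = np.array(
        data.draw(
            st.lists(
                st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=m, max_size=m,
            )
        )
    )
    s = data.draw(st.integers(min_value=1, max_value=m))
    res = fnc_screen(PValueVector(p), [0.1, 0.3], s_hat=s)
    order = np.lexsort((np.array([f"snp{i}" for i in range(m)], dtype=object), p))
    sorted_ids = tuple(f"snp{i}" for i in order)
    for k in range(2):
        j = res.cutoff_index[k]
        assert res.reduced_sets[k] == sorted_ids[:j]
        assert j == naive_screen(np.sort(p), s, res.eps_grid[k])
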