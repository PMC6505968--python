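import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainabc.distances import sbtp
from brainabc.morris import (
    SensitivityResult,
    elementary_effects,
    joint_summary,
    make_ranges,
    morris_design,
    rank_top,
)


class TestMakeRanges:
    def test_half_fraction_examples(self):
        ranges = make_ranges({"r_t": 0.018, "Xtot": 9.1})
        assert ranges["r_t"] == pytest.approx((0.009, 0.027))
        assert ranges["Xtot"] == pytest.approx((4.55, 13.65))

    def test_zero_default_rejected(self):
        with pytest.raises(ValueError, match="explicit bounds"):
            make_ranges({"p": 0.0})

    def test_negative_default_gives_ordered_bounds(self):
        lo, hi = make_ranges({"p": -2.0})["p"]
        assert lo < hi

    @pytest.mark.parametrize("bad", [0.0, 1.5, -0.2])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            make_ranges({"p": 1.0}, fraction=bad)


class TestMorrisDesign:
    def test_row_count(self):
        bounds = {f"p{i}": (0.0, 1.0) for i in range(10)}
        d = morris_design(bounds, n_trajectories=20, levels=4, seed=0)
        assert d.matrix.shape == (20 * 11, 10)

    def test_one_factor_changes_per_step(self):
        bounds = {f"p{i}": (0.0, 2.0) for i in range(5)}
        d = morris_design(bounds, n_trajectories=10, levels=4, seed=1)
        for tr in range(10):
            U = d.unit_matrix[d.trajectory_index == tr]
            for i in range(U.shape[0] - 1):
                du = U[i + 1] - U[i]
                changed = np.nonzero(np.abs(du) > 1e-12)[0]
                assert changed.size == 1
                assert abs(du[changed[0]]) == pytest.approx(d.delta)

    def test_reproducible_under_seed(self):
        bounds = {"a": (0.0, 1.0), "b": (1.0, 3.0)}
        d1 = morris_design(bounds, 5, 4, seed=3)
        d2 = morris_design(bounds, 5, 4, seed=3)
        np.testing.assert_array_equal(d1.matrix, d2.matrix)

    @pytest.mark.parametrize("levels", [3, 5, 2])
    def test_odd_or_small_levels_rejected(self, levels):
        with pytest.raises(ValueError):
            morris_design({"a": (0, 1)}, 5, levels=levels)

    @given(
        st.integers(1, 6),
        st.integers(2, 8),
        st.sampled_from([4, 6, 8]),
        st.integers(0, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_samples_always_within_bounds(self, k, r, levels, seed):
        rng = np.random.default_rng(seed)
        bounds = {}
        for i in range(k):
            lo = rng.uniform(-5, 5)
            bounds[f"p{i}"] = (lo, lo + rng.uniform(0.1, 5))
        d = morris_design(bounds, r, levels, seed=seed)
        for j, name in enumerate(d.names):
            lo, hi = bounds[name]
            assert d.matrix[:, j].min() >= lo - 1e-12
            assert d.matrix[:, j].max() <= hi + 1e-12


class TestElementaryEffects:
    def test_linear_response_recovers_coefficient(self):
        bounds = {"u1": (0.0, 1.0), "u2": (0.0, 1.0), "u3": (0.0, 1.0)}
        d = morris_design(bounds, n_trajectories=8, levels=4, seed=5)
        response = 3.0 * d.unit_matrix[:, 0]
        res = elementary_effects(d, response)
        assert res.mu_star["response"]["u1"] == pytest.approx(3.0)
        assert res.sigma["response"]["u1"] == pytest.approx(0.0, abs=1e-12)
        for p in ("u2", "u3"):
            assert res.mu_star["response"][p] == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_all_zero(self):
        d = morris_design({"a": (0, 1), "b": (0, 1)}, 5, 4, seed=2)
        res = elementary_effects(d, np.full(d.matrix.shape[0], 7.7))
        assert all(v == 0.0 for v in res.mu_star["response"].values())
        assert all(v == 0.0 for v in res.sigma["response"].values())

    def test_response_count_mismatch_rejected(self):
        d = morris_design({"a": (0, 1)}, 3, 4, seed=0)
        with pytest.raises(ValueError, match="design rows"):
            elementary_effects(d, np.zeros(5))

    def test_nonfinite_trajectories_dropped_whole(self):
        d = morris_design({"a": (0, 1), "b": (0, 1)}, 6, 4, seed=9)
        response = 2.0 * d.unit_matrix[:, 0]
        response[d.trajectory_index == 2] = np.nan
        res = elementary_effects(d, response)
        assert res.n_trajectories_dropped == 1
        assert res.n_trajectories_used == 5
        assert res.mu_star["response"]["a"] == pytest.approx(2.0)

    def test_toy_sbtp_summary_separates_amplitude_from_offset(self):
        """With an SBTP summary, the amplitude parameter a of
        y = a*x*sin(x) + b dominates the offset parameter b by >10x."""
        from brainabc.models.toy import toy_grid

        x = toy_grid(200)
        rng = np.random.default_rng(0)
        y0 = rng.normal(0.0, 0.005, x.size)  # default signal: noise only
        ref_range = float(np.ptp(y0))
        d = morris_design({"a": (0.5, 1.5), "b": (-0.5, 0.5)}, 20, 4, seed=4)
        resp = np.array(
            [sbtp(row[0] * x * np.sin(x) + row[1], ref_range) for row in d.matrix]
        )
        res = elementary_effects(d, resp)
        mu = res.mu_star["response"]
        assert mu["a"] / max(mu["b"], 1e-12) > 10


class TestJointAndRanking:
    def test_joint_summary_single_output_is_identity(self):
        v = np.arange(4.0)
        np.testing.assert_array_equal(joint_summary({"x": v}), v)

    def test_joint_summary_two_equal_outputs_double(self):
        v = np.arange(4.0)
        np.testing.assert_array_equal(joint_summary({"x": v, "y": v}), 2 * v)

    def test_joint_summary_matches_manual_table(self):
        table = {k: np.array(vals, float) for k, vals in
                 [("a", [1, 2, 3, 4]), ("b", [10, 20, 30, 40]), ("c", [0.1, 0.2, 0.3, 0.4])]}
        np.testing.assert_allclose(
            joint_summary(table), [11.1, 22.2, 33.3, 44.4]
        )

    def test_joint_summary_ragged_rejected(self):
        with pytest.raises(ValueError):
            joint_summary({"a": np.zeros(3), "b": np.zeros(4)})

    def _result(self, mu):
        names = list(mu)
        return SensitivityResult(
            names, {"joint": mu}, {"joint": {k: 0.0 for k in mu}}, 1
        )

    def test_rank_top_orders_by_mu_star(self):
        res = self._result({"p1": 3.0, "p2": 1.0, "p3": 2.0})
        assert rank_top(res, n=2) == ["p1", "p3"]

    def test_rank_all_gives_full_ordering(self):
        res = self._result({"p1": 3.0, "p2": 1.0, "p3": 2.0})
        assert rank_top(res, n=3) == ["p1", "p3", "p2"]

    def test_exact_ties_broken_by_declaration_order(self):
        res = self._result({"z_first": 1.0, "a_second": 1.0})
        assert rank_top(res, n=2) == ["z_first", "a_second"]


class TestScreeningOnSurrogate:
    def test_inert_parameter_ranks_last_with_zero_mu_star(
        self, minibrain, healthy_protocol
    ):
        from brainabc.morris import run_morris

        ins, _ = healthy_protocol
        res, _ = run_morris(
            minibrain,
            ins,
            parameters=["r_t", "Xtot", "sigma_coll", "dummy"],
            outputs=["TOI", "DHbO2", "DHHb", "DCCO"],
            n_trajectories=6,
            seed=13,
        )
        assert res.mu_star["joint"]["dummy"] == 0.0
        assert res.ranking("joint")[-1] == "dummy"
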