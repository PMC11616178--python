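"""MPT engine: closed-form fits vs numeric oracles, G² tests, Holm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from ctxbind import (
    ConditionKey,
    FrequencyTable,
    MptParams,
    Restriction,
    category_probabilities,
    effect_size_omega,
    fit_restricted,
    fit_saturated,
    holm_correction,
    interaction_test,
    read_tables_csv,
    write_tables_csv,
)

from oracles import (
    grid_equal_difference_g2,
    numeric_equal_prr_fit,
    numeric_saturated_fit,
)


def make_table(tt, rel, counts):
    return FrequencyTable(ConditionKey(tt, rel), *counts)


# ---------------------------------------------------------------------------
# category probabilities


class TestCategoryProbabilities:
    @pytest.mark.parametrize(
        "params, expected",
        [
            ((0.5, 0.5, 0.5), (0.5, 0.25, 0.125, 0.125)),
            ((1.0, 0.3, 0.7), (1.0, 0.0, 0.0, 0.0)),
            ((0.4, 1 / 6, 0.6), (0.4, 0.1, 0.3, 0.2)),
        ],
    )
    def test_known_values(self, params, expected):
        np.testing.assert_allclose(
            category_probabilities(MptParams(*params)), expected, atol=1e-12
        )

    @given(
        ci=st.floats(0, 1),
        psc=st.floats(0, 1),
        prr=st.floats(0, 1),
    )
    def test_always_sums_to_one(self, ci, psc, prr):
        p = category_probabilities(MptParams(ci, psc, prr))
        assert p.min() >= 0
        assert abs(p.sum() - 1.0) < 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            MptParams(1.2, 0.5, 0.5)


# ---------------------------------------------------------------------------
# saturated fit


class TestSaturatedFit:
    def test_worked_example(self):
        fit = fit_saturated(FrequencyTable("t", 40, 10, 30, 20))
        p = fit.estimates["t"]
        assert p.ci == pytest.approx(0.40)
        assert p.psc == pytest.approx(1 / 6)
        assert p.prr == pytest.approx(0.60)
        assert fit.g_squared == 0.0 and fit.df == 0

    def test_equal_counts(self):
        p = fit_saturated(FrequencyTable("t", 25, 25, 25, 25)).estimates["t"]
        assert (p.ci, p.psc, p.prr) == pytest.approx((0.25, 1 / 3, 0.5))

    def test_undefined_ratios_flagged(self):
        fit = fit_saturated(FrequencyTable("t", 100, 0, 0, 0))
        p = fit.estimates["t"]
        assert p.ci == 1.0
        assert math.isnan(p.psc) and math.isnan(p.prr)
        assert set(fit.undefined["t"]) == {"psc", "prr"}

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fit_saturated(FrequencyTable("t", 0, 0, 0, 0))

    def test_matches_numeric_maximizer_on_random_tables(self, rng):
        for _ in range(25):
            counts = rng.multinomial(
                int(rng.integers(40, 500)), rng.dirichlet([2, 2, 2, 2])
            )
            if min(counts) == 0:
                continue
            p = fit_saturated(FrequencyTable("t", *map(int, counts))).estimates["t"]
            oracle = numeric_saturated_fit(counts)
            np.testing.assert_allclose([p.ci, p.psc, p.prr], oracle, atol=1e-6)

    @given(
        counts=st.tuples(
            st.integers(1, 200),
            st.integers(1, 200),
            st.integers(1, 200),
            st.integers(1, 200),
        )
    )
    @settings(max_examples=60)
    def test_roundtrip_probabilities_reproduce_proportions(self, counts):
        table = FrequencyTable("t", *counts)
        p = fit_saturated(table).estimates["t"]
        probs = category_probabilities(p)
        np.testing.assert_allclose(
            probs * table.n_total, counts, atol=1e-8
        )


# ---------------------------------------------------------------------------
# restricted fits


class TestEqualPrrRestriction:
    def test_worked_pair_against_constrained_oracle(self):
        ir = make_table("IR", "repeated", (40, 10, 30, 20))
        c = make_table("C", "repeated", (40, 10, 10, 40))
        fit = fit_restricted(
            [ir, c], Restriction("equate_params", "prr", trees=(ir.tree_id, c.tree_id))
        )
        assert fit.extras["pooled"]["prr"] == pytest.approx(0.40)
        assert fit.df == 1
        assert fit.g_squared == pytest.approx(17.2609, abs=1e-3)
        # independent constrained numeric optimizer oracle
        _, ll_oracle = numeric_equal_prr_fit((40, 10, 30, 20), (40, 10, 10, 40))
        ll_sat = fit_saturated(ir).loglik + fit_saturated(c).loglik
        assert fit.g_squared == pytest.approx(2 * (ll_sat - ll_oracle), abs=1e-3)

    def test_identical_tables_give_zero_g2(self):
        a = make_table("IR", "changed", (40, 10, 30, 20))
        b = make_table("C", "changed", (40, 10, 30, 20))
        fit = fit_restricted(
            [a, b], Restriction("equate_params", "prr", trees=(a.tree_id, b.tree_id))
        )
        assert fit.g_squared == pytest.approx(0.0, abs=1e-12)

    def test_nonbinding_constraint_gives_zero_g2(self):
        a = make_table("IR", "repeated", (10, 10, 5, 5))
        b = make_table("C", "repeated", (20, 20, 10, 10))
        fit = fit_restricted(
            [a, b], Restriction("equate_params", "prr", trees=(a.tree_id, b.tree_id))
        )
        assert fit.g_squared == pytest.approx(0.0, abs=1e-12)

    def test_nesting_monotonicity(self, rng):
        """Adding trees to the equality constraint never decreases G²."""
        for _ in range(20):
            tabs = [
                FrequencyTable(
                    f"t{i}",
                    *map(int, rng.multinomial(200, rng.dirichlet([3, 3, 3, 3]))),
                )
                for i in range(3)
            ]
            g2_two = fit_restricted(
                tabs[:2],
                Restriction(
                    "equate_params", "prr", trees=(tabs[0].tree_id, tabs[1].tree_id)
                ),
            ).g_squared
            g2_three = fit_restricted(
                tabs,
                Restriction(
                    "equate_params", "prr", trees=tuple(t.tree_id for t in tabs)
                ),
            ).g_squared
            assert g2_three >= g2_two - 1e-9
            assert g2_two >= 0

    def test_pooling_other_parameters(self):
        a = make_table("IR", "repeated", (30, 10, 30, 30))
        b = make_table("C", "repeated", (50, 30, 10, 10))
        fit = fit_restricted(
            [a, b], Restriction("equate_params", "ci", trees=(a.tree_id, b.tree_id))
        )
        assert fit.extras["pooled"]["ci"] == pytest.approx(80 / 200)
        assert fit.df == 1

    def test_unknown_tree_rejected(self):
        a = make_table("IR", "repeated", (30, 10, 30, 30))
        with pytest.raises(ValueError):
            fit_restricted(
                [a], Restriction("equate_params", "prr", trees=(a.tree_id, "ghost"))
            )


class TestInteractionTest:
    def make_four(self, prrs, n_stage3=100, n1=100, n2=50):
        tabs = {}
        for (tt, rel), prr in prrs.items():
            n3 = int(round(prr * n_stage3))
            tabs[(tt, rel)] = make_table(tt, rel, (n1, n2, n3, n_stage3 - n3))
        return tabs

    def test_null_case_zero_g2(self):
        prrs = {k: 0.3 for k in [("IR", "repeated"), ("C", "repeated"), ("IR", "changed"), ("C", "changed")]}
        tabs = self.make_four(prrs)
        fit = interaction_test(
            tabs[("IR", "repeated")], tabs[("C", "repeated")],
            tabs[("IR", "changed")], tabs[("C", "changed")],
        )
        assert fit.g_squared == pytest.approx(0.0, abs=1e-6)
        assert fit.converged

    def test_matches_grid_search_oracle(self):
        prrs = {
            ("IR", "repeated"): 0.6,
            ("C", "repeated"): 0.2,
            ("IR", "changed"): 0.4,
            ("C", "changed"): 0.3,
        }
        tabs = self.make_four(prrs)
        fit = interaction_test(
            tabs[("IR", "repeated")], tabs[("C", "repeated")],
            tabs[("IR", "changed")], tabs[("C", "changed")],
        )
        oracle = grid_equal_difference_g2(tabs)
        assert fit.df == 1
        assert fit.g_squared == pytest.approx(oracle, abs=1e-3)

    def test_restricted_differences_equal_exactly(self):
        prrs = {
            ("IR", "repeated"): 0.55,
            ("C", "repeated"): 0.25,
            ("IR", "changed"): 0.35,
            ("C", "changed"): 0.30,
        }
        tabs = self.make_four(prrs)
        fit = interaction_test(
            tabs[("IR", "repeated")], tabs[("C", "repeated")],
            tabs[("IR", "changed")], tabs[("C", "changed")],
        )
        est = {k: fit.estimates[tabs[k].tree_id].prr for k in tabs}
        d_rep = est[("IR", "repeated")] - est[("C", "repeated")]
        d_chg = est[("IR", "changed")] - est[("C", "changed")]
        assert d_rep == pytest.approx(d_chg, abs=1e-9)
        assert d_rep == pytest.approx(fit.extras["d_hat"], abs=1e-9)

    def test_empty_stage_three_rejected(self):
        tabs = self.make_four(
            {k: 0.3 for k in [("IR", "repeated"), ("C", "repeated"), ("IR", "changed"), ("C", "changed")]}
        )
        bad = make_table("IR", "repeated", (100, 50, 0, 0))
        with pytest.raises(ValueError):
            interaction_test(
                bad, tabs[("C", "repeated")], tabs[("IR", "changed")], tabs[("C", "changed")]
            )


# ---------------------------------------------------------------------------
# effect size and Holm correction


class TestOmega:
    @pytest.mark.parametrize(
        "g2, n, expected",
        [(4.0, 400, 0.1), (0.0, 123, 0.0), (17.26, 200, 0.29376)],
    )
    def test_values(self, g2, n, expected):
        assert effect_size_omega(g2, n) == pytest.approx(expected, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effect_size_omega(1.0, 0)
        with pytest.raises(ValueError):
            effect_size_omega(-1.0, 10)


class TestHolm:
    def test_step_down_example(self):
        np.testing.assert_allclose(
            holm_correction([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(holm_correction([0.5]), [0.5])
        np.testing.assert_allclose(holm_correction([0.0, 0.0, 0.0]), [0.0, 0.0, 0.0])

    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=12),
    )
    def test_never_rejects_more_than_uncorrected(self, p):
        adj = holm_correction(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    @given(p=st.floats(0.0001, 1), k=st.integers(1, 10))
    def test_equals_bonferroni_for_equal_p(self, p, k):
        adj = holm_correction([p] * k)
        np.testing.assert_allclose(adj, min(1.0, k * p), rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_correction([0.5, 1.5])
        with pytest.raises(ValueError):
            holm_correction([])


class TestTableIo:
    def test_csv_round_trip(self, tmp_path):
        tabs = [
            FrequencyTable(ConditionKey("IR", "repeated", "random"), 40, 10, 30, 20),
            FrequencyTable(ConditionKey("C", "changed", "random"), 35, 15, 25, 25),
        ]
        path = tmp_path / "tables.csv"
        write_tables_csv(tabs, path)
        back = read_tables_csv(path)
        assert back == tabs

    def test_fit_result_serializes(self):
        ir = make_table("IR", "repeated", (40, 10, 30, 20))
        c = make_table("C", "repeated", (40, 10, 10, 40))
        fit = fit_restricted(
            [ir, c], Restriction("equate_params", "prr", trees=(ir.tree_id, c.tree_id))
        )
        text = fit.to_json()
        assert '"g_squared"' in text and '"-:IR:repeated"' in text
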