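"""Structural and right-hand-side tests of the reaction network."""

import numpy as np
import pytest

import mtorstress as m
from mtorstress.network import (
    MK2206_EXTENT,
    POOLS,
    SPECIES,
    SPECIES_INDEX,
    InputProfile,
    build_model,
    enumerate_candidate_inputs,
    evaluate_rhs,
    with_stress_input,
)


def _rand_inputs(rng, **kw):
    totals = rng.uniform(0.5, 2.0, size=9)
    return InputProfile(pool_totals=totals, **kw)


class TestBuildModel:
    def test_every_variant_has_25_species_and_same_reactions(self):
        base = build_model("I")
        for tag in ("I", "II", "III", "IV", "V"):
            model = build_model(tag)
            assert len(model.species) == 25
            assert [r.key for r in model.reactions] == [r.key for r in base.reactions]

    def test_stress_input_placement_per_variant(self):
        expected = {"I": 0, "II": 1, "III": 2, "IV": 2, "V": 3}
        for tag, n in expected.items():
            assert build_model(tag).n_stress_inputs() == n
        assert build_model("I").mtorc1_stress_param is None
        assert build_model("V").mtorc1_stress_param == "k_stress_mTORC1"

    def test_iii_and_iv_differ_only_in_akt_activity_flag(self):
        m3, m4 = build_model("III"), build_model("IV")
        assert m3.reactions == m4.reactions
        assert m3.variant.aktS473_alone_activates
        assert not m4.variant.aktS473_alone_activates

    def test_unknown_tag_rejected_with_valid_tags_named(self):
        with pytest.raises(ValueError, match="I, II, III, IV, V"):
            build_model("VI")

    def test_pools_partition_species(self):
        seen = [sp for p in POOLS for sp in p.members]
        assert sorted(seen) == sorted(SPECIES)
        assert len(seen) == 25

    def test_multiplicity_two_only_for_second_phosphorylations(self):
        model = build_model("V")
        mult2 = {r.key for r in model.reactions if r.multiplicity == 2}
        assert mult2 == {
            ("Akt_pS473", "Akt_pT308_pS473"),
            ("Akt_pT308", "Akt_pT308_pS473"),
            ("PRAS40_pS183", "PRAS40_pT246_pS183"),
            ("PRAS40_pT246", "PRAS40_pT246_pS183"),
            ("p70_S6K_pT229", "p70_S6K_pT229_pT389"),
            ("p70_S6K_pT389", "p70_S6K_pT229_pT389"),
        }
        # each shares its rate constant with a first-phosphorylation partner
        by_param = {}
        for r in model.reactions:
            by_param.setdefault(r.rate_param, []).append(r.multiplicity)
        for r in model.reactions:
            if r.multiplicity == 2:
                assert 1 in by_param[r.rate_param]

    def test_free_parameter_count_is_91_over_three_conditions(self):
        from mtorstress.simulate import condition_init_params, standard_conditions

        model = build_model("V")
        n_model = sum(1 for p in model.parameters if not p.fixed)
        n_init = sum(
            len(condition_init_params(c)) for c in standard_conditions().values()
        )
        assert n_model + n_init == 91


class TestCandidateEnumeration:
    def test_37_unique_candidates_excluding_pi3k_activation(self):
        cands = enumerate_candidate_inputs(build_model("II"))
        keys = [c.key for c in cands]
        assert len(keys) == 37
        assert len(set(keys)) == 37
        assert ("PI3K", "PI3K_p") not in keys
        assert keys[0] == ("Akt", "Akt_pS473")
        assert keys[1] == ("Akt_pT308", "Akt_pT308_pS473")

    def test_rejected_for_models_with_two_inputs(self):
        with pytest.raises(ValueError, match="stress inputs"):
            enumerate_candidate_inputs(build_model("III"))


class TestWithStressInput:
    def test_adds_exactly_one_parameter_without_mutating_original(self):
        base = build_model("II")
        n0 = len(base.parameters)
        out = with_stress_input(base, ("Akt", "Akt_pS473"))
        assert len(out.parameters) == n0 + 1
        assert len(base.parameters) == n0
        assert base.n_stress_inputs() == 1 and out.n_stress_inputs() == 2

    def test_composition_builds_three_input_topology(self):
        m2 = build_model("II")
        m5ish = with_stress_input(with_stress_input(m2, ("Akt", "Akt_pS473")), "mTORC1")
        assert m5ish.n_stress_inputs() == 3
        assert m5ish.mtorc1_stress_param is not None

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError, match="not a candidate"):
            with_stress_input(build_model("II"), ("PI3K", "PI3K_p"))


class TestRHS:
    def test_zero_phospho_zero_input_state_is_stationary(self):
        model = build_model("I")
        x = np.zeros(25)
        for sp in ("IR_beta", "IRS1", "PI3K", "PDK1_cyt", "Akt", "TSC2",
                   "PRAS40", "p70_S6K", "4EBP1"):
            x[SPECIES_INDEX[sp]] = 1.0
        inputs = InputProfile(stress=0.0, aa=0.0, insulin=0.0,
                              pool_totals=np.ones(9))
        dx = evaluate_rhs(model, x, model.default_values(), inputs)
        assert np.allclose(dx, 0.0)

    def test_pool_derivative_sums_vanish_on_random_states(self, random_states):
        rng = np.random.default_rng(1)
        for tag in ("I", "III", "V"):
            model = build_model(tag)
            params = 10 ** rng.uniform(-3, 0, size=len(model.parameters))
            for x in random_states[:5]:
                from mtorstress.simulate import pool_totals

                inputs = InputProfile(stress=1.0, pool_totals=pool_totals(x) + 0.1)
                dx = evaluate_rhs(model, x, params, inputs)
                for pool in POOLS:
                    assert abs(dx[list(pool.member_indices)].sum()) < 1e-12

    def test_flux_table_matches_brute_force_enumeration(self, random_states):
        """Independent oracle: re-derive dx/dt by looping over the documented
        rate law for every reaction with plain Python arithmetic."""
        model = build_model("V")
        rng = np.random.default_rng(5)
        params = 10 ** rng.uniform(-2.5, 0, size=len(model.parameters))
        pidx = model.param_index
        from mtorstress.simulate import pool_totals

        for x in random_states[:5]:
            C = pool_totals(x) + 0.05
            inputs = InputProfile(stress=1.0, aa=1.0, pool_totals=C)
            s = 1.0 if model.variant.aktS473_alone_activates else 0.0
            act = {
                "none": 1.0,
                "insulin": 0.0,
                "A_IR": x[1] / C[0],
                "A_IRS1": x[3] / C[1],
                "A_PI3K": x[6] / C[2],
                "A_PDK1": x[8] / C[3],
                "A_Akt": (x[10] + s * x[11] + 2 * x[12]) / C[4],
                "A_S6K": (x[21] + x[22]) / C[7],
                "A_mTORC2": x[6] / C[2],
                "A_mTORC1": (
                    params[pidx["k_aa"]] * 1.0
                    + params[pidx["k_stress_mTORC1"]] * 1.0
                )
                * max(0.0, 1 - x[13] / C[5])
                * max(0.0, 1 - x[15] / C[6]),
            }
            expected = np.zeros(25)
            for r in model.reactions:
                v = (
                    params[pidx[r.rate_param]]
                    * r.multiplicity
                    * x[SPECIES_INDEX[r.substrate]]
                    * act[r.modifier]
                )
                if r.stress_param is not None:
                    v += params[pidx[r.stress_param]] * 1.0 * x[SPECIES_INDEX[r.substrate]]
                expected[SPECIES_INDEX[r.substrate]] -= v
                expected[SPECIES_INDEX[r.product]] += v
            got = evaluate_rhs(model, x, params, inputs)
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-14)

    def test_variant_nesting_v_without_stress_matches_model_i(self, random_states):
        """With all stress strengths zeroed, model V's RHS equals model I's
        on any state with no Akt-pS473 (where the variants' Akt activity
        formulas coincide)."""
        m1, m5 = build_model("I"), build_model("V")
        rng = np.random.default_rng(9)
        shared = 10 ** rng.uniform(-2, 0, size=len(m1.parameters))
        p1 = shared
        p5 = np.zeros(len(m5.parameters))
        idx5 = m5.param_index
        for name, v in zip(m1.param_names, shared):
            p5[idx5[name]] = v
        for x in random_states[:5]:
            x = x.copy()
            x[SPECIES_INDEX["Akt_pS473"]] = 0.0
            from mtorstress.simulate import pool_totals

            inputs = InputProfile(stress=1.0, pool_totals=pool_totals(x) + 0.1)
            np.testing.assert_array_equal(
                evaluate_rhs(m1, x, p1, inputs), evaluate_rhs(m5, x, p5, inputs)
            )

    def test_model_iv_equals_iii_when_s473_absent(self, random_states):
        m3, m4 = build_model("III"), build_model("IV")
        rng = np.random.default_rng(13)
        params = 10 ** rng.uniform(-2, 0, size=len(m3.parameters))
        for x in random_states[:5]:
            x = x.copy()
            x[SPECIES_INDEX["Akt_pS473"]] = 0.0
            from mtorstress.simulate import pool_totals

            inputs = InputProfile(stress=1.0, pool_totals=pool_totals(x) + 0.1)
            np.testing.assert_array_equal(
                evaluate_rhs(m3, x, params, inputs),
                evaluate_rhs(m4, x, params, inputs),
            )

    def test_boolean_inhibitor_contract(self, random_states):
        model = build_model("V")
        rng = np.random.default_rng(17)
        params = 10 ** rng.uniform(-2, 0, size=len(model.parameters))
        from mtorstress.simulate import pool_totals

        for x in random_states[:5]:
            C = pool_totals(x) + 0.1
            base = InputProfile(stress=1.0, pool_totals=C)
            wort = InputProfile(stress=1.0, wortmannin=True, pool_totals=C)
            mk = InputProfile(stress=1.0, mk2206=True, pool_totals=C)
            dx_w = evaluate_rhs(model, x, params, wort)
            # PI3K activation flux exactly zero: PI3K_p balance is pure decay
            i_p = SPECIES_INDEX["PI3K_p"]
            kd = params[model.param_index["kd_PI3K"]]
            assert dx_w[i_p] == pytest.approx(-kd * x[i_p], abs=0.0)
            # MK-2206 scales Akt-driven fluxes by exactly (1 - 0.83):
            # TSC2 phosphorylation is driven only by Akt activity
            dx_0 = evaluate_rhs(model, x, params, base)
            dx_m = evaluate_rhs(model, x, params, mk)
            i_t = SPECIES_INDEX["TSC2_pT1462"]
            kd_t = params[model.param_index["kd_TSC2_T1462"]]
            phos_0 = dx_0[i_t] + kd_t * x[i_t]
            phos_m = dx_m[i_t] + kd_t * x[i_t]
            assert phos_m == pytest.approx((1 - MK2206_EXTENT) * phos_0, rel=1e-12)

    def test_rhs_input_validation(self):
        model = build_model("V")
        p = model.default_values()
        inputs = InputProfile(pool_totals=np.ones(9))
        with pytest.raises(ValueError, match="negative"):
            evaluate_rhs(model, np.full(25, -1.0), p, inputs)
        bad = p.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            evaluate_rhs(model, np.full(25, 0.5), bad, inputs)


class TestRHSProperties:
    """Invariants over arbitrary admissible states (property-based)."""

    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=25, max_size=25),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_conservation_and_flux_signs(self, state, param_seed):
        from mtorstress.simulate import pool_totals

        model = build_model("V")
        x = np.array(state)
        rng = np.random.default_rng(param_seed)
        params = 10 ** rng.uniform(-3, 0, size=len(model.parameters))
        inputs = InputProfile(stress=1.0, pool_totals=pool_totals(x) + 0.1)
        dx = evaluate_rhs(model, x, params, inputs)
        assert np.all(np.isfinite(dx))
        for pool in POOLS:
            assert abs(dx[list(pool.member_indices)].sum()) < 1e-12
        # an empty pool state cannot be drained further
        x_empty = x.copy()
        x_empty[list(POOLS[4].member_indices)] = 0.0
        dx_e = evaluate_rhs(
            model, x_empty, params,
            InputProfile(stress=1.0, pool_totals=pool_totals(x_empty) + 0.1),
        )
        assert np.all(dx_e[list(POOLS[4].member_indices)] >= -1e-15)


def test_model_summary_lists_species_reactions_parameters(model_V):
    text = m.model_summary(model_V)
    assert "pool Akt" in text
    assert "PI3K -> PI3K_p" in text
    assert "k_stress_mTORC1" in text
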