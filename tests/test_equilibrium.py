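"""Coupled-equilibrium forward model and free-concentration solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipallo.equilibrium import (
    BindingModelParams,
    InconsistentFractionsError,
    SequentialBindingSpec,
    Totals,
    ValidationError,
    compute_equilibrium,
    derived_agl_constants,
    free_concentrations_from_fractions,
    mole_fractions_from_free,
    sequential_binding_fractions,
)

from conftest import bisect, oracle_equilibrium, random_system, two_state_closed_form


class TestValidation:
    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ValidationError):
            BindingModelParams(k_ag=-1.0, k_al=[], k_alng=[])
        with pytest.raises(ValidationError):
            BindingModelParams(k_ag=1e6, k_al=[1e5, 0.0], k_alng=[1e6, 1e6])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            BindingModelParams(k_ag=1e6, k_al=[1e5], k_alng=[1e6, 1e6])

    def test_negative_totals_rejected(self):
        with pytest.raises(ValidationError):
            Totals(a_total=-1e-6, g_total=1e-6, l_total=0.0)
        with pytest.raises(ValidationError):
            Totals(a_total=float("nan"), g_total=1e-6, l_total=0.0)


class TestMoleFractionsFromFree:
    def test_zero_lipid_gives_no_lipid_bound_species(self, simple_params):
        f_al, f_agl = mole_fractions_from_free(simple_params, 1e-6, 0.0)
        assert np.all(f_al[1:] == 0) and np.all(f_agl[1:] == 0)

    def test_zero_partner_gives_no_complex(self, simple_params):
        f_al, f_agl = mole_fractions_from_free(simple_params, 0.0, 1e-5)
        assert np.all(f_agl == 0)

    def test_equal_weights_give_quarter_fractions(self):
        # weights {A: 1, AL: K_AL*L = 1, AG: K_AG*G = 1, AGL: K_AL1G*G*K_AL*L = 1}
        params = BindingModelParams(k_ag=1e6, k_al=[1e5], k_alng=[1e6])
        f_al, f_agl = mole_fractions_from_free(params, 1e-6, 1e-5)
        np.testing.assert_allclose(np.concatenate([f_al, f_agl]), 0.25, rtol=1e-12)

    def test_extreme_constants_evaluate_in_log_space(self):
        params = BindingModelParams(
            k_ag=1e12, k_al=[1e12, 1e12, 1e12], k_alng=[1e12, 1e12, 1e12]
        )
        f_al, f_agl = mole_fractions_from_free(params, 1e-2, 1e-2)
        assert np.isfinite(f_al).all() and np.isfinite(f_agl).all()
        assert abs(f_al.sum() + f_agl.sum() - 1) < 1e-10


class TestFreeConcentrationsFromFractions:
    def test_two_state_arithmetic(self):
        totals = Totals(a_total=2e-6, g_total=2e-6, l_total=0.0)
        free_g, free_l = free_concentrations_from_fractions(totals, [0.5], [0.5])
        assert free_g == pytest.approx(1e-6, rel=1e-12)
        assert free_l == 0.0

    def test_no_complex_leaves_partner_free(self):
        totals = Totals(a_total=2e-6, g_total=3e-6, l_total=1e-5)
        free_g, _ = free_concentrations_from_fractions(totals, [0.6, 0.4], [0.0, 0.0])
        assert free_g == pytest.approx(3e-6, rel=1e-12)

    def test_lipid_accounting(self):
        totals = Totals(a_total=2e-6, g_total=2e-6, l_total=2e-5)
        _, free_l = free_concentrations_from_fractions(
            totals, [0.5, 0.25], [0.0, 0.25]
        )
        assert free_l == pytest.approx(1.9e-5, rel=1e-12)

    def test_incompatible_fractions_raise(self):
        totals = Totals(a_total=2e-6, g_total=0.5e-6, l_total=0.0)
        with pytest.raises(InconsistentFractionsError):
            free_concentrations_from_fractions(totals, [0.5], [0.5])


class TestDerivedAglConstants:
    def test_no_coupling_reduces_to_lipid_constants(self):
        params = BindingModelParams(k_ag=1e6, k_al=[1e5, 5e4], k_alng=[1e6, 1e6])
        np.testing.assert_allclose(derived_agl_constants(params), params.k_al)

    def test_hand_value(self):
        params = BindingModelParams(k_ag=1e6, k_al=[1e5], k_alng=[2e6])
        assert derived_agl_constants(params)[0] == pytest.approx(2e5, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e2, 1e9), min_size=5, max_size=5))
    def test_cycle_closure_identity(self, ks):
        params = BindingModelParams(k_ag=ks[0], k_al=ks[1:3], k_alng=ks[3:5])
        k_agl = derived_agl_constants(params)
        glnk = params.glnk_constants
        np.testing.assert_allclose(
            k_agl * glnk[:-1], params.k_al * glnk[1:], rtol=1e-12
        )


class TestComputeEquilibrium:
    def test_two_state_closed_form(self):
        params = BindingModelParams(k_ag=1e6, k_al=[], k_alng=[])
        totals = Totals(a_total=2e-6, g_total=2e-6, l_total=0.0)
        state = compute_equilibrium(params, totals)
        np.testing.assert_allclose(state.f_al, [0.5], rtol=1e-9)
        np.testing.assert_allclose(state.f_agl, [0.5], rtol=1e-9)
        assert state.free_g == pytest.approx(1e-6, rel=1e-9)

    def test_vanishing_affinity_leaves_apo(self, simple_params):
        params = BindingModelParams(
            k_ag=1e-8, k_al=simple_params.k_al, k_alng=simple_params.k_alng
        )
        totals = Totals(a_total=2e-6, g_total=2e-6, l_total=0.0)
        state = compute_equilibrium(params, totals)
        assert state.f_al[0] == pytest.approx(1.0, abs=1e-8)
        assert state.f_agl.sum() == pytest.approx(0.0, abs=1e-8)

    def test_matches_bisection_oracle(self, simple_params):
        totals = Totals(a_total=2e-6, g_total=2e-6, l_total=2e-5)
        state = compute_equilibrium(simple_params, totals)
        _, _, f_al, f_agl = oracle_equilibrium(
            simple_params.k_ag, simple_params.k_al, simple_params.k_alng,
            totals.a_total, totals.g_total, totals.l_total,
        )
        np.testing.assert_allclose(state.f_al, f_al, atol=1e-6)
        np.testing.assert_allclose(state.f_agl, f_agl, atol=1e-6)

    def test_zero_lipid_reduces_to_quadratic(self, rng):
        for _ in range(20):
            k_a = 10.0 ** rng.uniform(4, 8)
            a, g = 10.0 ** rng.uniform(-7, -5, size=2)
            params = BindingModelParams(k_ag=k_a, k_al=[1e5], k_alng=[1e6])
            state = compute_equilibrium(params, Totals(a, g, 0.0))
            f_a, f_ag, free_g = two_state_closed_form(k_a, a, g)
            assert state.f_al[0] == pytest.approx(f_a, abs=1e-10)
            assert state.f_agl[0] == pytest.approx(f_ag, abs=1e-10)
            assert state.free_g == pytest.approx(free_g, rel=1e-8, abs=1e-18)

    def test_normalization_and_conservation(self, rng):
        for _ in range(50):
            n_max = int(rng.integers(0, 3))
            params, totals = random_system(rng, n_max)
            state = compute_equilibrium(params, totals)
            assert abs(state.fraction_sum - 1.0) < 1e-10
            a, g, lipid = state.bound_totals(totals)
            assert a == pytest.approx(totals.a_total, rel=1e-8)
            assert g == pytest.approx(totals.g_total, rel=1e-8, abs=1e-18)
            assert lipid == pytest.approx(totals.l_total, rel=1e-8, abs=1e-18)

    def test_partner_affinity_monotonically_raises_complex_fraction(self, rng):
        totals = Totals(a_total=2e-6, g_total=2e-6, l_total=1e-5)
        k_al, k_alng = [1e5, 5e4], [2e6, 4e6]
        prev = -1.0
        for k_ag in 10.0 ** np.linspace(3, 8, 10):
            params = BindingModelParams(k_ag=k_ag, k_al=k_al, k_alng=k_alng)
            state = compute_equilibrium(params, totals)
            assert state.f_agl.sum() > prev
            prev = state.f_agl.sum()

    def test_measured_fractions_mode_round_trips(self, simple_params):
        totals = Totals(a_total=2e-6, g_total=2e-6, l_total=2e-5)
        truth = compute_equilibrium(simple_params, totals)
        state = compute_equilibrium(
            simple_params, totals, mode="measured_fractions",
            observed=(truth.f_al, truth.f_agl),
        )
        np.testing.assert_allclose(state.f_al, truth.f_al, atol=1e-9)
        np.testing.assert_allclose(state.f_agl, truth.f_agl, atol=1e-9)

    def test_measured_mode_requires_observed(self, simple_params):
        with pytest.raises(ValidationError):
            compute_equilibrium(
                simple_params, Totals(2e-6, 2e-6, 0.0), mode="measured_fractions"
            )

    def test_unknown_mode_rejected(self, simple_params):
        with pytest.raises(ValidationError):
            compute_equilibrium(simple_params, Totals(2e-6, 2e-6, 0.0), mode="exact")


class TestSequentialBinding:
    def test_zero_ligand_is_apo(self):
        spec = SequentialBindingSpec(1e-6, [1e-5, 2e-5], 0.0)
        np.testing.assert_allclose(sequential_binding_fractions(spec), [1, 0, 0])

    def test_saturation_limit(self):
        spec = SequentialBindingSpec(1e-6, [1e-5, 2e-5], 1.0)
        fr = sequential_binding_fractions(spec)
        assert fr[-1] == pytest.approx(1.0, abs=1e-4)

    def test_matches_bisection_oracle(self):
        p_total, kds, l_total = 1e-6, np.array([1e-5, 2e-5, 4e-5]), 1e-4

        def frac(lipid):
            w = np.concatenate([[1.0], np.cumprod(lipid / kds)])
            return w / w.sum()

        free_l = bisect(
            lambda x: x + p_total * (np.arange(4) @ frac(x)) - l_total, 0.0, l_total
        )
        spec = SequentialBindingSpec(p_total, kds, l_total)
        np.testing.assert_allclose(
            sequential_binding_fractions(spec), frac(free_l), atol=1e-8
        )

    def test_fractions_sum_to_one(self):
        spec = SequentialBindingSpec(2e-6, [5e-6, 1e-5, 5e-5], 3e-5)
        assert sequential_binding_fractions(spec).sum() == pytest.approx(1.0, abs=1e-12)
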