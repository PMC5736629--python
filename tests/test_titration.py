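"""Species-table processing, pseudo chi-square, and the global binding fit."""

import numpy as np
import pandas as pd
import pytest

from lipallo.equilibrium import BindingModelParams, Totals, ValidationError, compute_equilibrium
from lipallo.synthetic import NoiseSpec, default_study_params, generate_titration
from lipallo.titration import (
    CoupledBindingFitter,
    IdentifiabilityError,
    SpeciesAbundanceTable,
    TitrationPoint,
    TitrationSeries,
    aggregate_replicates,
    chi_square,
    fit_binding_model,
    fold_adducts,
    kd_ag_from_point,
    table_to_point,
)

TOTALS0 = Totals(a_total=2e-6, g_total=2e-6, l_total=0.0)


def make_table(rows, totals=TOTALS0):
    df = pd.DataFrame(
        rows,
        columns=["n_glnk", "n_lipid", "n_adp_specific", "n_adp_nonspecific", "intensity"],
    )
    return SpeciesAbundanceTable(data=df, totals=totals)


class TestFoldAdducts:
    def test_satellite_added_to_parent(self):
        table = make_table([(1, 0, 3, 0, 100.0), (1, 0, 3, 1, 10.0)])
        folded = fold_adducts(table)
        assert folded.data["intensity"].tolist() == [110.0]
        assert folded.is_folded()

    def test_no_satellites_is_identity(self):
        table = make_table([(0, 0, 0, 0, 50.0), (1, 0, 3, 0, 70.0)])
        folded = fold_adducts(table)
        pd.testing.assert_frame_equal(
            folded.data.reset_index(drop=True), table.data.reset_index(drop=True),
            check_dtype=False,
        )

    def test_satellite_without_parent_creates_parent(self):
        table = make_table([(0, 1, 0, 1, 5.0), (0, 0, 0, 0, 95.0)])
        folded = fold_adducts(table)
        assert folded.total_intensity == pytest.approx(100.0)

    def test_total_intensity_conserved(self, rng):
        rows = [
            (int(g), int(n), 0, int(a), float(i))
            for g, n, a, i in zip(
                rng.integers(0, 2, 20), rng.integers(0, 4, 20),
                rng.integers(0, 2, 20), rng.uniform(0, 100, 20),
            )
        ]
        table = make_table(rows)
        assert fold_adducts(table).total_intensity == pytest.approx(
            table.total_intensity
        )

    def test_double_adducts_dropped_with_warning(self):
        table = make_table([(0, 0, 0, 0, 90.0), (0, 0, 0, 2, 10.0)])
        with pytest.warns(UserWarning, match="non-specific"):
            folded = fold_adducts(table)
        assert folded.total_intensity == pytest.approx(90.0)


class TestTableToPoint:
    def test_equal_intensities_split_evenly(self):
        table = make_table([(0, 0, 0, 0, 1.0), (1, 0, 3, 0, 1.0)])
        point = table_to_point(table)
        np.testing.assert_allclose(point.f_al, [0.5])
        np.testing.assert_allclose(point.f_agl, [0.5])

    def test_arithmetic_with_lipid_classes(self):
        table = make_table(
            [(0, 0, 0, 0, 2.0), (0, 1, 0, 0, 1.0), (1, 0, 3, 0, 1.0)],
            totals=Totals(2e-6, 2e-6, 1e-5),
        )
        point = table_to_point(table)
        np.testing.assert_allclose(point.f_al, [0.5, 0.25])
        np.testing.assert_allclose(point.f_agl, [0.25, 0.0])

    def test_scale_invariance(self):
        rows = [(0, 0, 0, 0, 2.0), (0, 1, 0, 0, 1.0), (1, 1, 3, 0, 3.0)]
        t1 = table_to_point(make_table(rows, Totals(2e-6, 2e-6, 1e-5)))
        rows_scaled = [(g, n, s, a, i * 7.3) for g, n, s, a, i in rows]
        t2 = table_to_point(make_table(rows_scaled, Totals(2e-6, 2e-6, 1e-5)))
        np.testing.assert_allclose(t1.f_al, t2.f_al)
        np.testing.assert_allclose(t1.f_agl, t2.f_agl)

    def test_all_zero_intensities_rejected(self):
        table = make_table([(0, 0, 0, 0, 0.0), (1, 0, 3, 0, 0.0)])
        with pytest.raises(ValidationError, match="zero"):
            table_to_point(table)

    def test_unfolded_table_rejected(self):
        table = make_table([(0, 0, 0, 0, 1.0), (0, 0, 0, 1, 0.1)])
        with pytest.raises(ValidationError, match="fold"):
            table_to_point(table)


class TestChiSquare:
    def test_noiseless_self_consistency(self, simple_params):
        grid = [Totals(2e-6, 2e-6, lt) for lt in (0.0, 5e-6, 2e-5, 8e-5)]
        points = []
        for t in grid:
            st = compute_equilibrium(simple_params, t)
            points.append(TitrationPoint(totals=t, f_al=st.f_al, f_agl=st.f_agl))
        series = TitrationSeries(lipid="x", points=points)
        assert chi_square(series, simple_params, "measured_fractions") < 1e-12
        assert chi_square(series, simple_params, "self_consistent") < 1e-12

    def test_known_discrepancy(self):
        # exact fractions at one condition, perturbed by moving 0.05 of mass
        # between two classes: chi2 = 2 * 0.05^2 under the self-consistent mode
        params = BindingModelParams(k_ag=1e6, k_al=[], k_alng=[])
        totals = Totals(2e-6, 2e-6, 0.0)
        st = compute_equilibrium(params, totals)
        f_al = st.f_al + 0.05
        f_agl = st.f_agl - 0.05
        pts = [
            TitrationPoint(totals=totals, f_al=f_al, f_agl=f_agl),
            TitrationPoint(
                totals=Totals(2e-6, 2e-6, 1e-9), f_al=st.f_al, f_agl=st.f_agl
            ),
        ]
        series = TitrationSeries(lipid="x", points=pts)
        assert chi_square(series, params, "self_consistent") == pytest.approx(
            2 * 0.05**2, rel=1e-6
        )

    def test_nonnegative(self, simple_params, rng):
        pts = []
        for lt in (0.0, 1e-5):
            f = rng.dirichlet(np.ones(6))
            pts.append(
                TitrationPoint(
                    totals=Totals(2e-6, 2e-6, lt), f_al=f[:3], f_agl=f[3:]
                )
            )
        assert chi_square(TitrationSeries("x", pts), simple_params, "self_consistent") >= 0


class TestFit:
    def test_noiseless_recovery_small(self):
        truth = BindingModelParams(k_ag=8.9e5, k_al=[1.5e5], k_alng=[1.8e6])
        bundle = generate_titration(
            truth,
            noise=NoiseSpec(sigma=0.0, adduct_fraction=0.0, seed=1),
            replicates=1,
        )
        fit = fit_binding_model(bundle.series, n_max=1, seed=3, n_starts=8)
        assert np.max(np.abs(fit.log10_mean - truth.log10())) < 1e-4
        assert fit.chi2 < 1e-10

    def test_modes_agree_at_optimum_on_noiseless_data(self):
        truth = BindingModelParams(k_ag=8.9e5, k_al=[1.5e5], k_alng=[1.8e6])
        bundle = generate_titration(
            truth, noise=NoiseSpec(sigma=0.0, adduct_fraction=0.0, seed=1),
            replicates=1,
        )
        fit = fit_binding_model(bundle.series, n_max=1, seed=3, n_starts=8)
        assert chi_square(bundle.series, fit.params_hat, "measured_fractions") < 1e-10
        assert chi_square(bundle.series, fit.params_hat, "self_consistent") < 1e-10

    def test_chi2_at_truth_not_beaten_by_perturbations(self, rng):
        truth = BindingModelParams(k_ag=8.9e5, k_al=[1.5e5], k_alng=[1.8e6])
        bundle = generate_titration(
            truth, noise=NoiseSpec(sigma=0.0, adduct_fraction=0.0, seed=1),
            replicates=1,
        )
        base = chi_square(bundle.series, truth, "measured_fractions")
        x0 = truth.log10()
        for _ in range(20):
            x = x0 + rng.uniform(-0.3, 0.3, size=x0.size)
            perturbed = BindingModelParams.from_log10(x, 1)
            assert chi_square(bundle.series, perturbed, "measured_fractions") >= base

    def test_lipid_constants_unidentifiable_without_lipid(self):
        params = BindingModelParams(k_ag=1e6, k_al=[], k_alng=[])
        st = compute_equilibrium(params, Totals(2e-6, 2e-6, 0.0))
        pts = [
            TitrationPoint(
                totals=Totals(2e-6, 2e-6, lt),
                f_al=np.concatenate([st.f_al, [0.0]]),
                f_agl=np.concatenate([st.f_agl, [0.0]]),
            )
            for lt in (0.0, 1e-9)
        ]
        series = TitrationSeries("x", pts)
        with pytest.raises(IdentifiabilityError, match="K_A,AL1"):
            fit_binding_model(series, n_max=1, seed=1)

    def test_estimator_follows_sklearn_conventions(self):
        est = CoupledBindingFitter(n_max=1, seed=9)
        assert est.get_params()["n_max"] == 1
        est.set_params(n_starts=4)
        truth = BindingModelParams(k_ag=8.9e5, k_al=[1.5e5], k_alng=[1.8e6])
        bundle = generate_titration(
            truth, noise=NoiseSpec(sigma=0.0, adduct_fraction=0.0, seed=1),
            replicates=1,
        )
        fitted = est.fit(bundle.series)
        assert fitted is est
        assert hasattr(est, "params_") and hasattr(est, "chi2_")
        states = est.predict([Totals(2e-6, 2e-6, 1e-5)])
        assert abs(states[0].fraction_sum - 1) < 1e-10


class TestKdAg:
    def test_equal_split_gives_micromolar_kd(self):
        point = TitrationPoint(totals=TOTALS0, f_al=[0.5], f_agl=[0.5])
        assert kd_ag_from_point(point) == pytest.approx(1e-6, rel=1e-12)

    def test_saturated_complex_is_an_error(self):
        point = TitrationPoint(totals=TOTALS0, f_al=[0.0], f_agl=[1.0])
        with pytest.raises(ValidationError, match="free G"):
            kd_ag_from_point(point)

    def test_lipid_bound_point_rejected(self):
        point = TitrationPoint(
            totals=Totals(2e-6, 2e-6, 1e-5), f_al=[0.4, 0.2], f_agl=[0.4, 0.0]
        )
        with pytest.raises(ValidationError, match="lipid-free"):
            kd_ag_from_point(point)

    def test_invariant_to_intensity_scaling(self):
        rows = [(0, 0, 0, 0, 30.0), (1, 0, 3, 0, 70.0)]
        k1 = kd_ag_from_point(table_to_point(make_table(rows)))
        rows2 = [(g, n, s, a, i * 11.0) for g, n, s, a, i in rows]
        k2 = kd_ag_from_point(table_to_point(make_table(rows2)))
        assert k1 == pytest.approx(k2, rel=1e-12)


class TestAggregateReplicates:
    def test_mean_and_sem(self):
        mean, sem = aggregate_replicates([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(0.5774, abs=1e-4)

    def test_identical_values_have_zero_sem(self):
        assert aggregate_replicates([4.2, 4.2, 4.2])[1] == 0.0

    def test_single_value_flagged(self):
        mean, sem = aggregate_replicates([7.0])
        assert mean == 7.0 and np.isnan(sem)
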