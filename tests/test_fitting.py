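"""Objective, Latin hypercube starts, multistart fits and inhibitor extents."""

import numpy as np
import pandas as pd
import pytest

import mtorstress as m
from mtorstress.data import NoiseModel, TimeCourseDataset
from mtorstress.fitting import FitProblem, extent_of_inhibition, fit_multistart, lhs_starts
from mtorstress.simulate import DEFAULT_TIMES, standard_conditions


@pytest.fixture(scope="module")
def noisefree_problem(model_V, truth_V, noisefree_study_V, all_conditions):
    return FitProblem(
        model_V,
        noisefree_study_V,
        all_conditions,
        free=["k_stress_PI3K", "k_stress_Akt_pS473", "k_stress_mTORC1"],
        fixed_values=truth_V,
    )


class TestChi2Objective:
    def test_zero_at_generating_parameters(self, noisefree_problem):
        """Generator and objective are mutually consistent."""
        assert noisefree_problem.chi2(noisefree_problem.default_x0()) < 1e-6

    def test_single_point_deviation_scores_squared_residual(
        self, model_V, truth_V, noisefree_study_V, all_conditions
    ):
        df = noisefree_study_V[0].frame.copy()
        i = df.index[(df["readout"] == "Akt_pS473") & (df["time_min"] == 60.0)][0]
        df.loc[i, "mean"] += 0.5
        df.loc[i, "sem"] = 0.5
        problem = FitProblem(
            model_V, [TimeCourseDataset(df)], all_conditions,
            free=["k_stress_PI3K"], fixed_values=truth_V,
        )
        # ((sim - mean)/sigma)^2 = (0.5/0.5)^2 = 1
        assert problem.chi2(problem.default_x0()) == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_record_order(
        self, model_V, truth_V, noisy_study_III, all_conditions
    ):
        ds = noisy_study_III[0]
        shuffled = TimeCourseDataset(
            ds.frame.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        kw = dict(free=["k_stress_PI3K"], fixed_values=truth_V)
        p1 = FitProblem(model_V, [ds], all_conditions, **kw)
        p2 = FitProblem(model_V, [shuffled], all_conditions, **kw)
        x = p1.default_x0()
        assert p1.chi2(x) == pytest.approx(p2.chi2(x), rel=1e-12)

    def test_sigma_floor_guards_zero_sem(self, noisefree_problem):
        # noise-free data carry sem = 0 everywhere; the objective is finite
        assert np.isfinite(noisefree_problem.chi2(noisefree_problem.default_x0()))

    def test_out_of_bounds_rejected(self, noisefree_problem):
        x = noisefree_problem.default_x0()
        with pytest.raises(ValueError, match="bounds"):
            m.chi2_objective(noisefree_problem, x + 100.0)


class TestLHS:
    def test_stratification_one_draw_per_bin(self):
        lo, hi = np.array([-5.0]), np.array([3.0])
        x = lhs_starts((lo, hi), 4, seed=0)
        bins = np.floor((x[:, 0] - (-5.0)) / 2.0).astype(int)
        assert sorted(bins) == [0, 1, 2, 3]

    def test_same_seed_identical(self):
        lo = np.array([-5.0, -5.0, -2.0])
        hi = np.array([3.0, 1.0, -2.0])
        a = lhs_starts((lo, hi), 10, seed=42)
        b = lhs_starts((lo, hi), 10, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_bounds_held_constant(self):
        lo = np.array([-5.0, -1.0])
        hi = np.array([3.0, -1.0])
        x = lhs_starts((lo, hi), 8, seed=1)
        assert (x[:, 1] == -1.0).all()
        assert x.shape == (8, 2)

    def test_full_space_shape(self, model_V, noisefree_study_V, all_conditions):
        problem = FitProblem(model_V, noisefree_study_V, all_conditions)
        x = lhs_starts(problem.bounds, 500, seed=0)
        assert x.shape == (500, 91)


class TestMultistart:
    def test_start_at_truth_converges_immediately(self, noisefree_problem):
        res = fit_multistart(
            noisefree_problem, 1, seed=0,
            x0_extra=[noisefree_problem.default_x0()],
        )
        assert res[0].chi2 < 1e-6
        assert res[0].converged

    def test_all_starts_retained_and_sorted(self, noisefree_problem):
        res = fit_multistart(noisefree_problem, 4, seed=2, max_nfev=10)
        assert len(res) == 4
        chis = [r.chi2 for r in res]
        assert chis == sorted(chis)
        assert {r.start_index for r in res} == {0, 1, 2, 3}

    def test_noise_free_recovery_within_ten_percent(
        self, model_V, truth_V, noisefree_study_V, all_conditions
    ):
        """Best of a seeded multistart recovers the generating stress-input
        strengths and a kinetic parameter to within 10% relative error."""
        problem = FitProblem(
            model_V, noisefree_study_V, all_conditions,
            free=["k_stress_PI3K", "k_stress_Akt_pS473", "k_stress_mTORC1",
                  "k_TSC2_T1462"],
            fixed_values=truth_V,
        )
        res = fit_multistart(problem, 10, seed=4)
        best = res[0]
        assert best.converged
        for name, v in zip(best.free_names, 10.0**best.log10_params):
            assert abs(v - truth_V[name]) / truth_V[name] < 0.10, name

    def test_nested_model_never_fits_worse(
        self, truth_III, noisy_study_III, all_conditions
    ):
        """Adding a free stress input cannot increase the best chi2."""
        m2, m3 = m.build_model("II"), m.build_model("III")
        kw = dict(fixed_values=truth_III, conditions=all_conditions)
        p2 = FitProblem(m2, noisy_study_III, free=["k_stress_PI3K"], **kw)
        p3 = FitProblem(
            m3, noisy_study_III, free=["k_stress_PI3K", "k_stress_Akt_pS473"], **kw
        )
        b2 = fit_multistart(p2, 3, seed=6)[0].chi2
        b3 = fit_multistart(p3, 3, seed=6, x0_extra=[p3.default_x0()])[0].chi2
        assert b3 <= b2 + 1e-3

    def test_chi2_increases_with_noise(self, model_III, truth_III, all_conditions):
        """Median best-fit chi2 grows with the generating noise level."""
        labels = ("arsenite", "arsenite_wortmannin")
        medians = []
        for cv in (0.0, 0.1, 0.2):
            chis = []
            for seed in range(5):
                datasets = [
                    m.generate_dataset(
                        model_III, truth_III, all_conditions[lab],
                        DEFAULT_TIMES, 4, NoiseModel(cv=cv, seed=100 + seed),
                    )
                    for lab in labels
                ]
                problem = FitProblem(
                    model_III, datasets, all_conditions,
                    free=["k_stress_PI3K", "k_stress_Akt_pS473"],
                    fixed_values=truth_III,
                )
                chis.append(
                    fit_multistart(
                        problem, 2, seed=seed,
                        x0_extra=[problem.default_x0()], max_nfev=25,
                    )[0].chi2
                )
            medians.append(np.median(chis))
        assert medians[0] < medians[1] < medians[2]

    def test_seeded_bitwise_reproducibility(self, noisefree_problem):
        a = fit_multistart(noisefree_problem, 3, seed=9, max_nfev=15)
        b = fit_multistart(noisefree_problem, 3, seed=9, max_nfev=15)
        for ra, rb in zip(a, b):
            assert ra.chi2 == rb.chi2
            np.testing.assert_array_equal(ra.log10_params, rb.log10_params)


def _slope_dataset(slope, *, label, sem=0.01, n_reps=4, noise_seed=None):
    times = np.array([0.0, 15.0, 30.0, 45.0, 60.0])
    means = 1.0 + slope * times
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        means = means + rng.normal(0, 1e-3, size=len(times))
    return TimeCourseDataset(
        pd.DataFrame(
            {
                "condition": label,
                "readout": "TSC2_pT1462",
                "time_min": times,
                "mean": means,
                "sem": sem,
                "n_reps": n_reps,
            }
        )
    )


class TestExtentOfInhibition:
    def test_slope_ratio_gives_mk2206_extent(self):
        """A treated induction slope at 17% of control yields 83% inhibition."""
        control = _slope_dataset(0.02, label="carrier")
        treated = _slope_dataset(0.02 * 0.17, label="mk2206")
        extent = extent_of_inhibition(control, treated, "TSC2_pT1462")
        assert extent == pytest.approx(0.83, abs=1e-9)

    def test_identical_datasets_give_zero(self):
        control = _slope_dataset(0.02, label="c")
        treated = _slope_dataset(0.02, label="t")
        assert extent_of_inhibition(control, treated, "TSC2_pT1462") == pytest.approx(0.0)

    def test_flat_treated_course_triggers_full_inhibition_rule(self):
        """No significant change across time points -> extent 1.0."""
        control = _slope_dataset(0.02, label="c")
        treated = _slope_dataset(0.0, label="w", sem=0.3, noise_seed=1)
        assert extent_of_inhibition(control, treated, "TSC2_pT1462") == 1.0

    def test_non_positive_control_slope_rejected(self):
        control = _slope_dataset(-0.01, label="c")
        treated = _slope_dataset(0.0, label="t")
        with pytest.raises(ValueError, match="non-positive"):
            extent_of_inhibition(control, treated, "TSC2_pT1462")

    def test_clipped_to_unit_interval(self):
        control = _slope_dataset(0.02, label="c")
        treated = _slope_dataset(-0.01, label="t")
        assert extent_of_inhibition(control, treated, "TSC2_pT1462") == 1.0
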