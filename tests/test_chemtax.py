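"""Pigment unmixing: exact solves, randomisation, and matrix optimisation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from plumetroph import (
    chemtax_run,
    fit_composition,
    final_ratio_matrix,
    initial_ratio_matrix,
    optimize_ratio_matrix,
    perturb_ratio_matrix,
)
from plumetroph.chemtax import CLASSES, PIGMENTS


def _mix(F, weights, scale=1.0):
    """Noise-free pigment sample from class weights (chl-a contributions)."""
    vec = scale * sum(w * F.loc[c].to_numpy(float) for c, w in weights.items())
    return pd.DataFrame([vec], columns=list(F.columns), index=["m0"])


class TestRatioMatrices:
    def test_chl_a_column_is_unity(self, ratio_initial, ratio_final):
        for F in (ratio_initial, ratio_final):
            np.testing.assert_array_equal(F["Chl a"].to_numpy(), np.ones(8))

    def test_structural_zeros_shared_between_initial_and_final(
        self, ratio_initial, ratio_final
    ):
        np.testing.assert_array_equal(
            ratio_initial.to_numpy() == 0, ratio_final.to_numpy() == 0
        )

    def test_diagnostic_markers(self, ratio_final):
        # peridinin is exclusive to dinoflagellates; alloxanthin to cryptophytes
        perid = ratio_final["Perid"]
        assert perid["Dinoflagellates1"] > 0 and (perid.drop("Dinoflagellates1") == 0).all()
        allo = ratio_final["Allo"]
        assert allo["Cryptophytes"] > 0 and (allo.drop("Cryptophytes") == 0).all()


class TestFitComposition:
    def test_single_class_exact(self, ratio_final):
        S = _mix(ratio_final, {"Diatoms1": 0.5})
        comp, obj = fit_composition(S, ratio_final)
        assert comp["Diatoms1"].iloc[0] == pytest.approx(0.5, abs=1e-9)
        assert comp["Diatoms1_pct"].iloc[0] == pytest.approx(100.0, abs=1e-6)
        assert obj == pytest.approx(0.0, abs=1e-9)

    def test_two_class_mixture_recovered_exactly(self, ratio_final):
        S = _mix(ratio_final, {"Haptophytes6": 0.3, "Cyanobacteria2": 0.7})
        comp, _ = fit_composition(S, ratio_final)
        assert comp["Haptophytes6_pct"].iloc[0] == pytest.approx(30.0, abs=1e-6)
        assert comp["Cyanobacteria2_pct"].iloc[0] == pytest.approx(70.0, abs=1e-6)

    def test_matches_grid_search_oracle(self, ratio_final):
        """2-class NNLS agrees with an exhaustive coarse grid search."""
        F2 = ratio_final.loc[["Diatoms1", "Cryptophytes"]]
        S = _mix(ratio_final, {"Diatoms1": 0.4, "Cryptophytes": 0.6})
        comp, _ = fit_composition(S, F2, weighting="none")
        grid = np.arange(0.0, 1.2001, 0.01)
        A = F2.to_numpy(float)
        s = S.to_numpy(float)[0]
        best = min(
            ((a, b) for a, b in itertools.product(grid, grid)),
            key=lambda ab: float(np.sum((ab[0] * A[0] + ab[1] * A[1] - s) ** 2)),
        )
        assert comp["Diatoms1"].iloc[0] == pytest.approx(best[0], abs=0.01)
        assert comp["Cryptophytes"].iloc[0] == pytest.approx(best[1], abs=0.01)

    def test_unmatched_pigment_adds_residual_not_bias(self, ratio_final):
        """A pigment no class carries raises the objective but not the coefficients."""
        F = ratio_final.copy()
        F.insert(0, "Unknown", 0.0)
        S = _mix(ratio_final, {"Diatoms1": 0.5})
        S.insert(0, "Unknown", 0.2)
        comp_with, obj_with = fit_composition(S, F, weighting="none")
        comp_wo, obj_wo = fit_composition(
            S.drop(columns="Unknown"), ratio_final, weighting="none"
        )
        assert obj_with > obj_wo
        np.testing.assert_allclose(
            comp_with[list(CLASSES)].to_numpy(), comp_wo[list(CLASSES)].to_numpy(), atol=1e-9
        )

    def test_percent_shares_sum_to_100(self, scenario, ratio_final):
        from plumetroph import gen_pigment_samples

        S, _ = gen_pigment_samples(scenario, n_samples=12)
        comp, _ = fit_composition(S, ratio_final)
        pct = comp[[f"{c}_pct" for c in CLASSES]].sum(axis=1)
        np.testing.assert_allclose(pct.to_numpy(), 100.0, atol=1e-6)
        assert (comp[list(CLASSES)].to_numpy() >= 0).all()

    def test_all_zero_sample_warns_and_yields_zero(self, ratio_final):
        S = pd.DataFrame([np.zeros(len(PIGMENTS))], columns=list(PIGMENTS), index=["z"])
        with pytest.warns(UserWarning, match="all pigments zero"):
            comp, _ = fit_composition(S, ratio_final)
        assert comp["total_chla"].iloc[0] == 0.0

    def test_dimension_mismatch_rejected(self, ratio_final):
        S = pd.DataFrame([[0.1]], columns=["Fuco"])
        with pytest.raises(ValueError, match="lacks columns"):
            fit_composition(S, ratio_final)


class TestPerturbation:
    def test_magnitude_zero_is_identity(self, ratio_initial):
        F = perturb_ratio_matrix(ratio_initial, 0.0, seed=3)
        pd.testing.assert_frame_equal(F, ratio_initial)

    def test_same_seed_same_matrix(self, ratio_initial):
        a = perturb_ratio_matrix(ratio_initial, 0.35, seed=42)
        b = perturb_ratio_matrix(ratio_initial, 0.35, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_structure_preserved(self, ratio_initial):
        F = perturb_ratio_matrix(ratio_initial, 0.35, seed=0)
        np.testing.assert_array_equal(F.to_numpy() == 0, ratio_initial.to_numpy() == 0)
        np.testing.assert_array_equal(F["Chl a"].to_numpy(), np.ones(8))

    def test_perturbation_is_mean_preserving(self, ratio_initial):
        draws = [
            perturb_ratio_matrix(ratio_initial, 0.35, seed=s).loc["Diatoms1", "Fuco"]
            for s in range(10_000)
        ]
        assert np.mean(draws) == pytest.approx(0.711, rel=0.01)

    def test_magnitude_bounds(self, ratio_initial):
        with pytest.raises(ValueError):
            perturb_ratio_matrix(ratio_initial, 1.0)


class TestOptimization:
    def test_noise_free_data_leave_matrix_unchanged(self, ratio_final):
        S = _mix(ratio_final, {"Diatoms1": 0.4, "Haptophytes6": 0.6})
        F, trace = optimize_ratio_matrix(S, ratio_final, max_iter=3)
        assert trace[0] == pytest.approx(0.0, abs=1e-9)
        pd.testing.assert_frame_equal(F, ratio_final)

    def test_planted_ratio_is_recovered(self, ratio_final):
        truth = ratio_final.copy()
        truth.loc["Diatoms1", "Fuco"] *= 1.2
        S = _mix(truth, {"Diatoms1": 0.5, "Cryptophytes": 0.5})
        F, trace = optimize_ratio_matrix(S, ratio_final, max_iter=20)
        start = ratio_final.loc["Diatoms1", "Fuco"]
        assert F.loc["Diatoms1", "Fuco"] > start
        assert trace[-1] < trace[0]

    def test_max_iter_zero_returns_initial(self, ratio_final):
        S = _mix(ratio_final, {"Diatoms1": 0.5})
        F, trace = optimize_ratio_matrix(S, ratio_final, max_iter=0)
        pd.testing.assert_frame_equal(F, ratio_final)
        assert len(trace) == 1

    def test_objective_trace_non_increasing(self, scenario, ratio_final):
        from plumetroph import gen_pigment_samples

        S, _ = gen_pigment_samples(scenario, n_samples=8)
        F0 = perturb_ratio_matrix(ratio_final, 0.2, seed=5)
        _, trace = optimize_ratio_matrix(S, F0, max_iter=5)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))


class TestChemtaxRun:
    def test_degenerate_configuration_equals_plain_fit(self, ratio_final):
        S = _mix(ratio_final, {"Diatoms1": 0.3, "Cryptophytes": 0.7})
        comp_run, _, _ = chemtax_run(
            S, ratio_final, n_random=1, n_runs=1, n_best=1, magnitude=0.0, max_iter=0
        )
        comp_fit, _ = fit_composition(S, ratio_final)
        pd.testing.assert_frame_equal(comp_run, comp_fit)

    def test_best_objective_non_increasing_across_runs(self, scenario, ratio_final):
        from plumetroph import gen_pigment_samples

        S, _ = gen_pigment_samples(scenario, n_samples=6)
        _, _, diags = chemtax_run(
            S, ratio_final, n_random=4, n_runs=3, n_best=2, max_iter=2, seed=9
        )
        objs = diags.best_objectives
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_zero_magnitude_invariant_under_seed(self, ratio_final):
        S = _mix(ratio_final, {"Diatoms1": 0.5, "Haptophytes6": 0.5})
        a, _, _ = chemtax_run(S, ratio_final, n_random=2, n_runs=1, n_best=1,
                              magnitude=0.0, max_iter=1, seed=1)
        b, _, _ = chemtax_run(S, ratio_final, n_random=2, n_runs=1, n_best=1,
                              magnitude=0.0, max_iter=1, seed=999)
        pd.testing.assert_frame_equal(a, b)

    def test_n_best_bounded_by_n_random(self, ratio_final):
        S = _mix(ratio_final, {"Diatoms1": 0.5})
        with pytest.raises(ValueError):
            chemtax_run(S, ratio_final, n_random=2, n_best=3)
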