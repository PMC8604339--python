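"""Weighted chi-square objective, multistart fitting, profile likelihood."""

import numpy as np
import pytest

from mrafit import (
    Condition,
    FitSettings,
    MRAModel,
    MRAParameters,
    PerturbationDataset,
    fit_model,
    load_network,
    prepare_design,
    profile_likelihood,
    simulate_design,
    weighted_chi2,
)
from mrafit.synthetic import (
    full_factorial_design,
    generate_perturbation_dataset,
    make_virtual_cell_line,
    panel_profiles,
)
from conftest import noise_free_dataset


class TestWeightedChi2:
    def test_perfect_fit_is_zero(self, chain_model):
        model, design = chain_model
        sim = simulate_design(model, design)
        data = noise_free_dataset(model, design)
        assert weighted_chi2(sim, data) == 0.0

    def test_single_two_sigma_deviation_scores_four(self, chain_model):
        model, design = chain_model
        sim = simulate_design(model, design)
        data = noise_free_dataset(model, design, sd=0.1)
        values = data.values.copy()
        values[1, 1] += 0.2  # 2 sigma
        data2 = PerturbationDataset(values=values, sd=data.sd, n_reps=2,
                                    labels=data.labels, readouts=data.readouts)
        assert weighted_chi2(sim, data2) == pytest.approx(4.0)

    def test_shape_mismatch_reports_both_shapes(self, chain_model, mapk_cycle):
        model, design = chain_model
        sim = simulate_design(model, design)
        other_design = prepare_design([Condition()], ("MEK",),
                                      mapk_cycle.network)
        other = noise_free_dataset(mapk_cycle, other_design)
        with pytest.raises(ValueError, match=r"\(4, 4\).*\(1, 1\)"):
            weighted_chi2(sim, other)

    def test_expected_mean_equals_data_point_count(self):
        """Mean chi2 of the generative model over simulated datasets equals
        the unmasked cell count (chi-square distribution mean)."""
        truth = make_virtual_cell_line(panel_profiles()["VC1"])
        design = full_factorial_design(truth.network)
        sim = simulate_design(truth, design)
        chis = [
            weighted_chi2(sim, generate_perturbation_dataset(
                truth, design, noise_sd=0.2, n_reps=2, seed=seed,
                sd_mode="known"))
            for seed in range(40)
        ]
        se = np.std(chis, ddof=1) / np.sqrt(len(chis))
        assert np.mean(chis) == pytest.approx(design.n_unmasked, abs=3 * se)


class TestFitModel:
    def test_noise_free_recovery_is_exact(self, chain_model):
        model, design = chain_model
        data = noise_free_dataset(model, design)
        fit = fit_model(model.network, data, design,
                        FitSettings(n_starts=20, seed=0))
        assert fit.chi2 < 1e-6
        for key, truth in model.params.r.items():
            assert fit.model.params.r[key] == pytest.approx(truth, rel=1e-3)
        assert fit.model.params.stim[("A", "L")] == pytest.approx(1.5, rel=1e-3)
        assert fit.model.params.inhib["Bi"] == pytest.approx(-0.8, rel=1e-3)

    def test_determinism_with_fixed_seed(self, chain_model):
        model, design = chain_model
        data = generate_perturbation_dataset(model, design, 0.2, 2, seed=5)
        settings = FitSettings(n_starts=3, seed=11)
        f1 = fit_model(model.network, data, design, settings)
        f2 = fit_model(model.network, data, design, settings)
        assert f1.chi2 == f2.chi2
        assert f1.model.params.r == f2.model.params.r
        assert f1.start_chi2s == f2.start_chi2s

    def test_chi2_near_dof_for_correct_identifiable_model(self, chain_model):
        """Least-squares expectation: E[chi2] ~ n_data - n_free when every
        parameter is identifiable and weights match the noise."""
        model, design = chain_model
        chis = []
        for seed in range(8):
            data = generate_perturbation_dataset(
                model, design, noise_sd=0.2, n_reps=2, seed=seed,
                sd_mode="known")
            fit = fit_model(model.network, data, design,
                            FitSettings(n_starts=8, seed=seed))
            chis.append(fit.chi2)
        dof = 16 - 5
        # mean of chi2_dof is dof, sd sqrt(2*dof); allow 3 SE over 8 draws
        se = np.sqrt(2 * dof / 8)
        assert np.mean(chis) == pytest.approx(dof, abs=3 * se)

    def test_best_chi2_is_minimum_over_starts(self, chain_model):
        model, design = chain_model
        data = generate_perturbation_dataset(model, design, 0.2, 2, seed=3)
        fit = fit_model(model.network, data, design,
                        FitSettings(n_starts=5, seed=2))
        assert fit.chi2 == pytest.approx(min(fit.start_chi2s))

    def test_refit_from_own_optimum_reproduces_chi2(self, chain_model):
        model, design = chain_model
        data = generate_perturbation_dataset(model, design, 0.2, 2, seed=9)
        fit = fit_model(model.network, data, design,
                        FitSettings(n_starts=6, seed=1))
        refit = fit_model(model.network, data, design,
                          FitSettings(n_starts=1, seed=1),
                          warm_starts=[fit.model.params])
        assert refit.chi2 == pytest.approx(fit.chi2, abs=1e-6)

    def test_fixed_params_held_and_excluded_from_free_count(self, chain_model):
        model, design = chain_model
        data = noise_free_dataset(model, design)
        fit = fit_model(model.network, data, design,
                        FitSettings(n_starts=5, seed=0,
                                    fixed_params={"i:Bi": -0.8}))
        assert fit.model.params.inhib["Bi"] == -0.8
        assert fit.n_free == 4

    def test_residual_normality_of_true_model(self):
        """Weighted residuals of the generative model are ~ N(0, 1) on the
        240-cell design (|mean| < 0.2, |sd - 1| < 0.2 per seed)."""
        truth = make_virtual_cell_line(panel_profiles()["VC5"])
        design = full_factorial_design(truth.network)
        sim = simulate_design(truth, design)
        for seed in range(5):
            data = generate_perturbation_dataset(
                truth, design, 0.2, 2, seed=seed, sd_mode="known")
            res = (data.values - sim.values) / data.sd
            res = res[np.isfinite(res)]
            assert abs(res.mean()) < 0.2
            assert abs(res.std(ddof=1) - 1) < 0.2

    def test_identifiable_path_product_recovery_under_noise(self):
        """Median relative error of ligand->readout path products < 10%
        across seeded noisy datasets (individual coefficients may sit on
        non-identifiable ridges; the products are the estimands)."""
        net = load_network(
            [("R", "K1"), ("K1", "K2")],
            {"R": "receptor", "K1": "kinase", "K2": "kinase"},
            ligand_map={"L": ("R",)}, inhibitor_map={"K1i": "K1"})
        params = MRAParameters(
            r={("K1", "R"): 0.8, ("K2", "K1"): 1.1},
            stim={("R", "L"): 1.4}, inhib={"K1i": -1.0})
        truth = MRAModel(net, params)
        conditions = [
            Condition(), Condition(stimuli=frozenset({"L"})),
            Condition(inhibitors=frozenset({"K1i"})),
            Condition(stimuli=frozenset({"L"}),
                      inhibitors=frozenset({"K1i"})),
        ]
        design = prepare_design(conditions, ("K1", "K2"), net)
        true_p1 = 1.4 * 0.8
        true_p2 = 1.4 * 0.8 * 1.1
        errors = []
        for seed in range(20):
            data = generate_perturbation_dataset(
                truth, design, noise_sd=0.2, n_reps=2, seed=seed,
                sd_mode="known")
            fit = fit_model(net, data, design,
                            FitSettings(n_starts=8, seed=seed))
            p = fit.model.params
            est_p1 = p.stim[("R", "L")] * p.r[("K1", "R")]
            est_p2 = est_p1 * p.r[("K2", "K1")]
            errors.append(abs(est_p1 - true_p1) / true_p1)
            errors.append(abs(est_p2 - true_p2) / true_p2)
        assert np.median(errors) < 0.10


class TestProfileLikelihood:
    def test_nonidentifiable_inhibitor_link_pair_is_flat(self):
        """With one downstream observation, only the product iota * r is
        constrained: the inhibitor-strength profile stays inside the 95%
        band across the whole grid."""
        net = load_network([("A", "B")], {"A": "kinase", "B": "kinase"},
                           inhibitor_map={"Ai": "A"})
        model = MRAModel(net, MRAParameters(
            r={("B", "A"): 0.8}, stim={}, inhib={"Ai": -1.0}))
        design = prepare_design(
            [Condition(), Condition(inhibitors=frozenset({"Ai"}))],
            ("A", "B"), net)
        data = generate_perturbation_dataset(model, design, 0.1, 2, seed=1,
                                             sd_mode="known")
        fit = fit_model(net, data, design, FitSettings(n_starts=10, seed=0))
        curve = profile_likelihood(fit, "i:Ai", np.linspace(-3.0, -0.3, 7))
        assert not curve.identifiable()
        assert np.all(curve.chi2 <= curve.threshold)

    def test_well_constrained_stimulus_has_unique_minimum(self, chain_model):
        model, design = chain_model
        data = noise_free_dataset(model, design)
        fit = fit_model(model.network, data, design,
                        FitSettings(n_starts=10, seed=0))
        grid = np.linspace(0.5, 2.5, 9)
        curve = profile_likelihood(fit, "s:L->A", grid)
        assert curve.identifiable()
        assert grid[np.argmin(curve.chi2)] == pytest.approx(1.5, abs=0.26)

    def test_grid_containing_best_fit_reaches_chi2_min(self, chain_model):
        model, design = chain_model
        data = noise_free_dataset(model, design)
        fit = fit_model(model.network, data, design,
                        FitSettings(n_starts=10, seed=0))
        best = fit.model.params.stim[("A", "L")]
        curve = profile_likelihood(fit, "s:L->A", [best - 0.2, best, best + 0.2])
        assert min(curve.chi2) == pytest.approx(fit.chi2, abs=1e-6)

    def test_grid_outside_range_rejected(self, chain_model):
        model, design = chain_model
        data = noise_free_dataset(model, design)
        fit = fit_model(model.network, data, design,
                        FitSettings(n_starts=2, seed=0))
        with pytest.raises(ValueError, match="outside"):
            profile_likelihood(fit, "s:L->A", [10.0])
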