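"""LRT p-values, greedy extension/reduction and inhibitor harmonisation."""

import numpy as np
import pytest

from mrafit import (
    Condition,
    FitSettings,
    MRAModel,
    MRAParameters,
    fit_model,
    load_network,
    lrt_pvalue,
    prepare_design,
)
from mrafit.selection import extend_model, harmonise_models, reduce_model
from mrafit.synthetic import (
    full_factorial_design,
    generate_perturbation_dataset,
    make_virtual_cell_line,
    panel_profiles,
)
from conftest import noise_free_dataset


class TestLrtPvalue:
    @pytest.mark.parametrize("delta, expected, tol", [
        (3.84, 0.05, 0.001),
        (0.0, 1.0, 0.0),
        (10.83, 0.001, 0.0001),
    ])
    def test_df1_reference_values(self, delta, expected, tol):
        assert lrt_pvalue(delta, 0.0, df=1) == pytest.approx(expected, abs=tol)

    def test_negative_delta_clamped_to_one(self):
        assert lrt_pvalue(5.0, 5.5, df=1) == 1.0

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(1.0, 0.0, df=0)


class TestExtendModel:
    def test_planted_link_accepted_first_round(self, planted_edge_problem):
        start_net, truth, design = planted_edge_problem
        data = generate_perturbation_dataset(truth, design, 0.2, 2, seed=4,
                                             sd_mode="known")
        base = fit_model(start_net, data, design,
                         FitSettings(n_starts=8, seed=0))
        _, trace = extend_model(base, data, design, bonferroni=True)
        assert trace.rounds[0].edge == ("B", "Y")
        assert trace.rounds[0].accepted
        assert trace.rounds[0].p_value < 0.05

    def test_noise_free_true_topology_accepts_nothing(self, planted_edge_problem):
        start_net, truth, design = planted_edge_problem
        # data generated from the start network itself, exactly
        start_model = MRAModel(start_net, MRAParameters(
            r={("B", "A"): 1.0, ("Y", "X"): 0.9},
            stim=truth.params.stim, inhib=truth.params.inhib))
        data = noise_free_dataset(start_model, design)
        base = fit_model(start_net, data, design,
                         FitSettings(n_starts=8, seed=0))
        _, trace = extend_model(base, data, design)
        assert trace.accepted_edges == ()

    def test_alpha_zero_accepts_nothing(self, planted_edge_problem):
        start_net, truth, design = planted_edge_problem
        data = generate_perturbation_dataset(truth, design, 0.2, 2, seed=4,
                                             sd_mode="known")
        base = fit_model(start_net, data, design,
                         FitSettings(n_starts=8, seed=0))
        _, trace = extend_model(base, data, design, alpha=0.0)
        assert trace.accepted_edges == ()

    def test_empty_candidate_set_returns_input(self, planted_edge_problem):
        start_net, truth, design = planted_edge_problem
        data = generate_perturbation_dataset(truth, design, 0.2, 2, seed=4)
        base = fit_model(start_net, data, design,
                         FitSettings(n_starts=4, seed=0))
        result, trace = extend_model(base, data, design,
                                     candidate_policy=lambda net: [])
        assert result is base and trace.rounds == ()

    def test_type_one_error_rate_compatible_with_alpha(self):
        """On null data (true topology), the fraction of datasets with any
        accepted link lies between the single-test rate alpha and the
        independence family-wise bound 1-(1-alpha)^c, each widened by
        binomial 95% sampling error."""
        net = load_network(
            [("A", "B"), ("B", "C")],
            {"A": "receptor", "B": "kinase", "C": "kinase"},
            ligand_map={"L": ("A",)}, inhibitor_map={"Bi": "B"})
        params = MRAParameters(
            r={("B", "A"): 1.0, ("C", "B"): 0.8},
            stim={("A", "L"): 1.5}, inhib={"Bi": -1.0})
        truth = MRAModel(net, params)
        conditions = [
            Condition(), Condition(stimuli=frozenset({"L"})),
            Condition(inhibitors=frozenset({"Bi"})),
            Condition(stimuli=frozenset({"L"}), inhibitors=frozenset({"Bi"})),
        ]
        design = prepare_design(conditions, ("A", "B", "C"), net)
        alpha, n_candidates, n_seeds = 0.05, 4, 50
        accepted = 0
        for seed in range(n_seeds):
            data = generate_perturbation_dataset(
                truth, design, 0.2, 2, seed=seed, sd_mode="known")
            base = fit_model(net, data, design,
                             FitSettings(n_starts=6, seed=seed))
            _, trace = extend_model(base, data, design, alpha=alpha,
                                    candidate_starts=3, max_rounds=1)
            accepted += bool(trace.accepted_edges)
        frac = accepted / n_seeds
        upper_p = 1 - (1 - alpha) ** n_candidates
        lo = alpha - 1.96 * np.sqrt(alpha * (1 - alpha) / n_seeds)
        hi = upper_p + 1.96 * np.sqrt(upper_p * (1 - upper_p) / n_seeds)
        assert max(lo, 0.0) <= frac <= hi


class TestReduceModel:
    def test_spurious_edge_removed_true_edges_kept(self, planted_edge_problem):
        start_net, truth, design = planted_edge_problem
        # data from the plain two-chain model; A->Y is a spurious extra edge
        null_model = MRAModel(start_net, MRAParameters(
            r={("B", "A"): 1.0, ("Y", "X"): 0.9},
            stim=truth.params.stim, inhib=truth.params.inhib))
        data = generate_perturbation_dataset(null_model, design, 0.2, 2,
                                             seed=2, sd_mode="known")
        bloated = start_net.with_edge("A", "Y")
        fit = fit_model(bloated, data, design, FitSettings(n_starts=8, seed=0))
        reduced, trace = reduce_model(fit, data, design)
        assert ("A", "Y") in trace.removed_edges
        assert set(start_net.edges) <= set(reduced.model.network.edges)

    def test_all_edges_protected_logs_retained_by_policy(self, planted_edge_problem):
        start_net, truth, design = planted_edge_problem
        null_model = MRAModel(start_net, MRAParameters(
            r={("B", "A"): 1.0, ("Y", "X"): 0.9},
            stim=truth.params.stim, inhib=truth.params.inhib))
        data = generate_perturbation_dataset(null_model, design, 0.2, 2,
                                             seed=2, sd_mode="known")
        fit = fit_model(start_net, data, design,
                        FitSettings(n_starts=6, seed=0))
        reduced, trace = reduce_model(fit, data, design,
                                      retain_policy=frozenset(start_net.edges))
        assert reduced.model.network.edges == start_net.edges
        assert all(not r.removed for r in trace.rounds)
        assert any(r.retained_by_policy for r in trace.rounds)

    def test_essential_chain_edge_survives(self):
        """Removing the only route from stimulus to a strongly responding
        readout is highly significant, so the edge is kept."""
        net = load_network(
            [("A", "B"), ("B", "C")],
            {"A": "receptor", "B": "kinase", "C": "kinase"},
            ligand_map={"L": ("A",)})
        params = MRAParameters(r={("B", "A"): 1.0, ("C", "B"): 1.0},
                               stim={("A", "L"): 2.0}, inhib={})
        truth = MRAModel(net, params)
        design = prepare_design(
            [Condition(), Condition(stimuli=frozenset({"L"}))],
            ("B", "C"), net)
        data = generate_perturbation_dataset(truth, design, 0.2, 2, seed=1,
                                             sd_mode="known")
        fit = fit_model(net, data, design, FitSettings(n_starts=6, seed=0))
        reduced, trace = reduce_model(fit, data, design)
        assert ("A", "B") in reduced.model.network.edges
        assert ("B", "C") in reduced.model.network.edges

    def test_extension_then_reduction_recovers_planted_topology(
            self, planted_edge_problem):
        start_net, truth, design = planted_edge_problem
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            data = generate_perturbation_dataset(
                truth, design, noise_sd=0.2, n_reps=2, seed=seed,
                sd_mode="known")
            base = fit_model(start_net, data, design,
                             FitSettings(n_starts=8, seed=0))
            ext, _ = extend_model(base, data, design, bonferroni=True)
            red, _ = reduce_model(ext, data, design,
                                  retain_policy=frozenset(start_net.edges))
            hits += set(red.model.network.edges) == set(truth.network.edges)
        assert hits >= 0.8 * n_seeds


class TestHarmoniseModels:
    def _two_fits(self, strengths, seed=0):
        net = load_network(
            [("R", "RAF"), ("RAF", "MEK"), ("MEK", "ERK"), ("ERK", "RAF")],
            {"R": "receptor", "RAF": "kinase", "MEK": "kinase",
             "ERK": "kinase"},
            ligand_map={"L": ("R",)}, inhibitor_map={"MEKi": "MEK"})
        conditions = [
            Condition(), Condition(stimuli=frozenset({"L"})),
            Condition(inhibitors=frozenset({"MEKi"})),
            Condition(stimuli=frozenset({"L"}),
                      inhibitors=frozenset({"MEKi"})),
        ]
        design = prepare_design(conditions, ("MEK", "ERK"), net)
        fits = []
        for k, iota in enumerate(strengths):
            params = MRAParameters(
                r={("RAF", "R"): 1.0, ("MEK", "RAF"): 0.8,
                   ("ERK", "MEK"): 0.9, ("RAF", "ERK"): -1.0},
                stim={("R", "L"): 1.0}, inhib={"MEKi": iota})
            model = MRAModel(net, params)
            data = noise_free_dataset(model, design)
            fits.append(fit_model(net, data, design,
                                  FitSettings(n_starts=6, seed=seed + k),
                                  warm_starts=[params]))
        return fits

    def test_consensus_is_arithmetic_mean(self):
        fits = self._two_fits([-1.0, -2.0])
        h = harmonise_models(fits)
        assert h.consensus["MEKi"] == pytest.approx(-1.5, abs=0.01)
        for refit in h.fits:
            assert refit.model.params.inhib["MEKi"] == pytest.approx(
                h.consensus["MEKi"])

    def test_single_model_idempotent(self):
        fits = self._two_fits([-1.0])
        h = harmonise_models(fits)
        assert h.consensus["MEKi"] == pytest.approx(
            fits[0].model.params.inhib["MEKi"])
        assert h.chi2_after[0] == pytest.approx(fits[0].chi2, abs=1e-6)

    def test_asymmetric_inhibitor_sets_rejected(self):
        fits = self._two_fits([-1.0])
        net2 = load_network([("A", "B")], {"A": "kinase", "B": "kinase"},
                            inhibitor_map={"Ai": "A"})
        model2 = MRAModel(net2, MRAParameters(
            r={("B", "A"): 0.5}, stim={}, inhib={"Ai": -1.0}))
        design2 = prepare_design(
            [Condition(), Condition(inhibitors=frozenset({"Ai"}))],
            ("A", "B"), net2)
        data2 = noise_free_dataset(model2, design2)
        fit2 = fit_model(net2, data2, design2, FitSettings(n_starts=3, seed=0))
        with pytest.raises(ValueError, match="Ai|MEKi"):
            harmonise_models([fits[0], fit2])

    def test_panel_consensus_recovery_with_small_inflation(self):
        """Six virtual lines sharing true MEKi strength -1: the consensus lands
        within 0.2 of the truth and refitting with it fixed inflates chi2 by
        under 5% on average at full-design scale."""
        profiles = panel_profiles()
        fits = []
        for k, name in enumerate(sorted(profiles)):
            truth = make_virtual_cell_line(profiles[name])
            design = full_factorial_design(truth.network)
            data = generate_perturbation_dataset(
                truth, design, noise_sd=0.2, n_reps=2, seed=300 + k,
                sd_mode="known")
            fits.append(fit_model(truth.network, data, design,
                                  FitSettings(n_starts=4, seed=k),
                                  warm_starts=[truth.params]))
        h = harmonise_models(fits)
        assert h.consensus["MEKi"] == pytest.approx(-1.0, abs=0.2)
        inflation = np.mean(
            [(a - b) / b for a, b in zip(h.chi2_after, h.chi2_before)])
        assert inflation < 0.05
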