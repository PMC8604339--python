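"""Reference simulation studies bundled with the package.

These are the canned in-silico experiments used to validate the pipeline
end to end on virtual cell lines: likelihood-ratio detection of a planted
receptor-mediated feedback, goodness-of-fit calibration of the weighted
chi-square against its theoretical mean, and drug-sensitivity phenotyping of
a synthetic panel.  Each study is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .drugresponse import fit_ic50, growth_rate, relative_growth
from .fitting import FitSettings, fit_model
from .network import simulate_design
from .selection import lrt_pvalue
from .synthetic import (
    VirtualCellLineProfile,
    focused_design,
    focused_network,
    full_factorial_design,
    generate_confluency_panel,
    generate_perturbation_dataset,
    make_virtual_cell_line,
    panel_profiles,
    synthetic_ic50_panel,
)
from .fitting import weighted_chi2

__all__ = [
    "planted_feedback_lrt_study",
    "chi2_calibration_study",
    "ic50_panel_study",
]


def planted_feedback_lrt_study(
    n_datasets: int = 20,
    seed: int = 0,
    noise_sd: float = 0.2,
    n_reps: int = 2,
    n_starts: int = 8,
) -> np.ndarray:
    """LRT p-values for adding the S6K->IGF1R feedback on data that has it.

    A virtual cell line with a strong pathway-intrinsic feedback (ERK->RAF
    multiplier 3.5) and the receptor-mediated S6K->IGF1R feedback (strength
    -1) is probed with the focused 3 stimulus x 3 inhibitor x 6 readout
    design.  Per dataset, models with and without the link are fitted from
    scratch and compared with the df=1 chi-square likelihood-ratio test.
    Returns one p-value per dataset.
    """
    profile = VirtualCellLineProfile(
        name="focused-feedback",
        feedback_multipliers={("ERK", "RAF"): 3.5, ("S6K", "IGF1R"): 1.0},
        noise_sd=noise_sd,
    )
    truth = make_virtual_cell_line(profile, network=focused_network())
    design = focused_design(truth.network)
    without_net = truth.network.without_edge("S6K", "IGF1R")
    rng = np.random.default_rng(seed)
    data_seeds = rng.integers(0, 2**31 - 1, size=n_datasets)
    p_values = []
    for k, data_seed in enumerate(data_seeds):
        data = generate_perturbation_dataset(
            truth, design, noise_sd=noise_sd, n_reps=n_reps,
            seed=int(data_seed), sd_mode="known")
        fit_with = fit_model(truth.network, data, design,
                             FitSettings(n_starts=n_starts, seed=2 * k))
        fit_without = fit_model(without_net, data, design,
                                FitSettings(n_starts=n_starts, seed=2 * k + 1))
        p_values.append(lrt_pvalue(fit_without.chi2, fit_with.chi2, df=1))
    return np.asarray(p_values)


def chi2_calibration_study(
    n_datasets: int = 100,
    seed: int = 0,
    noise_sd: float = 0.2,
    n_reps: int = 2,
    line: str = "VC4",
) -> tuple[np.ndarray, int]:
    """Weighted SSR of the generative model over full-factorial datasets.

    Datasets are drawn over the (4 ligands + control) x (7 inhibitors +
    control) x 6 readout design with Gaussian noise whose standard deviation
    equals the chi-square weighting SD, and the true model is evaluated
    without refitting.  If the model explains all the data the mean equals
    the unmasked data-point count.  Returns (per-dataset chi2 values,
    unmasked cell count).
    """
    truth = make_virtual_cell_line(panel_profiles()[line])
    design = full_factorial_design(truth.network)
    sim = simulate_design(truth, design)
    rng = np.random.default_rng(seed)
    data_seeds = rng.integers(0, 2**31 - 1, size=n_datasets)
    chis = [
        weighted_chi2(sim, generate_perturbation_dataset(
            truth, design, noise_sd=noise_sd, n_reps=n_reps,
            seed=int(s), sd_mode="known"))
        for s in data_seeds
    ]
    return np.asarray(chis), design.n_unmasked


def ic50_panel_study(seed: int = 0, noise_frac: float = 0.05) -> dict[str, float]:
    """Fitted MEK-inhibitor IC50s (uM) for the synthetic nine-line panel.

    Each line's confluency traces are generated from its declared
    dose-response curve over the standard 0.1-100 uM dose ladder (72 h at
    2 h intervals), growth rates extracted by log-linear regression,
    normalised to the DMSO control and refitted with the sigmoid.
    """
    rng = np.random.default_rng(seed)
    doses = [0.0, 0.1, 1.0, 10.0, 100.0]
    fitted = {}
    for name, (ic50_uM, slope) in synthetic_ic50_panel().items():
        traces = generate_confluency_panel(
            0.03, float(np.log(ic50_uM)), slope, doses,
            noise_frac=noise_frac, seed=int(rng.integers(0, 2**31 - 1)))
        rates = {tr.dose_uM: growth_rate(tr) for tr in traces}
        dmso = rates.pop(0.0)
        dd = np.array(sorted(rates))
        v = np.array([relative_growth(rates[d], dmso, clip=True) for d in dd])
        fitted[name] = fit_ic50(dd, v).ic50_uM
    return fitted
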