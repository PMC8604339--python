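"""Virtual cell lines and synthetic datasets for the whole pipeline.

The generators emulate the statistical structure of the perturbation study
the package is built for: a panel of neuroblastoma-like cell lines probed
with all combinations of 4 growth-factor ligands (or BSA carrier control) and
7 small-molecule inhibitors (or DMSO control), reading out 6 phosphoproteins
(pMEK, p-p38, pERK, p-cJUN, pAKT, pS6K) as log2 fold-changes to the
BSA+DMSO control, with at least 2 biological replicates and Gaussian
replicate noise on the log2 scale.  Virtual cell lines differ in receptor
expression (scaling ligand stimulus strengths), in the strength of the two
negative feedbacks that matter for MEK-inhibitor resistance (the
pathway-intrinsic ERK->RAF feedback, 3-4x stronger in resistant lines, and a
receptor-mediated S6K->IGF1R feedback present in a subset), and in an
NRAS-mutant-like rerouting (weaker receptor->MAPK, slightly stronger
receptor->PI3K coupling).

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .drugresponse import ConfluencyTrace, sigmoid
from .fitting import PerturbationDataset
from .network import (
    Condition,
    MRAModel,
    MRAParameters,
    PerturbationDesign,
    SignallingNetwork,
    SimulationError,
    load_network,
    prepare_design,
    simulate_design,
)
from .phospho import KinaseSubstrateSets, PhosphoMatrix

__all__ = [
    "LIGANDS",
    "INHIBITORS",
    "READOUTS",
    "VirtualCellLineProfile",
    "literature_network",
    "focused_network",
    "base_parameters",
    "full_factorial_design",
    "focused_design",
    "make_virtual_cell_line",
    "generate_perturbation_dataset",
    "generate_confluency_panel",
    "generate_phospho_dataset",
    "panel_profiles",
    "synthetic_ic50_panel",
]

LIGANDS = ("EGF", "PDGF", "NGF", "IGF1")
INHIBITORS = ("PI3Ki", "MEKi", "AKTi", "mTORi", "RAFi", "ASK1i", "ALKi")
READOUTS = ("MEK", "p38", "ERK", "cJUN", "AKT", "S6K")

#: default local response coefficients of the literature topology
_BASE_R = {
    ("MEK", "RAF"): 0.8,
    ("ERK", "MEK"): 0.9,
    ("RAF", "ERK"): -0.5,   # pathway-intrinsic negative feedback (base)
    ("AKT", "PI3K"): 0.8,
    ("mTOR", "AKT"): 0.7,
    ("S6K", "mTOR"): 0.9,
    ("p38", "ASK1"): 0.8,
    ("cJUN", "ASK1"): 0.7,
    ("IGF1R", "S6K"): -1.0,  # receptor-mediated negative feedback (base)
}

FEEDBACK_EDGES = (("ERK", "RAF"), ("S6K", "IGF1R"))


def literature_network() -> SignallingNetwork:
    """Canonical MAPK + PI3K/AKT network with intermediate nodes suppressed.

    Receptor tyrosine kinases feed RAF (MAPK branch) and PI3K; the well
    documented ERK->RAF feedback closes the MAPK loop.  IGF1 signals through
    both IGF1R (into MAPK) and IGF2R (into PI3K) independently.  The stress
    branch (ASK1 -> p38 / cJUN) is probed only through the ASK1 inhibitor.
    """
    roles = {
        "EGFR": "receptor", "PDGFR": "receptor", "NTRK1": "receptor",
        "IGF1R": "receptor", "IGF2R": "receptor", "ALK": "receptor",
        "RAF": "kinase", "MEK": "kinase", "ERK": "kinase",
        "PI3K": "kinase", "AKT": "kinase", "mTOR": "kinase", "S6K": "kinase",
        "ASK1": "kinase", "p38": "kinase", "cJUN": "kinase",
    }
    edges = [
        ("EGFR", "RAF"), ("PDGFR", "RAF"), ("NTRK1", "RAF"),
        ("IGF1R", "RAF"), ("ALK", "RAF"),
        ("EGFR", "PI3K"), ("PDGFR", "PI3K"), ("NTRK1", "PI3K"),
        ("IGF2R", "PI3K"), ("ALK", "PI3K"),
        ("RAF", "MEK"), ("MEK", "ERK"), ("ERK", "RAF"),
        ("PI3K", "AKT"), ("AKT", "mTOR"), ("mTOR", "S6K"),
        ("ASK1", "p38"), ("ASK1", "cJUN"),
    ]
    ligand_map = {
        "EGF": ("EGFR",), "PDGF": ("PDGFR",), "NGF": ("NTRK1",),
        "IGF1": ("IGF1R", "IGF2R"),
    }
    inhibitor_map = {
        "PI3Ki": "PI3K", "MEKi": "MEK", "AKTi": "AKT", "mTORi": "mTOR",
        "RAFi": "RAF", "ASK1i": "ASK1", "ALKi": "ALK",
    }
    return load_network(edges, roles, ligand_map, inhibitor_map,
                        upstream_acting_inhibitors={"AKTi"})


def focused_network() -> SignallingNetwork:
    """Reduced network for the focused feedback-dissection experiments.

    Growth-factor (EGF) and IGF1 inputs into MAPK and PI3K/AKT/mTOR/S6K,
    with the ERK->RAF feedback; p38 and cJUN are carried as measured but
    unperturbed nodes.  Inhibitors: MEKi and mTORi.
    """
    roles = {
        "EGFR": "receptor", "IGF1R": "receptor", "IGF2R": "receptor",
        "RAF": "kinase", "MEK": "kinase", "ERK": "kinase",
        "PI3K": "kinase", "AKT": "kinase", "mTOR": "kinase", "S6K": "kinase",
        "p38": "kinase", "cJUN": "kinase",
    }
    edges = [
        ("EGFR", "RAF"), ("IGF1R", "RAF"), ("EGFR", "PI3K"),
        ("IGF2R", "PI3K"),
        ("RAF", "MEK"), ("MEK", "ERK"), ("ERK", "RAF"),
        ("PI3K", "AKT"), ("AKT", "mTOR"), ("mTOR", "S6K"),
    ]
    ligand_map = {"EGF": ("EGFR",), "IGF1": ("IGF1R", "IGF2R")}
    inhibitor_map = {"MEKi": "MEK", "mTORi": "mTOR"}
    return load_network(edges, roles, ligand_map, inhibitor_map)


def base_parameters(network: SignallingNetwork) -> MRAParameters:
    """Default parameter template: named coefficients where defined,
    1.0 for receptor outputs and 0.8 for other kinase edges; unit stimulus
    strengths; all inhibitor strengths -1."""
    r = {}
    for src, tgt in network.edges:
        if (tgt, src) in _BASE_R:
            r[(tgt, src)] = _BASE_R[(tgt, src)]
        elif network.roles[src] == "receptor":
            r[(tgt, src)] = 1.0
        else:
            r[(tgt, src)] = 0.8
    stim = {
        (rec, lig): 1.0
        for lig, recs in network.ligand_map.items() for rec in recs
    }
    inhib = {name: -1.0 for name in network.inhibitor_map}
    return MRAParameters(r=r, stim=stim, inhib=inhib)


def full_factorial_design(network: SignallingNetwork | None = None) -> PerturbationDesign:
    """(4 ligands + BSA control) x (7 inhibitors + DMSO control), 6 readouts.

    40 conditions x 6 readouts = 240 design cells per cell line; the pAKT
    readout is masked under AKT inhibition.
    """
    network = network or literature_network()
    conditions = [
        Condition(stimuli=frozenset(stim), inhibitors=frozenset(inhib))
        for stim, inhib in product(
            [()] + [(lig,) for lig in LIGANDS],
            [()] + [(inh,) for inh in INHIBITORS],
        )
    ]
    return prepare_design(conditions, READOUTS, network)


def focused_design(network: SignallingNetwork | None = None) -> PerturbationDesign:
    """3 stimulus x 3 inhibitor focused design over the 6 readouts.

    Stimuli {BSA, EGF, IGF1} crossed with {DMSO, MEKi, mTORi}.  An inhibitor
    upstream of S6K is required for a receptor feedback out of S6K to be
    identifiable under the linear steady-state contract, because superposition
    makes purely MAPK-directed inhibitors blind to it (see docs/methods.md).
    """
    network = network or focused_network()
    conditions = [
        Condition(stimuli=frozenset(stim), inhibitors=frozenset(inhib))
        for stim, inhib in product(
            [(), ("EGF",), ("IGF1",)],
            [(), ("MEKi",), ("mTORi",)],
        )
    ]
    return prepare_design(conditions, READOUTS, network)


@dataclass(frozen=True)
class VirtualCellLineProfile:
    """Structural description of one virtual cell line.

    ``receptor_expression`` scales the stimulus strengths of ligands hitting
    each receptor (relative level, 1 = reference).  ``feedback_multipliers``
    scale the base strengths of the ERK->RAF and S6K->IGF1R feedbacks; a zero
    S6K->IGF1R multiplier means the link is absent from the topology.
    ``nras_mutant`` halves receptor->RAF couplings and scales receptor->PI3K
    couplings by 1.5.
    """

    name: str = "VC"
    receptor_expression: dict[str, float] = field(default_factory=dict)
    feedback_multipliers: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("ERK", "RAF"): 1.0, ("S6K", "IGF1R"): 0.0})
    nras_mutant: bool = False
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for edge, mult in self.feedback_multipliers.items():
            if edge not in FEEDBACK_EDGES:
                raise ValueError(f"unknown feedback edge {edge}")
            if mult < 0:
                raise ValueError(f"feedback multiplier for {edge} must be >= 0")
        for rec, level in self.receptor_expression.items():
            if level < 0:
                raise ValueError(f"receptor expression for {rec} must be >= 0")


NRAS_MAPK_FACTOR = 0.5
NRAS_PI3K_FACTOR = 1.5


def make_virtual_cell_line(
    profile: VirtualCellLineProfile,
    network: SignallingNetwork | None = None,
    base_params: MRAParameters | None = None,
) -> MRAModel:
    """Deterministic ground-truth model for one virtual cell line."""
    network = network or literature_network()
    params = base_params or base_parameters(network)
    r = dict(params.r)
    stim = dict(params.stim)
    inhib = dict(params.inhib)
    # receptor expression scales stimulus strengths
    for (rec, lig), value in list(stim.items()):
        stim[(rec, lig)] = value * profile.receptor_expression.get(rec, 1.0)
    # feedback multipliers on base strengths; zero multiplier = absent link
    net = network
    for src, tgt in FEEDBACK_EDGES:
        mult = profile.feedback_multipliers.get((src, tgt))
        if mult is None:
            continue
        base = params.r.get((tgt, src), _BASE_R[(tgt, src)])
        if (src, tgt) in net.edges:
            if mult == 0:
                net = net.without_edge(src, tgt)
                r.pop((tgt, src), None)
            else:
                r[(tgt, src)] = base * mult
        elif mult > 0:
            net = net.with_edge(src, tgt)
            r[(tgt, src)] = base * mult
    if profile.nras_mutant:
        for (tgt, src), value in list(r.items()):
            if net.roles.get(src) == "receptor":
                if tgt == "RAF":
                    r[(tgt, src)] = value * NRAS_MAPK_FACTOR
                elif tgt == "PI3K":
                    r[(tgt, src)] = value * NRAS_PI3K_FACTOR
    model = MRAModel(network=net,
                     params=MRAParameters(r=r, stim=stim, inhib=inhib))
    # fail fast if the requested feedbacks destabilise the steady state
    system = np.eye(len(net.nodes)) - model.r_matrix()
    if np.linalg.cond(system) > 1e12:
        raise SimulationError(
            f"virtual cell line {profile.name!r} is unstable ((I - r) "
            f"singular); reduce the feedback multipliers"
        )
    return model


def generate_perturbation_dataset(
    model: MRAModel,
    design: PerturbationDesign,
    noise_sd: float = 0.2,
    n_reps: int = 2,
    seed: int = 0,
    sd_mode: str = "replicate",
    sd_floor: float = 0.1,
) -> PerturbationDataset:
    """Replicated noisy measurements of a model over a design.

    Per unmasked cell, ``n_reps`` independent draws of simulated value +
    Gaussian(0, noise_sd); the dataset stores the replicate mean and, as the
    weighting SD, either the floored empirical replicate scatter
    (``sd_mode="replicate"``) or the exact noise standard error of the mean
    ``noise_sd/sqrt(n_reps)`` (``sd_mode="known"``, useful for calibration
    studies where the weighting SD must equal the generative noise SD).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if sd_mode not in ("replicate", "known"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    rng = np.random.default_rng(seed)
    sim = simulate_design(model, design)
    reps = sim.values[None, :, :] + rng.normal(
        0.0, noise_sd, size=(n_reps,) + sim.values.shape)
    if sd_mode == "replicate":
        dataset = PerturbationDataset.from_replicates(
            reps, sim.labels, sim.readouts, sd_floor=sd_floor)
    else:
        mean = reps.mean(axis=0)
        sd = np.full_like(mean, noise_sd / np.sqrt(n_reps))
        dataset = PerturbationDataset(values=mean, sd=sd, n_reps=n_reps,
                                      labels=sim.labels, readouts=sim.readouts)
    return dataset


def generate_confluency_panel(
    growth_rate0: float,
    drug_ic50: float,
    drug_slope: float,
    doses,
    duration_h: float = 72.0,
    interval_h: float = 2.0,
    noise_frac: float = 0.05,
    seed: int = 0,
    conf0: float = 5.0,
    drug: str = "drug",
) -> list[ConfluencyTrace]:
    """Exponential confluency traces under a dose-response sigmoid.

    Each dose grows at ``growth_rate0 * V(dose)`` with V the two-parameter
    sigmoid (``drug_ic50`` on the natural-log concentration scale); traces
    carry multiplicative log-normal noise of relative SD ``noise_frac``.
    Dose 0 denotes the DMSO control (V = 1).  Sampling mirrors live-cell
    imaging runs: ``duration_h`` hours at ``interval_h`` spacing.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 0.5 * interval_h, interval_h)
    traces = []
    for dose in doses:
        if dose < 0:
            raise ValueError("doses must be >= 0")
        v = 1.0 if dose == 0 else float(sigmoid(np.array([dose]), drug_ic50,
                                                drug_slope)[0])
        clean = conf0 * np.exp(growth_rate0 * v * t)
        noise = np.exp(rng.normal(0.0, noise_frac, size=t.shape))
        traces.append(ConfluencyTrace(
            time_h=t, confluency=clean * noise,
            label=f"{drug}@{dose:g}uM", drug=drug, dose_uM=float(dose)))
    return traces


def generate_phospho_dataset(
    n_sites: int,
    kinase_sets: KinaseSubstrateSets,
    activity_shifts: dict[str, float],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PhosphoMatrix:
    """Single-contrast site score column with planted kinase activities.

    Background sites are Gaussian(0, noise_sd); each kinase's substrates are
    additionally shifted by its activity shift.  A site annotated to several
    shifted kinases receives the sum of their shifts.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    unknown = set(activity_shifts) - set(kinase_sets.sets)
    if unknown:
        raise ValueError(f"shifts reference unknown kinases {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    substrate_ids = sorted(set().union(*kinase_sets.sets.values()))
    background_ids = [f"BG{i:05d}_S1" for i in range(n_sites)]
    ids = background_ids + [s for s in substrate_ids if s not in background_ids]
    scores = pd.Series(rng.normal(0.0, noise_sd, size=len(ids)), index=ids)
    for kinase, shift in activity_shifts.items():
        for site in kinase_sets.sets[kinase]:
            scores.loc[site] += shift
    frame = scores.to_frame("score")
    return PhosphoMatrix(data=frame, annotation={"score": "synthetic contrast"})


def panel_profiles() -> dict[str, VirtualCellLineProfile]:
    """Default six-line virtual panel spanning weak to strong feedback.

    ERK->RAF feedback multipliers (1, 1, 1, 2, 3.5, 3.5) mirror the observed
    sensitive-to-resistant spectrum; the two NRAS-mutant-like lines sit among
    the weak-feedback members, and the strongest-feedback line additionally
    carries the receptor-mediated S6K->IGF1R feedback.
    """
    mults = [1.0, 1.0, 1.0, 2.0, 3.5, 3.5]
    expression = [
        {"EGFR": 1.2, "IGF1R": 0.8},
        {"NTRK1": 1.5},
        {},
        {"IGF1R": 1.3, "IGF2R": 1.2},
        {"EGFR": 0.6, "IGF1R": 1.1},
        {"IGF1R": 1.4, "IGF2R": 1.3},
    ]
    profiles = {}
    for k, (mult, expr) in enumerate(zip(mults, expression), start=1):
        profiles[f"VC{k}"] = VirtualCellLineProfile(
            name=f"VC{k}",
            receptor_expression=expr,
            feedback_multipliers={
                ("ERK", "RAF"): mult,
                ("S6K", "IGF1R"): 1.0 if k == 6 else 0.0,
            },
            nras_mutant=k in (2, 3),
            seed=k,
        )
    return profiles


def synthetic_ic50_panel() -> dict[str, tuple[float, float]]:
    """Synthetic stand-in drug-sensitivity panel: name -> (IC50 uM, slope).

    Constructed fixture (no measured values): nine lines of which six are
    MEK-inhibitor resistant with IC50 above 10 uM and three are highly
    sensitive in the 10-100 nM range, matching the qualitative composition
    of a heterogeneous high-risk panel.
    """
    return {
        "SYN-R1": (25.0, -1.5),
        "SYN-R2": (40.0, -1.2),
        "SYN-R3": (60.0, -2.0),
        "SYN-R4": (18.0, -1.0),
        "SYN-R5": (80.0, -1.8),
        "SYN-R6": (30.0, -1.4),
        "SYN-S1": (0.012, -1.5),
        "SYN-S2": (0.05, -1.2),
        "SYN-S3": (0.09, -2.0),
    }
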