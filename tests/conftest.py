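"""Shared fixtures: small hand-checkable networks and virtual cell lines."""

import numpy as np
import pytest

from mrafit import (
    Condition,
    MRAModel,
    MRAParameters,
    load_network,
    prepare_design,
)


@pytest.fixture
def mapk_cycle():
    """3-node MAPK core with a strong negative ERK->RAF feedback and MEKi."""
    net = load_network(
        [("RAF", "MEK"), ("MEK", "ERK"), ("ERK", "RAF")],
        {"RAF": "kinase", "MEK": "kinase", "ERK": "kinase"},
        inhibitor_map={"MEKi": "MEK"},
    )
    params = MRAParameters(
        r={("MEK", "RAF"): 1.0, ("ERK", "MEK"): 1.0, ("RAF", "ERK"): -2.0},
        stim={}, inhib={"MEKi": -1.0},
    )
    return MRAModel(net, params)


@pytest.fixture
def chain_model():
    """Fully measured acyclic chain A->B->C->D with a ligand and an inhibitor.

    Every parameter is identifiable from the four conditions, which makes it
    the reference problem for exact parameter recovery.
    """
    net = load_network(
        [("A", "B"), ("B", "C"), ("C", "D")],
        {"A": "receptor", "B": "kinase", "C": "kinase", "D": "kinase"},
        ligand_map={"L": ("A",)}, inhibitor_map={"Bi": "B"},
    )
    params = MRAParameters(
        r={("B", "A"): 0.7, ("C", "B"): 1.2, ("D", "C"): -0.6},
        stim={("A", "L"): 1.5}, inhib={"Bi": -0.8},
    )
    model = MRAModel(net, params)
    conditions = [
        Condition(),
        Condition(stimuli=frozenset({"L"})),
        Condition(inhibitors=frozenset({"Bi"})),
        Condition(stimuli=frozenset({"L"}), inhibitors=frozenset({"Bi"})),
    ]
    design = prepare_design(conditions, ("A", "B", "C", "D"), net)
    return model, design


@pytest.fixture
def planted_edge_problem():
    """Two parallel chains plus a planted cross-link B->Y that is uniquely
    identifiable: B carries its own inhibitor (separating B->Y from A->Y) and
    both X and Y are measured (separating B->Y from B->X)."""
    net = load_network(
        [("A", "B"), ("X", "Y")],
        {"A": "receptor", "B": "kinase", "X": "receptor", "Y": "kinase"},
        ligand_map={"L1": ("A",), "L2": ("X",)}, inhibitor_map={"Bi": "B"},
    )
    true_net = net.with_edge("B", "Y")
    params = MRAParameters(
        r={("B", "A"): 1.0, ("Y", "X"): 0.9, ("Y", "B"): -1.0},
        stim={("A", "L1"): 1.5, ("X", "L2"): 1.2}, inhib={"Bi": -1.0},
    )
    truth = MRAModel(true_net, params)
    conditions = [
        Condition(),
        Condition(stimuli=frozenset({"L1"})),
        Condition(stimuli=frozenset({"L2"})),
        Condition(inhibitors=frozenset({"Bi"})),
        Condition(stimuli=frozenset({"L1"}), inhibitors=frozenset({"Bi"})),
        Condition(stimuli=frozenset({"L2"}), inhibitors=frozenset({"Bi"})),
    ]
    design = prepare_design(conditions, ("A", "B", "X", "Y"), true_net)
    return net, truth, design


def noise_free_dataset(model, design, sd=0.1):
    """Dataset whose values equal the simulation exactly (unit test helper)."""
    from mrafit import PerturbationDataset, simulate_design

    sim = simulate_design(model, design)
    return PerturbationDataset(
        values=sim.values.copy(), sd=np.full_like(sim.values, sd), n_reps=2,
        labels=sim.labels, readouts=sim.readouts,
    )
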