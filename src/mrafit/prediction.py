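"""Path values and combination-treatment predictions from fitted models.

A path value is the product of the local response coefficients along a route
(prefixed by the stimulus strength when the route starts at a ligand), giving
a directly comparable per-model summary of how strongly a perturbation is
routed into a measured node.  Because path values across models are only
defined up to the shared non-identifiabilities, tables are usually presented
scaled by the per-route maximum absolute value.

Combination predictions follow the dual-effect inhibitor convention: an
inhibitor of strength iota acts as a negative stimulus transmitted strictly
downstream of its target.  One consequence deserves emphasis because it is
the least intuitive part of the contract: an ERK inhibitor does not reduce
the measured ERK phosphosite itself (the phosphosite is upstream of the drug's
action), it only attenuates what ERK transmits — so ERKi neither suppresses a
MEKi-induced pMEK feedback rise nor lowers pERK in the simulation, which is
exactly the measured behaviour that motivates vertical inhibition at RAF
rather than ERK.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import Condition, MRAModel, NetworkError, simulate_response

__all__ = [
    "PathRoute",
    "PathValueTable",
    "ComboPrediction",
    "path_value",
    "enumerate_routes",
    "path_value_table",
    "scale_paths_across_models",
    "predict_combination",
]


@dataclass(frozen=True)
class PathRoute:
    """Ordered node route; may optionally start at a ligand name."""

    nodes: tuple[str, ...]
    ligand: str | None = None

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValueError("route must contain at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"route repeats a node: {self.nodes}")

    @property
    def label(self) -> str:
        head = (self.ligand + "->") if self.ligand else ""
        return head + "->".join(self.nodes)


@dataclass(frozen=True)
class PathValueTable:
    """Routes x models matrix of path values."""

    routes: tuple[str, ...]
    models: tuple[str, ...]
    values: np.ndarray


@dataclass(frozen=True)
class ComboPrediction:
    """Predicted log2-FC per readout of adding inhibitors to a stimulus."""

    stimulus: Condition
    inhibitors: dict[str, float]
    response: dict[str, float]


def path_value(model: MRAModel, route: PathRoute) -> float:
    """Product of coefficients along a route (times stimulus strength if
    ligand-origin)."""
    network = model.network
    value = 1.0
    if route.ligand is not None:
        rec = route.nodes[0]
        if route.ligand not in network.ligand_map or \
                rec not in network.ligand_map[route.ligand]:
            raise NetworkError(
                f"ligand {route.ligand!r} does not stimulate {rec!r}")
        value *= model.params.stim[(rec, route.ligand)]
    for src, tgt in zip(route.nodes, route.nodes[1:]):
        if (src, tgt) not in network.edges:
            raise NetworkError(f"route {route.label} has no edge {src}->{tgt}")
        value *= model.params.r[(tgt, src)]
    return float(value)


def enumerate_routes(model: MRAModel, entry: str, readout: str,
                     max_len: int = 6) -> list[PathRoute]:
    """All simple paths from an entry node to a readout, up to ``max_len`` nodes."""
    g = nx.DiGraph(model.network.edges)
    if entry not in g or readout not in g:
        return []
    return [
        PathRoute(nodes=tuple(p))
        for p in nx.all_simple_paths(g, entry, readout, cutoff=max_len - 1)
    ]


def path_value_table(models: dict[str, MRAModel], routes: list[PathRoute]) -> PathValueTable:
    """Evaluate the same routes across a panel of models."""
    names = tuple(models)
    values = np.array(
        [[path_value(models[m], route) for m in names] for route in routes]
    )
    return PathValueTable(routes=tuple(r.label for r in routes), models=names,
                          values=values)


def scale_paths_across_models(table: PathValueTable) -> PathValueTable:
    """Scale each route row by its maximum absolute value across models.

    Scaled entries lie in [-1, 1]; all-zero rows stay zero.
    """
    if table.values.size == 0:
        raise ValueError("empty path value table")
    scale = np.max(np.abs(table.values), axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return PathValueTable(routes=table.routes, models=table.models,
                          values=table.values / scale)


def predict_combination(
    model: MRAModel,
    stimulus: Condition,
    inhibitors: dict[str, float | None],
) -> ComboPrediction:
    """Predict readout changes of an inhibitor combination on top of a stimulus.

    Returns, per node, the simulated log2-FC relative to the stimulus-only
    condition.  Unspecified inhibitor strengths default to -1, the convention
    used when comparing vertical-inhibition strategies across models.
    """
    network = model.network
    strengths = {}
    for name, value in inhibitors.items():
        if name not in network.inhibitor_map:
            raise NetworkError(f"unknown inhibitor {name!r}")
        strengths[name] = -1.0 if value is None else float(value)
    base = simulate_response(model, stimulus)
    override = type(model.params)(
        r=dict(model.params.r), stim=dict(model.params.stim),
        inhib={**model.params.inhib, **strengths},
    )
    treated_model = type(model)(network=network, params=override)
    combo = Condition(
        stimuli=stimulus.stimuli,
        inhibitors=stimulus.inhibitors | frozenset(strengths),
        label=f"{stimulus.label}+{'+'.join(sorted(strengths)) or 'none'}",
    )
    treated = simulate_response(treated_model, combo)
    response = {node: treated[node] - base[node] for node in network.nodes}
    return ComboPrediction(stimulus=stimulus, inhibitors=strengths,
                           response=response)
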