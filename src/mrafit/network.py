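"""Signalling networks, perturbation designs and steady-state response simulation.

The model is the modular-response-analysis (MRA) linearisation of a signalling
network at pseudo-steady state: each node's log2 fold-change ``a_i`` (relative
to the unperturbed control) is a linear combination of the fold-changes of its
direct upstream regulators, external ligand stimuli and small-molecule
inhibitor perturbations,

    a = r (a + d) + u        <=>        a = (I - r)^{-1} (r d + u)

where ``r[target, source]`` is the local response coefficient attached to the
network edge source -> target (zero diagonal), ``u`` collects ligand stimulus
strengths on receptor nodes, and ``d`` carries inhibitor strengths on the
inhibited nodes.  Inhibitors have a dual effect: they act as a negative
stimulus transmitted to every node downstream of the target, but the target's
own measured phosphorylation stays driven by its upstream inputs only.  A
consequence worth remembering is that relief of a negative feedback can raise
the measured phosphorylation of the inhibited node itself (the classic pMEK
rise under MEK inhibitor when an ERK->RAF feedback is present).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkError",
    "SimulationError",
    "SignallingNetwork",
    "Condition",
    "PerturbationDesign",
    "MRAParameters",
    "MRAModel",
    "ResponseMatrix",
    "load_network",
    "prepare_design",
    "simulate_response",
    "simulate_design",
]

#: node roles accepted by :class:`SignallingNetwork`
ROLES = ("receptor", "kinase")


class NetworkError(ValueError):
    """Invalid network structure or configuration."""


class SimulationError(RuntimeError):
    """Steady-state system is singular or numerically unstable."""


@dataclass(frozen=True)
class SignallingNetwork:
    """Directed signalling network with perturbation entry points.

    Parameters
    ----------
    nodes
        Node names in deterministic (insertion) order.
    roles
        Node -> ``"receptor"`` or ``"kinase"``.
    edges
        Ordered ``(source, target)`` pairs; no duplicates, no self-loops.
        Cycles are allowed — feedback loops are the point.
    ligand_map
        Ligand name -> tuple of receptor nodes it activates.  A ligand hitting
        two receptors (IGF1 -> IGF1R and IGF2R) gets one stimulus parameter
        per (receptor, ligand) pair.
    inhibitor_map
        Inhibitor name -> target node.
    upstream_acting_inhibitors
        Inhibitors that block the target's own activating phosphorylation
        (act upstream of the annotated node); the target readout must be
        masked whenever they are applied.
    """

    nodes: tuple[str, ...]
    roles: dict[str, str]
    edges: tuple[tuple[str, str], ...]
    ligand_map: dict[str, tuple[str, ...]]
    inhibitor_map: dict[str, str]
    upstream_acting_inhibitors: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for src, tgt in self.edges:
            if src == tgt:
                raise NetworkError(f"self-loop edge ({src}, {tgt}) is not allowed")
            if (src, tgt) in seen:
                raise NetworkError(f"duplicate edge ({src}, {tgt})")
            seen.add((src, tgt))
            for name in (src, tgt):
                if name not in self.roles:
                    raise NetworkError(f"edge references unknown node {name!r}")
        for node, role in self.roles.items():
            if role not in ROLES:
                raise NetworkError(f"node {node!r} has unknown role {role!r}")
        for lig, receptors in self.ligand_map.items():
            for rec in receptors:
                if rec not in self.roles:
                    raise NetworkError(f"ligand {lig!r} maps to unknown node {rec!r}")
        for inh, tgt in self.inhibitor_map.items():
            if tgt not in self.roles:
                raise NetworkError(f"inhibitor {inh!r} maps to unknown node {tgt!r}")
        for inh in self.upstream_acting_inhibitors:
            if inh not in self.inhibitor_map:
                raise NetworkError(
                    f"upstream-acting inhibitor {inh!r} missing from inhibitor_map"
                )

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def receptors(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.roles[n] == "receptor")

    def with_edge(self, source: str, target: str) -> "SignallingNetwork":
        """Return a copy with one extra edge (used by model extension)."""
        return replace(self, edges=self.edges + ((source, target),))

    def without_edge(self, source: str, target: str) -> "SignallingNetwork":
        """Return a copy with one edge removed (used by model reduction)."""
        if (source, target) not in self.edges:
            raise NetworkError(f"edge ({source}, {target}) not in network")
        return replace(
            self, edges=tuple(e for e in self.edges if e != (source, target))
        )


@dataclass(frozen=True)
class Condition:
    """One treatment: a set of ligand stimuli and a set of inhibitors.

    Empty sets denote the vehicle controls (BSA for ligands, DMSO for
    inhibitors); the all-empty condition is the reference against which every
    fold-change is expressed, so its simulated response is identically zero.
    """

    stimuli: frozenset[str] = frozenset()
    inhibitors: frozenset[str] = frozenset()
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            stim = "+".join(sorted(self.stimuli)) or "ctrl"
            inhib = "+".join(sorted(self.inhibitors)) or "ctrl"
            object.__setattr__(self, "label", f"{stim}|{inhib}")


@dataclass(frozen=True)
class PerturbationDesign:
    """Ordered conditions x readouts layout with a fitting mask.

    ``mask`` lists (condition label, readout) cells excluded from any
    objective, e.g. the pAKT readout under AKT inhibition.
    """

    conditions: tuple[Condition, ...]
    readouts: tuple[str, ...]
    mask: frozenset[tuple[str, str]] = frozenset()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    @property
    def n_cells(self) -> int:
        """Total number of design cells before masking."""
        return len(self.conditions) * len(self.readouts)

    @property
    def n_unmasked(self) -> int:
        return self.n_cells - len(self.mask)

    def mask_array(self) -> np.ndarray:
        """Boolean conditions x readouts array, True where masked."""
        out = np.zeros((len(self.conditions), len(self.readouts)), dtype=bool)
        ridx = {r: j for j, r in enumerate(self.readouts)}
        lidx = {lab: i for i, lab in enumerate(self.labels)}
        for lab, readout in self.mask:
            out[lidx[lab], ridx[readout]] = True
        return out


@dataclass(frozen=True)
class MRAParameters:
    """Numeric parameters of an MRA model.

    ``r`` maps (target, source) -> local response coefficient, one entry per
    edge; ``stim`` maps (receptor, ligand) -> stimulus strength (log2-FC
    units, >= 0); ``inhib`` maps inhibitor name -> strength (log2-FC units,
    <= 0, a negative stimulus).
    """

    r: dict[tuple[str, str], float]
    stim: dict[tuple[str, str], float]
    inhib: dict[str, float]

    def validate(self, network: SignallingNetwork) -> None:
        edge_keys = {(tgt, src) for src, tgt in network.edges}
        if set(self.r) != edge_keys:
            missing = edge_keys - set(self.r)
            extra = set(self.r) - edge_keys
            raise NetworkError(
                f"r keys do not match edges (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        for (rec, lig), value in self.stim.items():
            if lig not in network.ligand_map or rec not in network.ligand_map[lig]:
                raise NetworkError(f"stim key ({rec}, {lig}) not in ligand_map")
            if value < 0:
                raise NetworkError(f"stim({rec}, {lig}) = {value} must be >= 0")
        for inh, value in self.inhib.items():
            if inh not in network.inhibitor_map:
                raise NetworkError(f"inhib key {inh!r} not in inhibitor_map")
            if value > 0:
                raise NetworkError(f"inhib({inh}) = {value} must be <= 0")


@dataclass(frozen=True)
class MRAModel:
    """A signalling network together with its numeric MRA parameters."""

    network: SignallingNetwork
    params: MRAParameters

    def __post_init__(self) -> None:
        self.params.validate(self.network)

    def r_matrix(self) -> np.ndarray:
        """Local response coefficient matrix, ``r[target, source]``."""
        idx = self.network.node_index
        r = np.zeros((len(idx), len(idx)))
        for (tgt, src), value in self.params.r.items():
            r[idx[tgt], idx[src]] = value
        return r


@dataclass(frozen=True)
class ResponseMatrix:
    """Simulated conditions x readouts log2 fold-changes with masked cells NaN."""

    values: np.ndarray
    labels: tuple[str, ...]
    readouts: tuple[str, ...]


def load_network(
    edge_records,
    roles,
    ligand_map=None,
    inhibitor_map=None,
    upstream_acting_inhibitors=(),
) -> SignallingNetwork:
    """Build and validate a :class:`SignallingNetwork` from edge records.

    Node order is deterministic: insertion order of ``roles``, then any node
    first seen in the edge list.
    """
    if not edge_records:
        raise NetworkError("edge record list is empty")
    roles = dict(roles)
    for src, tgt in edge_records:
        if not src or not tgt:
            raise NetworkError(f"blank node name in edge ({src!r}, {tgt!r})")
        for name in (src, tgt):
            roles.setdefault(name, "kinase")
    nodes = tuple(roles)
    ligand_map = {k: tuple(v) if not isinstance(v, str) else (v,)
                  for k, v in (ligand_map or {}).items()}
    return SignallingNetwork(
        nodes=nodes,
        roles=roles,
        edges=tuple(tuple(e) for e in edge_records),
        ligand_map=ligand_map,
        inhibitor_map=dict(inhibitor_map or {}),
        upstream_acting_inhibitors=frozenset(upstream_acting_inhibitors),
    )


def prepare_design(conditions, readouts, network: SignallingNetwork) -> PerturbationDesign:
    """Validate conditions against the network and build the fitting mask.

    Each condition whose inhibitor set contains an upstream-acting inhibitor
    gets the cell (condition, target readout) masked — the measured
    phosphosite of such a target no longer reports pathway activity (e.g.
    MK2206 blocks AKT auto-phosphorylation, so pAKT is removed under AKTi).
    """
    conditions = tuple(conditions)
    readouts = tuple(readouts)
    known_ligands = set(network.ligand_map)
    known_inhibitors = set(network.inhibitor_map)
    for cond in conditions:
        bad_l = set(cond.stimuli) - known_ligands
        bad_i = set(cond.inhibitors) - known_inhibitors
        if bad_l:
            raise NetworkError(
                f"condition {cond.label!r} uses unknown ligand(s) {sorted(bad_l)}; "
                f"valid: {sorted(known_ligands)}"
            )
        if bad_i:
            raise NetworkError(
                f"condition {cond.label!r} uses unknown inhibitor(s) {sorted(bad_i)}; "
                f"valid: {sorted(known_inhibitors)}"
            )
    for readout in readouts:
        if readout not in network.roles:
            raise NetworkError(f"readout {readout!r} is not a network node")
    mask = set()
    for cond in conditions:
        for inh in cond.inhibitors & network.upstream_acting_inhibitors:
            target = network.inhibitor_map[inh]
            if target in readouts:
                mask.add((cond.label, target))
    return PerturbationDesign(conditions=conditions, readouts=readouts,
                              mask=frozenset(mask))


def _steady_state(model: MRAModel, condition: Condition) -> np.ndarray:
    network = model.network
    idx = network.node_index
    n = len(idx)
    u = np.zeros(n)
    for lig in condition.stimuli:
        for rec in network.ligand_map[lig]:
            u[idx[rec]] += model.params.stim.get((rec, lig), 0.0)
    d = np.zeros(n)
    for inh in condition.inhibitors:
        d[idx[network.inhibitor_map[inh]]] += model.params.inhib.get(inh, -1.0)
    r = model.r_matrix()
    system = np.eye(n) - r
    rhs = r @ d + u
    try:
        a = np.linalg.solve(system, rhs)
    except np.linalg.LinAlgError:
        rho = float(np.max(np.abs(np.linalg.eigvals(r))))
        raise SimulationError(
            f"network at instability: (I - r) singular, spectral radius {rho:.4g}"
        ) from None
    if not np.all(np.isfinite(a)) or np.linalg.cond(system) > 1e12:
        rho = float(np.max(np.abs(np.linalg.eigvals(r))))
        raise SimulationError(
            f"network at instability: ill-conditioned (I - r), "
            f"spectral radius {rho:.4g}"
        )
    return a


def simulate_response(model: MRAModel, condition: Condition) -> dict[str, float]:
    """Steady-state log2 fold-change of every node under one condition."""
    a = _steady_state(model, condition)
    return dict(zip(model.network.nodes, a.tolist()))


def simulate_design(model: MRAModel, design: PerturbationDesign) -> ResponseMatrix:
    """Simulate all design conditions; masked cells are NaN."""
    idx = model.network.node_index
    for readout in design.readouts:
        if readout not in idx:
            raise NetworkError(f"readout {readout!r} not in model network")
    cols = [idx[r] for r in design.readouts]
    rows = []
    for cond in design.conditions:
        try:
            a = _steady_state(model, cond)
        except SimulationError as err:
            raise SimulationError(f"condition {cond.label!r}: {err}") from err
        rows.append(a[cols])
    values = np.asarray(rows, dtype=float)
    values[design.mask_array()] = np.nan
    return ResponseMatrix(values=values, labels=design.labels,
                          readouts=design.readouts)
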