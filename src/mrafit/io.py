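"""File formats: perturbation CSV (MIDAS-style), network TSV+YAML, model JSON.

The perturbation CSV dialect is the de-facto convention for this kind of
data: one row per measured replicate, treatment columns ``TR:<name>`` with
0/1 flags (ligands and inhibitors are told apart by the network's maps),
readout columns ``DV:<node>`` with log2 fold-changes, and an optional
``ID:label`` column.  Replicate rows sharing a treatment pattern are
aggregated to mean and floored standard error.  Models round-trip through a
sorted-keys JSON document carrying the network, the parameters, the
goodness-of-fit summary and the fit settings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, FitSettings, PerturbationDataset
from .network import (
    Condition,
    MRAModel,
    MRAParameters,
    NetworkError,
    PerturbationDesign,
    SignallingNetwork,
    load_network,
    prepare_design,
)

__all__ = [
    "read_network",
    "write_network",
    "read_perturbation_csv",
    "write_perturbation_csv",
    "write_model_json",
    "read_model_json",
]


def read_network(edges_path, config_path) -> SignallingNetwork:
    """Load a network from a ``source<TAB>target`` edge list and a YAML config
    block with roles, ligand_map, inhibitor_map, upstream_acting_inhibitors."""
    edges = []
    for lineno, line in enumerate(Path(edges_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkError(
                f"{edges_path}:{lineno}: expected 'source<TAB>target', "
                f"got {line!r}")
        edges.append((parts[0], parts[1]))
    config = yaml.safe_load(Path(config_path).read_text()) or {}
    return load_network(
        edges,
        roles=config.get("roles", {}),
        ligand_map=config.get("ligand_map", {}),
        inhibitor_map=config.get("inhibitor_map", {}),
        upstream_acting_inhibitors=config.get("upstream_acting_inhibitors", []),
    )


def write_network(network: SignallingNetwork, edges_path, config_path) -> None:
    Path(edges_path).write_text(
        "".join(f"{src}\t{tgt}\n" for src, tgt in network.edges))
    config = {
        "roles": dict(network.roles),
        "ligand_map": {k: list(v) for k, v in network.ligand_map.items()},
        "inhibitor_map": dict(network.inhibitor_map),
        "upstream_acting_inhibitors": sorted(network.upstream_acting_inhibitors),
    }
    # insertion order is the canonical (deterministic) node order
    Path(config_path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_perturbation_csv(
    path,
    network: SignallingNetwork,
    sd_floor: float = 0.1,
) -> tuple[PerturbationDesign, PerturbationDataset]:
    """Parse a MIDAS-style CSV into a design and replicate-aggregated dataset."""
    frame = pd.read_csv(path)
    tr_cols = [c for c in frame.columns if c.startswith("TR:")]
    dv_cols = [c for c in frame.columns if c.startswith("DV:")]
    other = [c for c in frame.columns
             if not c.startswith(("TR:", "DV:", "ID:"))]
    if other:
        raise ValueError(
            f"{path}: unknown column prefix in {other}; expected TR:/DV:/ID:")
    if not dv_cols:
        raise ValueError(f"{path}: no DV: readout columns")
    if frame[tr_cols + dv_cols].isna().any().any():
        bad = int(frame[tr_cols + dv_cols].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}: ragged/missing values around line {bad}")
    readouts = tuple(c[3:] for c in dv_cols)
    known_l, known_i = set(network.ligand_map), set(network.inhibitor_map)
    treatments = [c[3:] for c in tr_cols]
    unknown = [t for t in treatments if t not in known_l | known_i]
    if unknown:
        raise NetworkError(
            f"{path}: unknown treatment(s) {unknown}; valid ligands "
            f"{sorted(known_l)}, inhibitors {sorted(known_i)}")

    def row_condition(row) -> Condition:
        stimuli = frozenset(t for c, t in zip(tr_cols, treatments)
                            if t in known_l and row[c])
        inhibitors = frozenset(t for c, t in zip(tr_cols, treatments)
                               if t in known_i and row[c])
        return Condition(stimuli=stimuli, inhibitors=inhibitors)

    conditions: list[Condition] = []
    groups: dict[str, list[np.ndarray]] = {}
    label_flags: dict[str, tuple] = {}
    for _, row in frame.iterrows():
        cond = row_condition(row)
        label = str(row["ID:label"]) if "ID:label" in frame.columns else cond.label
        flags = tuple(int(row[c]) for c in tr_cols)
        if label in label_flags:
            if label_flags[label] != flags:
                raise ValueError(
                    f"{path}: condition label {label!r} appears with "
                    f"conflicting TR flags")
        else:
            label_flags[label] = flags
            conditions.append(Condition(stimuli=cond.stimuli,
                                        inhibitors=cond.inhibitors,
                                        label=label))
        groups.setdefault(label, []).append(
            row[dv_cols].to_numpy(dtype=float))
    design = prepare_design(conditions, readouts, network)
    values = np.empty((len(conditions), len(readouts)))
    sd = np.empty_like(values)
    n_reps = min(len(g) for g in groups.values())
    for i, cond in enumerate(conditions):
        reps = np.vstack(groups[cond.label])
        n = reps.shape[0]
        values[i] = reps.mean(axis=0)
        scatter = reps.std(axis=0, ddof=1) if n > 1 else np.zeros(len(readouts))
        sd[i] = np.maximum(scatter, sd_floor) / np.sqrt(n)
    mask = design.mask_array()
    values[mask] = np.nan
    dataset = PerturbationDataset(values=values, sd=sd, n_reps=n_reps,
                                  labels=design.labels, readouts=readouts)
    return design, dataset


def write_perturbation_csv(
    path,
    design: PerturbationDesign,
    network: SignallingNetwork,
    replicates: np.ndarray,
) -> None:
    """Write a replicates x conditions x readouts stack in the MIDAS dialect."""
    treatments = list(network.ligand_map) + list(network.inhibitor_map)
    rows = []
    for rep in range(replicates.shape[0]):
        for i, cond in enumerate(design.conditions):
            row = {"ID:label": cond.label}
            for t in treatments:
                active = t in cond.stimuli or t in cond.inhibitors
                row[f"TR:{t}"] = int(active)
            for j, readout in enumerate(design.readouts):
                row[f"DV:{readout}"] = replicates[rep, i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _network_to_dict(network: SignallingNetwork) -> dict:
    return {
        "nodes": list(network.nodes),
        "roles": dict(network.roles),
        "edges": [list(e) for e in network.edges],
        "ligand_map": {k: list(v) for k, v in network.ligand_map.items()},
        "inhibitor_map": dict(network.inhibitor_map),
        "upstream_acting_inhibitors": sorted(network.upstream_acting_inhibitors),
    }


def _network_from_dict(doc: dict) -> SignallingNetwork:
    for key in ("roles", "edges"):
        if key not in doc:
            raise ValueError(f"model JSON network section missing field {key!r}")
    roles = doc["roles"]
    if "nodes" in doc:  # restore node ordering (sorted-keys JSON loses it)
        roles = {n: roles[n] for n in doc["nodes"]}
    return load_network(
        [tuple(e) for e in doc["edges"]],
        roles=roles,
        ligand_map=doc.get("ligand_map", {}),
        inhibitor_map=doc.get("inhibitor_map", {}),
        upstream_acting_inhibitors=doc.get("upstream_acting_inhibitors", []),
    )


def write_model_json(fit: FitResult | MRAModel, path, traces: dict | None = None,
                     extra: dict | None = None) -> None:
    """Serialise a fit (or bare model) to deterministic sorted-keys JSON."""
    if isinstance(fit, MRAModel):
        model, meta = fit, {}
    else:
        model = fit.model
        meta = {
            "chi2": fit.chi2,
            "n_data": fit.n_data,
            "n_free": fit.n_free,
            "seed": fit.settings.seed,
            "settings": {
                "n_starts": fit.settings.n_starts,
                "r_range": list(fit.settings.r_range),
                "stim_range": list(fit.settings.stim_range),
                "inhib_range": list(fit.settings.inhib_range),
                "max_iter": fit.settings.max_iter,
                "tol": fit.settings.tol,
                "fixed_params": dict(fit.settings.fixed_params),
            },
        }
    doc = {
        "network": _network_to_dict(model.network),
        "parameters": {
            "r": {f"{src}->{tgt}": model.params.r[(tgt, src)]
                  for src, tgt in model.network.edges},
            "stim": {f"{lig}->{rec}": value
                     for (rec, lig), value in model.params.stim.items()},
            "inhib": dict(model.params.inhib),
        },
        **meta,
    }
    if traces:
        doc["traces"] = traces
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def read_model_json(path) -> tuple[MRAModel, dict]:
    """Load a model JSON; returns the model and the remaining metadata."""
    doc = json.loads(Path(path).read_text())
    if "network" not in doc:
        raise ValueError(f"{path}: model JSON missing field 'network'")
    network = _network_from_dict(doc["network"])
    pdoc = doc.get("parameters", {})
    r = {}
    for key, value in pdoc.get("r", {}).items():
        src, tgt = key.split("->")
        r[(tgt, src)] = float(value)
    stim = {}
    for key, value in pdoc.get("stim", {}).items():
        lig, rec = key.split("->")
        stim[(rec, lig)] = float(value)
    inhib = {k: float(v) for k, v in pdoc.get("inhib", {}).items()}
    model = MRAModel(network=network,
                     params=MRAParameters(r=r, stim=stim, inhib=inhib))
    meta = {k: v for k, v in doc.items() if k not in ("network", "parameters")}
    return model, meta
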