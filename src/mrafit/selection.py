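"""Likelihood-ratio-driven network extension, reduction and harmonisation.

Extension follows a greedy hill climb: each round, every absent edge is added
singly and refitted, the candidate with the largest chi-square drop is
accepted if its df=1 likelihood-ratio test beats ``alpha``, and the loop runs
until no significant link can be added.  Reduction mirrors it: present edges
are dropped singly and the least informative one removed while its removal is
non-significant, unless a retain policy protects it (e.g. the shared
literature core, kept so parameters stay comparable across cell lines).

Harmonisation addresses the structural interdependence between an inhibitor
strength and the link strength downstream of the inhibited node: since every
cell line received the same inhibitor concentrations, inhibitor parameters
are fixed to their consensus (arithmetic mean) across models and each model
is refitted, making the remaining link parameters directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .fitting import FitResult, FitSettings, PerturbationDataset, fit_model
from .network import PerturbationDesign, SignallingNetwork

__all__ = [
    "ExtensionRound",
    "ExtensionTrace",
    "ReductionRound",
    "ReductionTrace",
    "HarmonisedSet",
    "lrt_pvalue",
    "candidate_edges",
    "extend_model",
    "reduce_model",
    "harmonise_models",
]


@dataclass(frozen=True)
class ExtensionRound:
    edge: tuple[str, str]
    delta_chi2: float
    p_value: float
    accepted: bool
    candidates: tuple[tuple[tuple[str, str], float, float], ...]  # (edge, dchi2, p)


@dataclass(frozen=True)
class ExtensionTrace:
    rounds: tuple[ExtensionRound, ...]

    @property
    def accepted_edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(r.edge for r in self.rounds if r.accepted)


@dataclass(frozen=True)
class ReductionRound:
    edge: tuple[str, str]
    delta_chi2: float
    p_value: float
    removed: bool
    retained_by_policy: bool


@dataclass(frozen=True)
class ReductionTrace:
    rounds: tuple[ReductionRound, ...]

    @property
    def removed_edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(r.edge for r in self.rounds if r.removed)


@dataclass(frozen=True)
class HarmonisedSet:
    """Per-model refits with inhibitor strengths fixed to the consensus."""

    consensus: dict[str, float]
    fits: tuple[FitResult, ...]
    chi2_before: tuple[float, ...]

    @property
    def chi2_after(self) -> tuple[float, ...]:
        return tuple(f.chi2 for f in self.fits)


def lrt_pvalue(chi2_nested: float, chi2_full: float, df: int = 1) -> float:
    """Likelihood-ratio p-value for nested weighted least-squares models.

    The chi-square drop from adding ``df`` parameters is referred to the
    chi-square distribution with ``df`` degrees of freedom; a negative drop
    (numerical noise) is clamped to zero.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = max(chi2_nested - chi2_full, 0.0)
    return float(chi2_dist.sf(delta, df=df))


def candidate_edges(network: SignallingNetwork) -> list[tuple[str, str]]:
    """Default candidate universe for extension.

    All ordered node pairs that are not already edges, excluding self-loops.
    Edges into receptor nodes are allowed — receptor-mediated feedbacks
    (S6K into the IGF1 receptor) are exactly the discoveries of interest.
    Ligands are perturbations, not nodes, so they are never candidates.
    """
    existing = set(network.edges)
    return [
        (src, tgt)
        for src in network.nodes
        for tgt in network.nodes
        if src != tgt and (src, tgt) not in existing
    ]


def _candidate_settings(settings: FitSettings, n_starts: int) -> FitSettings:
    return FitSettings(
        n_starts=n_starts,
        r_range=settings.r_range,
        stim_range=settings.stim_range,
        inhib_range=settings.inhib_range,
        seed=settings.seed,
        max_iter=settings.max_iter,
        tol=settings.tol,
        fixed_params=dict(settings.fixed_params),
    )


def extend_model(
    fit: FitResult,
    data: PerturbationDataset,
    design: PerturbationDesign,
    alpha: float = 0.05,
    candidate_policy=None,
    candidate_starts: int = 5,
    max_rounds: int = 20,
    bonferroni: bool = False,
) -> tuple[FitResult, ExtensionTrace]:
    """Greedy single-link extension until no candidate passes the LRT.

    Candidate refits are warm-started from the incumbent parameters plus a
    small Latin-hypercube batch for the new coefficient.  By default ``alpha``
    is applied per test with no multiplicity correction across candidates,
    the single-threshold convention of greedy hill climbing; with
    ``bonferroni=True`` the per-round threshold becomes alpha / number of
    candidates, trading sensitivity for control of spurious acceptances when
    the candidate universe is large.  Tie-breaks on equal chi-square drop go
    to lexicographic (source, target) order.
    """
    policy = candidate_policy or candidate_edges
    rounds: list[ExtensionRound] = []
    current = fit
    for _ in range(max_rounds):
        candidates = sorted(policy(current.model.network))
        if not candidates:
            break
        threshold = alpha / len(candidates) if bonferroni else alpha
        results = []
        for src, tgt in candidates:
            net = current.model.network.with_edge(src, tgt)
            warm = current.model.params
            warm_ext = type(warm)(
                r={**warm.r, (tgt, src): 0.0}, stim=dict(warm.stim),
                inhib=dict(warm.inhib),
            )
            sub = fit_model(
                net, data, design,
                _candidate_settings(current.settings, candidate_starts),
                warm_starts=[warm_ext],
            )
            dchi2 = max(current.chi2 - sub.chi2, 0.0)
            p = lrt_pvalue(current.chi2, sub.chi2, df=1)
            results.append(((src, tgt), dchi2, p, sub))
        results.sort(key=lambda item: (-item[1], item[0]))
        best_edge, best_dchi2, best_p, best_fit = results[0]
        table = tuple((e, d, p) for e, d, p, _ in results)
        accepted = best_p < threshold
        rounds.append(ExtensionRound(edge=best_edge, delta_chi2=best_dchi2,
                                     p_value=best_p, accepted=accepted,
                                     candidates=table))
        if not accepted:
            break
        current = best_fit
    return current, ExtensionTrace(rounds=tuple(rounds))


def reduce_model(
    fit: FitResult,
    data: PerturbationDataset,
    design: PerturbationDesign,
    alpha: float = 0.05,
    retain_policy=frozenset(),
    candidate_starts: int = 5,
    max_rounds: int = 50,
) -> tuple[FitResult, ReductionTrace]:
    """Successive removal of non-significant links.

    Each round drops every present edge singly and refits; the edge whose
    removal costs the least chi-square is removed if the cost is
    non-significant (p >= alpha).  Edges in ``retain_policy`` are logged as
    retained-by-policy instead of removed, so that a shared core topology can
    be preserved for cross-model parameter comparison.
    """
    protected = frozenset(tuple(e) for e in retain_policy)
    rounds: list[ReductionRound] = []
    current = fit
    for _ in range(max_rounds):
        removable = sorted(set(current.model.network.edges))
        if not removable:
            break
        results = []
        for src, tgt in removable:
            net = current.model.network.without_edge(src, tgt)
            warm = current.model.params
            warm_red = type(warm)(
                r={k: v for k, v in warm.r.items() if k != (tgt, src)},
                stim=dict(warm.stim), inhib=dict(warm.inhib),
            )
            sub = fit_model(
                net, data, design,
                _candidate_settings(current.settings, candidate_starts),
                warm_starts=[warm_red],
            )
            dchi2 = max(sub.chi2 - current.chi2, 0.0)
            p = lrt_pvalue(sub.chi2, current.chi2, df=1)
            results.append(((src, tgt), dchi2, p, sub))
        results.sort(key=lambda item: (item[1], item[0]))
        # smallest chi2 cost first; find least costly non-protected edge
        candidate = next((item for item in results if item[0] not in protected), None)
        significant_only = candidate is None or candidate[2] < alpha
        if candidate is not None and not significant_only:
            edge, dchi2, p, sub = candidate
            rounds.append(ReductionRound(edge=edge, delta_chi2=dchi2, p_value=p,
                                         removed=True, retained_by_policy=False))
            current = sub
            continue
        # remaining removals are significant or protected: log and stop
        for edge, dchi2, p, _ in results:
            rounds.append(ReductionRound(
                edge=edge, delta_chi2=dchi2, p_value=p, removed=False,
                retained_by_policy=edge in protected,
            ))
        break
    return current, ReductionTrace(rounds=tuple(rounds))


def harmonise_models(fits: list[FitResult]) -> HarmonisedSet:
    """Fix inhibitor strengths to their cross-model mean and refit each model.

    All member fits must expose the same inhibitor names; the consensus is
    the arithmetic mean per inhibitor.  Refits keep each model's own design
    and data, with the inhibitor parameters held at the consensus via the
    fixed-parameter mechanism.
    """
    if not fits:
        raise ValueError("no fits to harmonise")
    names = [set(f.model.network.inhibitor_map) for f in fits]
    common = names[0]
    for other in names[1:]:
        if other != common:
            asym = common.symmetric_difference(other)
            raise ValueError(
                f"inhibitor sets differ across models: {sorted(asym)}"
            )
    consensus = {
        name: float(np.mean([f.model.params.inhib[name] for f in fits]))
        for name in sorted(common)
    }
    refits = []
    for f in fits:
        fixed = dict(f.settings.fixed_params)
        fixed.update({f"i:{name}": value for name, value in consensus.items()})
        settings = FitSettings(**{**f.settings.__dict__, "fixed_params": fixed})
        warm = f.model.params
        warm_fixed = type(warm)(
            r=dict(warm.r), stim=dict(warm.stim), inhib=dict(consensus),
        )
        refits.append(fit_model(f.model.network, f.data, f.design, settings,
                                warm_starts=[warm_fixed]))
    return HarmonisedSet(
        consensus=consensus,
        fits=tuple(refits),
        chi2_before=tuple(f.chi2 for f in fits),
    )
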