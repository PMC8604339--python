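"""Weighted maximum-likelihood fitting of MRA models.

Estimation is weighted nonlinear least squares: the objective is the weighted
chi-square

    chi2 = sum over unmasked cells ((data - sim) / sd)^2

whose minimiser is the maximum-likelihood estimate under independent Gaussian
noise with the given per-cell standard deviations.  The global search is a
seeded Latin-hypercube multistart over the parameter box, each start refined
by a trust-region-reflective least-squares optimiser; starts that land on a
singular (I - r) are discarded, not retried, so the start count stays
reproducible.  Profile likelihood curves (re-optimising all other parameters
on a grid for one) expose the structural non-identifiabilities typical of this
model class, e.g. the interdependence of an inhibitor strength and the link
strength directly downstream of the inhibited node.

Parameter identifiers are strings: ``"r:SRC->TGT"`` for local response
coefficients, ``"s:LIGAND->RECEPTOR"`` for stimulus strengths and
``"i:NAME"`` for inhibitor strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import qmc

from .network import (
    MRAModel,
    MRAParameters,
    PerturbationDesign,
    ResponseMatrix,
    SignallingNetwork,
)

__all__ = [
    "PerturbationDataset",
    "FitSettings",
    "FitResult",
    "ProfileCurve",
    "FitError",
    "weighted_chi2",
    "fit_model",
    "profile_likelihood",
    "param_ids",
    "params_to_vector",
    "vector_to_params",
]

_PENALTY = 1e8


class FitError(RuntimeError):
    """All multistart attempts failed."""


@dataclass(frozen=True)
class PerturbationDataset:
    """Measured conditions x readouts log2-FC means with per-cell weights.

    ``values`` and ``sd`` are conditions x readouts arrays aligned with a
    :class:`~mrafit.network.PerturbationDesign`; masked cells may be NaN.
    ``sd`` is the weighting standard deviation of each stored mean.
    """

    values: np.ndarray
    sd: np.ndarray
    n_reps: int
    labels: tuple[str, ...]
    readouts: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sd", sd)
        if values.shape != sd.shape:
            raise ValueError(f"values {values.shape} vs sd {sd.shape} shape mismatch")
        if values.shape != (len(self.labels), len(self.readouts)):
            raise ValueError(
                f"data shape {values.shape} does not match "
                f"{len(self.labels)} conditions x {len(self.readouts)} readouts"
            )
        finite = np.isfinite(values)
        if np.any(sd[finite] <= 0):
            raise ValueError("sd must be > 0 for every unmasked cell")

    @classmethod
    def from_replicates(
        cls,
        replicates: np.ndarray,
        labels,
        readouts,
        sd_floor: float = 0.1,
    ) -> "PerturbationDataset":
        """Aggregate a replicates x conditions x readouts stack to mean/SD.

        The stored ``sd`` is the standard error of the replicate mean, floored
        at ``sd_floor / sqrt(n_reps)`` to avoid infinite weights when
        replicates agree by luck.
        """
        replicates = np.asarray(replicates, dtype=float)
        if replicates.ndim != 3:
            raise ValueError("replicates must be a 3-d stack")
        n_reps = replicates.shape[0]
        mean = replicates.mean(axis=0)
        sd = replicates.std(axis=0, ddof=1) if n_reps > 1 else np.zeros_like(mean)
        sd = np.maximum(sd, sd_floor) / np.sqrt(n_reps)
        return cls(values=mean, sd=sd, n_reps=n_reps,
                   labels=tuple(labels), readouts=tuple(readouts))


@dataclass(frozen=True)
class FitSettings:
    """Controls for the multistart weighted least-squares search."""

    n_starts: int = 100
    r_range: tuple[float, float] = (-5.0, 5.0)
    stim_range: tuple[float, float] = (0.0, 5.0)
    inhib_range: tuple[float, float] = (-5.0, 0.0)
    seed: int = 0
    max_iter: int = 1000
    tol: float = 1e-8
    fixed_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for lo, hi in (self.r_range, self.stim_range, self.inhib_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("parameter ranges must be finite with lo < hi")


@dataclass(frozen=True)
class FitResult:
    """Best-fit model with goodness-of-fit bookkeeping."""

    model: MRAModel
    chi2: float
    residuals: np.ndarray  # conditions x readouts, NaN on masked cells
    n_data: int
    n_free: int
    start_chi2s: tuple[float, ...]
    settings: FitSettings
    design: PerturbationDesign
    data: PerturbationDataset


@dataclass(frozen=True)
class ProfileCurve:
    """Profile likelihood of one parameter: chi2 re-optimised along a grid."""

    param_id: str
    grid: np.ndarray
    chi2: np.ndarray
    chi2_min: float
    threshold: float

    def identifiable(self) -> bool:
        """Whether the curve exceeds the 95% threshold somewhere on the grid."""
        return bool(np.any(self.chi2 > self.threshold))


# ---------------------------------------------------------------------------
# parameter vector layout


def param_ids(network: SignallingNetwork) -> tuple[str, ...]:
    """Canonical parameter ordering: edges, then stimuli, then inhibitors."""
    ids = [f"r:{src}->{tgt}" for src, tgt in network.edges]
    for lig in network.ligand_map:
        for rec in network.ligand_map[lig]:
            ids.append(f"s:{lig}->{rec}")
    ids.extend(f"i:{name}" for name in network.inhibitor_map)
    return tuple(ids)


def params_to_vector(network: SignallingNetwork, params: MRAParameters) -> np.ndarray:
    vec = []
    for src, tgt in network.edges:
        vec.append(params.r[(tgt, src)])
    for lig in network.ligand_map:
        for rec in network.ligand_map[lig]:
            vec.append(params.stim.get((rec, lig), 0.0))
    for name in network.inhibitor_map:
        vec.append(params.inhib.get(name, 0.0))
    return np.asarray(vec, dtype=float)


def vector_to_params(network: SignallingNetwork, vec: np.ndarray) -> MRAParameters:
    vec = np.asarray(vec, dtype=float)
    pos = 0
    r = {}
    for src, tgt in network.edges:
        r[(tgt, src)] = float(vec[pos])
        pos += 1
    stim = {}
    for lig in network.ligand_map:
        for rec in network.ligand_map[lig]:
            stim[(rec, lig)] = float(vec[pos])
            pos += 1
    inhib = {}
    for name in network.inhibitor_map:
        inhib[name] = float(vec[pos])
        pos += 1
    return MRAParameters(r=r, stim=stim, inhib=inhib)


def _bounds(network: SignallingNetwork, settings: FitSettings) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for pid in param_ids(network):
        if pid.startswith("r:"):
            rng = settings.r_range
        elif pid.startswith("s:"):
            rng = settings.stim_range
        else:
            rng = settings.inhib_range
        lo.append(rng[0])
        hi.append(rng[1])
    return np.asarray(lo), np.asarray(hi)


class _Objective:
    """Design compiled to index arrays for fast residual evaluation.

    One evaluation fills r, U and D from the parameter vector and does a
    single (I - r) solve against all condition right-hand sides.
    """

    def __init__(self, network: SignallingNetwork, design: PerturbationDesign,
                 data: PerturbationDataset):
        if data.labels != design.labels or data.readouts != design.readouts:
            raise ValueError(
                f"dataset layout {data.labels}x{data.readouts} does not match "
                f"design {design.labels}x{design.readouts}"
            )
        self.network = network
        idx = network.node_index
        self.n_nodes = len(idx)
        self.n_cond = len(design.conditions)
        ids = param_ids(network)
        self.ids = ids
        pid_pos = {pid: k for k, pid in enumerate(ids)}
        # edge coefficient placement
        self.r_pos = np.array(
            [pid_pos[f"r:{src}->{tgt}"] for src, tgt in network.edges], dtype=int)
        self.r_tgt = np.array([idx[tgt] for _, tgt in network.edges], dtype=int)
        self.r_src = np.array([idx[src] for src, _ in network.edges], dtype=int)
        # stimulus and inhibitor placement per condition
        s_pos, s_node, s_cond = [], [], []
        i_pos, i_node, i_cond = [], [], []
        for c, cond in enumerate(design.conditions):
            for lig in cond.stimuli:
                for rec in network.ligand_map[lig]:
                    s_pos.append(pid_pos[f"s:{lig}->{rec}"])
                    s_node.append(idx[rec])
                    s_cond.append(c)
            for inh in cond.inhibitors:
                i_pos.append(pid_pos[f"i:{inh}"])
                i_node.append(idx[network.inhibitor_map[inh]])
                i_cond.append(c)
        self.s_pos = np.array(s_pos, dtype=int)
        self.s_node = np.array(s_node, dtype=int)
        self.s_cond = np.array(s_cond, dtype=int)
        self.i_pos = np.array(i_pos, dtype=int)
        self.i_node = np.array(i_node, dtype=int)
        self.i_cond = np.array(i_cond, dtype=int)
        self.readout_rows = np.array([idx[r] for r in design.readouts], dtype=int)
        unmasked = ~design.mask_array() & np.isfinite(data.values)
        self.unmasked = unmasked
        self.data = data.values
        self.sd = data.sd
        self.n_data = int(unmasked.sum())
        self.eye = np.eye(self.n_nodes)

    def simulate(self, vec: np.ndarray) -> np.ndarray:
        """Readout responses (conditions x readouts) for a full parameter vector."""
        r = np.zeros((self.n_nodes, self.n_nodes))
        r[self.r_tgt, self.r_src] = vec[self.r_pos]
        u = np.zeros((self.n_nodes, self.n_cond))
        if self.s_pos.size:
            np.add.at(u, (self.s_node, self.s_cond), vec[self.s_pos])
        d = np.zeros((self.n_nodes, self.n_cond))
        if self.i_pos.size:
            np.add.at(d, (self.i_node, self.i_cond), vec[self.i_pos])
        a = np.linalg.solve(self.eye - r, r @ d + u)
        return a[self.readout_rows].T

    def residuals(self, vec: np.ndarray) -> np.ndarray:
        try:
            sim = self.simulate(vec)
        except np.linalg.LinAlgError:
            return np.full(self.n_data, _PENALTY)
        if not np.all(np.isfinite(sim)) or np.max(np.abs(sim)) > 1e8:
            return np.full(self.n_data, _PENALTY)
        res = (self.data - sim) / self.sd
        return res[self.unmasked]


def weighted_chi2(sim: ResponseMatrix, data: PerturbationDataset) -> float:
    """Weighted sum of squared residuals over unmasked cells.

    If the model explains all the data, its expectation equals the number of
    unmasked data points (mean of a chi-square with that many degrees of
    freedom) — the calibration yardstick used to judge goodness of fit.
    """
    if sim.values.shape != data.values.shape:
        raise ValueError(
            f"shape mismatch: simulation {sim.values.shape} vs data "
            f"{data.values.shape}"
        )
    res = (data.values - sim.values) / data.sd
    return float(np.nansum(res ** 2))


def fit_model(
    network: SignallingNetwork,
    data: PerturbationDataset,
    design: PerturbationDesign,
    settings: FitSettings | None = None,
    warm_starts: list[MRAParameters] | None = None,
) -> FitResult:
    """Multistart weighted least-squares fit of an MRA model.

    ``n_starts`` Latin-hypercube samples of the free parameters (seeded, so
    the whole fit is deterministic) are each refined by a bounded
    trust-region least-squares optimiser; the best chi-square wins.
    ``fixed_params`` entries are held constant and excluded from ``n_free``.
    ``warm_starts`` prepends explicit start points (used by model selection
    and profiling) to the random ones.
    """
    settings = settings or FitSettings()
    obj = _Objective(network, design, data)
    ids = obj.ids
    lo, hi = _bounds(network, settings)
    fixed = dict(settings.fixed_params)
    unknown = set(fixed) - set(ids)
    if unknown:
        raise ValueError(f"fixed_params reference unknown parameters {sorted(unknown)}")
    free_idx = np.array([k for k, pid in enumerate(ids) if pid not in fixed],
                        dtype=int)
    full0 = np.zeros(len(ids))
    for pid, val in fixed.items():
        full0[ids.index(pid)] = val
    n_free = len(free_idx)

    def expand(x_free: np.ndarray) -> np.ndarray:
        full = full0.copy()
        full[free_idx] = x_free
        return full

    def fun(x_free: np.ndarray) -> np.ndarray:
        return obj.residuals(expand(x_free))

    starts: list[np.ndarray] = []
    for wp in warm_starts or []:
        starts.append(params_to_vector(network, wp)[free_idx])
    if n_free > 0:
        sampler = qmc.LatinHypercube(d=n_free, seed=settings.seed)
        unit = sampler.random(settings.n_starts)
        starts.extend(qmc.scale(unit, lo[free_idx], hi[free_idx]))
    else:
        starts.append(np.zeros(0))

    best_x = None
    best_chi2 = np.inf
    start_chi2s: list[float] = []
    statuses: list[str] = []
    for x0 in starts:
        x0 = np.clip(x0, lo[free_idx], hi[free_idx])
        r0 = fun(x0)
        if r0[0] >= _PENALTY:  # singular start: discard, do not retry
            statuses.append("singular_start")
            start_chi2s.append(np.inf)
            continue
        if n_free == 0:
            chi2_val = float(r0 @ r0)
            start_chi2s.append(chi2_val)
            statuses.append("fixed")
            if chi2_val < best_chi2:
                best_chi2, best_x = chi2_val, x0
            continue
        try:
            sol = optimize.least_squares(
                fun, x0, bounds=(lo[free_idx], hi[free_idx]), method="trf",
                xtol=settings.tol, ftol=settings.tol, gtol=settings.tol,
                max_nfev=settings.max_iter * max(n_free, 1),
            )
        except Exception as err:  # pragma: no cover - optimiser edge cases
            statuses.append(f"failed: {err}")
            start_chi2s.append(np.inf)
            continue
        chi2_val = float(2.0 * sol.cost)
        start_chi2s.append(chi2_val)
        statuses.append("ok")
        if chi2_val < best_chi2:
            best_chi2, best_x = chi2_val, sol.x
    if best_x is None:
        raise FitError(
            "all starts failed; per-start status: " + ", ".join(statuses)
        )
    full = expand(best_x)
    params = vector_to_params(network, full)
    model = MRAModel(network=network, params=params)
    sim = obj.simulate(full)
    residuals = (data.values - sim) / data.sd
    residuals[~obj.unmasked] = np.nan
    return FitResult(
        model=model,
        chi2=best_chi2,
        residuals=residuals,
        n_data=obj.n_data,
        n_free=n_free,
        start_chi2s=tuple(start_chi2s),
        settings=settings,
        design=design,
        data=data,
    )


def profile_likelihood(
    fit: FitResult,
    param_id: str,
    grid,
    alpha: float = 0.05,
    n_starts: int = 1,
) -> ProfileCurve:
    """Profile one parameter: fix it at each grid value, re-optimise the rest.

    Each grid point warm-starts from the previous point's optimum (continuity
    of the profile); the 95% df=1 threshold chi2_min + 3.84 (recomputed for a
    different ``alpha``) marks the confidence region.
    """
    ids = param_ids(fit.model.network)
    if param_id not in ids:
        raise ValueError(f"unknown parameter {param_id!r}")
    if param_id in fit.settings.fixed_params:
        raise ValueError(f"{param_id!r} is fixed, not a free parameter")
    lo, hi = _bounds(fit.model.network, fit.settings)
    pos = ids.index(param_id)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < lo[pos]) or np.any(grid > hi[pos]):
        raise ValueError(f"grid outside parameter range [{lo[pos]}, {hi[pos]}]")
    chi2_vals = np.empty_like(grid)
    warm = fit.model.params
    base = FitSettings(
        n_starts=n_starts,
        r_range=fit.settings.r_range,
        stim_range=fit.settings.stim_range,
        inhib_range=fit.settings.inhib_range,
        seed=fit.settings.seed,
        max_iter=fit.settings.max_iter,
        tol=fit.settings.tol,
    )
    for k, value in enumerate(grid):
        fixed = dict(fit.settings.fixed_params)
        fixed[param_id] = float(value)
        settings_k = FitSettings(**{**base.__dict__, "fixed_params": fixed})
        sub = fit_model(fit.model.network, fit.data, fit.design, settings_k,
                        warm_starts=[warm])
        chi2_vals[k] = sub.chi2
        warm = sub.model.params
    threshold = fit.chi2 + float(chi2_dist.ppf(1.0 - alpha, df=1))
    return ProfileCurve(param_id=param_id, grid=grid, chi2=chi2_vals,
                        chi2_min=fit.chi2, threshold=threshold)
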