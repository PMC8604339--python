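"""Phenotype arm: growth rates, sigmoid IC50 fits and Bliss synergy.

Growth rates come from an ordinary least-squares fit of log confluency
against time (exponential growth assumption), normalised to the average DMSO
control rate of the same plate.  Dose-response curves are summarised by the
two-parameter sigmoid

    V(C) = 1 / (1 + exp(S * (IC50 - log C)))

with V the relative growth, C the concentration, IC50 the log-concentration
of half-maximal effect (the curve passes 0.5 at C = exp(IC50) regardless of
the slope S; S < 0 for an inhibitor).  Drug-combination grids are scored
against Bliss independence, E_AB = E_A + E_B - E_A*E_B, on growth-inhibition
fractions thresholded to [0, 1] (0 = growth as fast as control, 1 = no growth
or cell death).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ConfluencyTrace",
    "DoseResponseFit",
    "DoseMatrix",
    "SynergyResult",
    "growth_rate",
    "relative_growth",
    "sigmoid",
    "fit_ic50",
    "bliss_synergy",
]


@dataclass(frozen=True)
class ConfluencyTrace:
    """Confluency (% area) time series for one well/condition."""

    time_h: np.ndarray
    confluency: np.ndarray
    label: str = ""
    drug: str = ""
    dose_uM: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        c = np.asarray(self.confluency, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "confluency", c)
        if t.shape != c.shape:
            raise ValueError("time and confluency lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")


@dataclass(frozen=True)
class DoseResponseFit:
    """Sigmoid dose-response fit.

    ``ic50`` is on the natural-log concentration scale; ``ic50_uM`` the
    corresponding concentration.  ``out_of_range`` flags curves whose
    measured relative growths never cross the informative band (all > 0.9 or
    all < 0.1), for which ``ic50`` is a boundary estimate only (reported as
    "IC50 outside tested range", e.g. resistant lines with IC50 > 10 uM).
    """

    ic50: float
    slope: float
    doses: np.ndarray
    v: np.ndarray
    residual: float
    out_of_range: bool = False
    log_base: str = "natural"  # metadata: dose axis is log_e internally

    @property
    def ic50_uM(self) -> float:
        return float(np.exp(self.ic50))

    def predict(self, doses) -> np.ndarray:
        return sigmoid(np.asarray(doses, dtype=float), self.ic50, self.slope)


@dataclass(frozen=True)
class DoseMatrix:
    """Growth-inhibition fractions on a (doseA x doseB) grid, with marginals.

    ``inhibition[i, j]`` is 1 - relative growth at (doses_a[i], doses_b[j]),
    clipped to [0, 1]; index 0 of each axis must be dose 0 so that the row
    ``inhibition[:, 0]`` and column ``inhibition[0, :]`` are the single-drug
    marginals.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.doses_a, dtype=float)
        b = np.asarray(self.doses_b, dtype=float)
        inh = np.asarray(self.inhibition, dtype=float)
        object.__setattr__(self, "doses_a", a)
        object.__setattr__(self, "doses_b", b)
        object.__setattr__(self, "inhibition", inh)
        if inh.shape != (a.size, b.size):
            raise ValueError("inhibition grid does not match dose axes")
        if a[0] != 0 or b[0] != 0:
            raise ValueError("dose axes must start at 0 (marginals)")
        if np.any(inh < 0) or np.any(inh > 1):
            raise ValueError("inhibition outside [0, 1]; clip before scoring")


@dataclass(frozen=True)
class SynergyResult:
    """Bliss excess per grid cell and its mean over the combination cells."""

    excess: np.ndarray
    score: float  # mean excess x 100, percentage points


def growth_rate(trace: ConfluencyTrace) -> float:
    """Exponential growth rate (1/h): OLS slope of ln(confluency) vs time."""
    if trace.time_h.size < 3:
        raise ValueError("need at least 3 time points for a growth rate")
    if np.any(trace.confluency <= 0):
        raise ValueError("confluency must be > 0 for the log transform")
    slope = np.polyfit(trace.time_h, np.log(trace.confluency), 1)[0]
    return float(slope)


def relative_growth(rate: float, dmso_rate: float, clip: bool = False) -> float:
    """Growth rate relative to the DMSO control; optionally clipped to [0, 1]."""
    if dmso_rate <= 0:
        raise ValueError(f"DMSO control rate must be > 0, got {dmso_rate}")
    v = rate / dmso_rate
    if clip:
        v = min(max(v, 0.0), 1.0)
    return float(v)


def sigmoid(doses: np.ndarray, ic50: float, slope: float) -> np.ndarray:
    """V(C) = 1 / (1 + exp(slope * (ic50 - log C)))."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(slope * (ic50 - np.log(doses))))


def fit_ic50(doses, v) -> DoseResponseFit:
    """Least-squares sigmoid fit of relative growth against concentration.

    ``doses`` are concentrations (> 0, typically 0.1, 1, 10, 100 uM); ``v``
    the matching relative growths.  When the data never cross the informative
    band the IC50 is not determined by the tested range: the fit is flagged
    ``out_of_range`` with a boundary estimate (max dose for flat-resistant
    curves, min dose for flat-sensitive ones).
    """
    doses = np.asarray(doses, dtype=float)
    v = np.asarray(v, dtype=float)
    if doses.size < 4:
        raise ValueError("need at least 4 dose levels")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if doses.shape != v.shape:
        raise ValueError("doses and v lengths differ")
    if np.all(v > 0.9):
        return DoseResponseFit(
            ic50=float(np.log(doses.max())), slope=0.0, doses=doses, v=v,
            residual=float(np.sum((v - 1.0) ** 2)), out_of_range=True)
    if np.all(v < 0.1):
        return DoseResponseFit(
            ic50=float(np.log(doses.min())), slope=0.0, doses=doses, v=v,
            residual=float(np.sum(v ** 2)), out_of_range=True)
    log_doses = np.log(doses)
    # midpoint guess: dose where V crosses 0.5
    order = np.argsort(log_doses)
    guess_ic50 = float(np.interp(0.5, v[order][::-1], log_doses[order][::-1]))
    best = None
    for slope0 in (-2.0, -0.5, -5.0):
        try:
            with warnings.catch_warnings():
                # exact fits make the covariance singular; we only need popt
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    sigmoid, doses, v, p0=(guess_ic50, slope0), maxfev=10000)
        except RuntimeError:
            continue
        resid = float(np.sum((sigmoid(doses, *popt) - v) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("sigmoid fit did not converge from any start")
    (ic50, slope), resid = best
    return DoseResponseFit(ic50=float(ic50), slope=float(slope), doses=doses,
                           v=v, residual=resid)


def bliss_synergy(matrix: DoseMatrix) -> SynergyResult:
    """Bliss excess over the independence expectation for a dose grid.

    Expected combined inhibition per cell is E_A + E_B - E_A*E_B from the
    single-drug marginals; excess = observed - expected.  The summary score is
    the mean excess over the true combination cells (both doses > 0), in
    percentage points (x100).  Positive scores indicate synergy.
    """
    e_a = matrix.inhibition[:, 0][:, None]
    e_b = matrix.inhibition[0, :][None, :]
    expected = e_a + e_b - e_a * e_b
    excess = matrix.inhibition - expected
    combo = excess[1:, 1:]
    score = float(np.mean(combo) * 100.0) if combo.size else 0.0
    return SynergyResult(excess=excess, score=score)
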