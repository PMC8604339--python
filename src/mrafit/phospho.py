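"""Phosphoproteomics scoring: TMT normalisation, synergy contrasts and KSEA.

The TMT workflow carries a 16th reference channel composed of a superset of
all samples; reporting intensities are divided row-wise by that reference,
log2-transformed, median-centred per sample and scaled by the per-sample
median absolute deviation.  Synergy contrasts quantify deviation of a
combination treatment from additivity of the single treatments on the log
scale.  Kinase-substrate enrichment (KSEA) aggregates site-level scores to
kinase activities using annotation sets (e.g. PhosphoSitePlus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

logger = logging.getLogger(__name__)

__all__ = [
    "PhosphoMatrix",
    "KinaseSubstrateSets",
    "KseaResult",
    "normalise_tmt",
    "synergy_contrast",
    "ksea",
]


@dataclass(frozen=True)
class PhosphoMatrix:
    """Phosphosite x sample matrix with sample annotation.

    ``data`` holds raw reporter intensities (before :func:`normalise_tmt`) or
    normalised scores (after).  ``annotation`` maps sample -> treatment label;
    ``reference`` names the reference channel column for raw intensities.
    """

    data: pd.DataFrame
    annotation: dict[str, str] = field(default_factory=dict)
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.annotation:
            missing = [c for c in self.data.columns if c not in self.annotation
                       and c != self.reference]
            if missing:
                raise ValueError(f"samples without annotation: {missing}")


@dataclass(frozen=True)
class KinaseSubstrateSets:
    """Kinase -> set of phosphosite ids (GENE_residuePosition)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        empty = [k for k, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty substrate sets: {empty}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "KinaseSubstrateSets":
        """Build from a two-column (kinase, site) table."""
        kin_col, site_col = frame.columns[:2]
        grouped = frame.groupby(kin_col)[site_col].agg(frozenset)
        return cls(sets={str(k): v for k, v in grouped.items()})


@dataclass(frozen=True)
class KseaResult:
    """Kinase -> (enrichment score, substrate count used)."""

    scores: dict[str, tuple[float, int]]

    def top(self, n: int = 10) -> list[tuple[str, float, int]]:
        ranked = sorted(self.scores.items(), key=lambda kv: -abs(kv[1][0]))
        return [(k, s, m) for k, (s, m) in ranked[:n]]


def normalise_tmt(matrix: PhosphoMatrix) -> PhosphoMatrix:
    """Reference-channel ratio, log2, median-centring and MAD scaling.

    Rows with a non-positive reference intensity cannot form a ratio and are
    dropped (count logged).  The result is location/scale standardised per
    sample: median 0, MAD 1.
    """
    if matrix.reference is None or matrix.reference not in matrix.data.columns:
        raise ValueError("reference channel missing from matrix")
    data = matrix.data
    ref = data[matrix.reference]
    keep = ref > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("normalise_tmt: dropped %d rows with non-positive "
                    "reference intensity", dropped)
    data = data.loc[keep]
    samples = [c for c in data.columns if c != matrix.reference]
    ratio = np.log2(data[samples].div(data[matrix.reference], axis=0))
    centred = ratio - ratio.median(axis=0)
    mad = centred.apply(lambda col: median_abs_deviation(col, nan_policy="omit"))
    # a column identical to the reference is exactly zero after centring:
    # leave it as zeros rather than dividing 0/0
    degenerate = (mad == 0) & (centred.abs().max(axis=0) < 1e-12)
    if np.any((mad == 0) & ~degenerate):
        bad = list(mad.index[(mad == 0) & ~degenerate])
        raise ValueError(f"zero MAD in sample column(s) {bad}; cannot scale")
    normalised = centred / mad.where(mad > 0, 1.0)
    return PhosphoMatrix(data=normalised, annotation=dict(matrix.annotation),
                         reference=None)


def synergy_contrast(lfc_a: pd.Series, lfc_b: pd.Series,
                     lfc_ab: pd.Series) -> pd.Series:
    """Deviation of a combination from treatment additivity, per site.

    deviation = lfc_AB - (lfc_A + lfc_B).  Negative values are synergistic
    down-regulation, positive values synergistic up-regulation.  Significance
    calling on the deviations is delegated to standard differential tooling.
    """
    ids_a, ids_b, ids_ab = set(lfc_a.index), set(lfc_b.index), set(lfc_ab.index)
    if not (ids_a == ids_b == ids_ab):
        diff = ids_a ^ ids_b | ids_a ^ ids_ab
        raise ValueError(f"site ids differ between inputs: {sorted(diff)[:10]}")
    return lfc_ab - (lfc_a.reindex(lfc_ab.index) + lfc_b.reindex(lfc_ab.index))


def ksea(
    site_scores: pd.Series,
    sets: KinaseSubstrateSets,
    min_size: int = 3,
    mode: str = "zscore",
) -> KseaResult:
    """Kinase-substrate enrichment scores from one column of site scores.

    Sites are first z-scored against the whole column.  The default
    ``"zscore"`` mode scores each kinase as mean(z of substrates) * sqrt(m)
    (a z-test statistic: under the null of no enrichment it is ~N(0, 1) for
    any substrate count m).  ``"ratio"`` mode instead reports the literal
    ratio mean(z of substrates) / mean(|z| overall).  Substrate ids absent
    from the matrix are dropped (logged); kinases left with fewer than
    ``min_size`` substrates are omitted.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if mode not in ("zscore", "ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    x = site_scores.astype(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("site scores must be finite")
    sd = float(x.std(ddof=0))
    if sd == 0:
        raise ValueError("zero variance in site scores")
    z = (x - float(x.mean())) / sd
    mean_abs_z = float(np.abs(z).mean())
    scores: dict[str, tuple[float, int]] = {}
    for kinase, substrates in sets.sets.items():
        present = [s for s in substrates if s in z.index]
        missing = len(substrates) - len(present)
        if missing:
            logger.debug("ksea: kinase %s missing %d substrate(s)",
                         kinase, missing)
        m = len(present)
        if m < min_size:
            continue
        mean_z = float(z.loc[present].mean())
        if mode == "zscore":
            score = mean_z * np.sqrt(m)
        else:
            score = mean_z / mean_abs_z
        scores[kinase] = (float(score), m)
    return KseaResult(scores=scores)
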