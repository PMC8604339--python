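# Methods

## Steady-state response model

The package models a signalling network as a directed graph whose nodes are
receptors and kinases and whose edges carry local response coefficients
r̃ (dimensionless, log2-FC per log2-FC). At pseudo-steady state and under a
locally linear approximation, the global response *a* (log2 fold-change of
each node's phosphorylation relative to the unperturbed BSA+DMSO control)
satisfies

    a = r (a + d) + u,    solved as    a = (I − r)⁻¹ (r d + u),

with `r[target, source]` nonzero exactly on the network's edges (zero
diagonal — equivalent to the classical MRA convention of a −1 diagonal on
I − r), `u` the sum of stimulus strengths of active ligands on their
receptors (one parameter per (receptor, ligand) pair, ≥ 0; a ligand such as
IGF1 hitting both IGF1R and IGF2R gets two independent parameters), and `d`
the inhibitor strengths on inhibited nodes (≤ 0).

**Dual-effect inhibitors.** An inhibitor enters only through `d`: every node
downstream of the target sees the target's activity plus ι, while the
target's own measured phosphosite is driven purely by its upstream inputs.
Consequences worth spelling out, because they carry the biology:

* With a negative feedback looping around the inhibited node (ERK→RAF around
  MEK), inhibition *raises* the measured phosphorylation of the target
  (feedback relief) while lowering its downstream node — the pMEK-up /
  pERK-down signature of MEK inhibition in resistant lines.
* An inhibitor whose drug acts upstream of the measured phosphosite (the
  AKT inhibitor MK2206 blocks AKT's own activating phosphorylation) does not
  fit this convention; such inhibitors are declared `upstream_acting` and
  the (condition, target-readout) cells are masked out of every objective.
  Masking is data preparation, not likelihood weighting: masked cells are
  simply absent.
* An ERK inhibitor is a negative term on ERK's *transmitted* activity only.
  It never directly lowers the measured pERK. When the ERK→RAF feedback
  edge exists, the ERKi term propagates through it (with a negative
  coefficient), so adding ERKi to MEKi does not suppress — and can even
  increase — the feedback-driven pMEK rise, whereas RAF co-inhibition
  strictly suppresses it. This asymmetry is the model's case for vertical
  inhibition at RAF rather than ERK.

Units are log2 fold-changes throughout; the linear algebra is base-agnostic
but log2 matches the measurement convention. Simulation refuses to return
non-finite values: a singular or ill-conditioned (I − r) (condition number
above 1e12) raises an error reporting the spectral radius of r.

## Fitting

The objective is the weighted sum of squared residuals
χ² = Σ ((data − sim)/sd)² over unmasked cells, the maximum-likelihood
objective under independent Gaussian noise. Its calibration yardstick: a
model that explains all the data has E[χ²] equal to the number of data
points.

* **Weights.** Datasets store replicate means; the weighting sd is the
  standard error of that mean. Empirical replicate scatter is floored at
  0.1 log2 units (before the 1/√n factor) so that lucky duplicate agreement
  cannot produce near-infinite weights. For calibration studies the known
  generative noise can be stored instead (`sd_mode="known"`).
* **Global search.** A seeded Latin hypercube (scipy.stats.qmc) draws
  `n_starts` initial vectors inside the parameter box (defaults: r ∈ [−5, 5],
  stim ∈ [0, 5], inhib ∈ [−5, 0], covering the magnitudes such data support
  while keeping I − r typically invertible); each start is refined by
  scipy's bounded trust-region-reflective least squares; the best χ² wins.
  Starts that land on a singular (I − r) are discarded, not redrawn, so a
  seed fully determines the fit. Optimiser tolerances default to 1e-8 —
  tighter values only crawl along non-identifiable ridges.
* **Identifiability.** Several parameter combinations are structurally
  confounded: a stimulus strength with the receptor's outgoing coefficient,
  and an inhibitor strength with the link directly downstream of its target.
  Profile likelihood (fix one parameter on a grid, re-optimise the rest,
  warm-starting each grid point from its neighbour; 95% df=1 threshold
  χ²min + 3.84) makes these ridges visible. Fits remain well-defined — the
  identifiable quantities are path products, and tests assert recovery of
  those rather than of raw coefficients.

## Model selection

Nested models differing by one edge are compared by the likelihood-ratio
test: Δχ² referred to χ²(df = 1); negative Δχ² from numerical noise is
clamped to zero.

* **Extension** is greedy hill climbing: every absent non-self-loop ordered
  pair (edges *into* receptors included — receptor-mediated feedbacks are
  the interesting discoveries; ligands are perturbations, not nodes, and are
  never candidates) is added singly and refitted (warm-started from the
  incumbent plus a small Latin-hypercube batch for the new coefficient); the
  largest Δχ² wins its round if p < α, and rounds repeat until nothing
  passes. α defaults to 0.05 per test with no multiplicity correction; a
  Bonferroni switch (α / candidate count per round) is available and is the
  right choice when the candidate universe is large — at α = 0.05 with ~12
  candidates the per-round family false-accept rate is ≈ 0.4.
* **Reduction** mirrors extension: each present edge is removed singly, the
  cheapest removal is made if non-significant, and a retain-policy set
  (e.g. the shared literature core) is kept regardless so that per-model
  parameters stay comparable across a panel.
* **Harmonisation** fixes every inhibitor strength to its arithmetic mean
  across models and refits each model with those values frozen. Because the
  inhibitor/downstream-link confounding is a ridge, refits recover almost
  all of the fit quality; the χ² cost of pinning an identifiable inhibitor
  parameter is O(1) per model, i.e. well under 5% at the study's ~235
  unmasked points per cell line (but proportionally large on toy designs —
  a property of the statistics, not of the implementation).

**A structural caveat of the linear contract.** Superposition makes
perturbation effects additive and condition-independent, so distinct edges
that connect the same two branches (S6K→IGF1R, S6K→RAF, mTOR→RAF, …) can
produce identical fits; which member of such an equivalence class a greedy
search names is then decided by noise. Recovering a *specific* planted edge
is only a meaningful test on designs where that edge is uniquely
identifiable; otherwise the meaningful statement is that the search closes
the right loop. Likewise, a feedback onto a receptor is invisible to
inhibitors that act only on the downstream cascade: detecting S6K→IGF1R
requires a perturbation upstream of S6K in the design. The bundled focused
design therefore crosses {control, EGF, IGF1} with {control, MEKi, mTORi} —
an mTOR inhibitor, present in the full factorial panel, is what closes the
loop S6K→IGF1R→RAF→MEK for the likelihood-ratio test.

## Synthetic data: what the generators emulate

`mrafit.synthetic` defines the study conditions under which everything is
validated:

* **Designs.** The full factorial design crosses 4 ligands (EGF, PDGF, NGF,
  IGF1) + BSA control with 7 inhibitors (PI3Ki, MEKi, AKTi, mTORi, RAFi,
  ASK1i, ALKi) + DMSO control over 6 readouts (pMEK, p-p38, pERK, p-cJUN,
  pAKT, pS6K): 240 cells per cell line, of which the 5 (AKTi condition,
  pAKT) cells are masked. The focused design is the 3 × 3 × 6 grid above.
* **Virtual cell lines.** A profile scales stimulus strengths by receptor
  expression, multiplies the two feedback base strengths (ERK→RAF base −0.5;
  S6K→IGF1R base −1.0, absent when its multiplier is 0), and optionally
  applies NRAS-mutant-like rerouting (receptor→RAF couplings × 0.5,
  receptor→PI3K × 1.5 — declared defaults encoding weaker MAPK and slightly
  stronger PI3K inducibility, not fitted values). The default six-line panel
  spans ERK→RAF multipliers (1, 1, 1, 2, 3.5, 3.5) — the resistant-like end
  carries the 3.5× feedback — with the strongest line also carrying the
  receptor feedback, and two NRAS-mutant-like members among the weak-feedback
  lines.
* **Noise.** Gaussian with SD 0.2 log2 units per replicate, 2 replicates by
  default — a declared fixture constant for typical bead-ELISA replicate
  scatter. Generators are pure functions of their arguments including the
  seed.
* **Phenotype and phospho fixtures.** Confluency traces are exponential
  growth at rate × V(dose) sampled 72 h every 2 h with multiplicative
  log-normal noise; phospho site-score columns are Gaussian background with
  substrate sets shifted by planted kinase activities (overlapping sets sum
  their shifts). A synthetic nine-line IC50 panel (six resistant lines above
  10 μM, three sensitive in the 10–100 nM range) stands in for measured
  drug-sensitivity tables; it is constructed, not measured, and is labelled
  synthetic at its definition.

What passing tests on these generators shows: the estimator, the LRT
machinery, and the scoring arms behave correctly when the model class is
true and noise is Gaussian and independent. What it does not show: robustness
to the saturation, plate effects, non-Gaussian outliers and time-dependence
of real perturbation data, none of which the generators emulate, nor
correctness of any specific biological network.

## Drug response

Growth rate is the OLS slope of ln(confluency) against time (needs ≥3
points, positive confluency; invariant to confluency rescaling). Relative
growth divides by the plate's DMSO control rate, clipped to [0, 1] only at
the synergy-input stage (0 = no growth or death, 1 = control growth);
negative rates (cell death) are preserved internally. The dose-response
sigmoid is V(C) = 1/(1 + exp(S·(IC50 − log C))): the only parenthesisation
of the two-parameter logistic for which V = 0.5 at C = exp(IC50) regardless
of the slope. Concentrations are handled on the natural-log scale internally
and reported in μM; the output records this, since fits published elsewhere
may use log10. Curves whose measured relative growths never cross (0.1, 0.9)
carry no IC50 information within the tested range and are flagged
out-of-range with a boundary estimate, as with highly resistant lines
(IC50 > 10 μM at a 0.1–100 μM ladder). Bliss scoring takes a dose grid of
growth-inhibition fractions with single-drug marginals, computes the
independence expectation E_A + E_B − E_A·E_B per cell, and reports per-cell
excess plus the unweighted mean excess over combination cells × 100
(percentage points; positive = synergy).

## Phospho scoring

TMT normalisation divides each sample column row-wise by the 16th
(reference) channel — rows with non-positive reference are dropped and
counted — then log2-transforms, median-centres per column and scales by the
per-column median absolute deviation (plain MAD, so the output has median 0
and MAD 1; a column identical to the reference is left at zero rather than
dividing 0/0). Synergy contrasts are lfc_AB − (lfc_A + lfc_B) per site;
significance calling is deliberately left to standard differential tooling.
KSEA z-scores the site column and scores each kinase as
mean(z of substrates) · √m — the z-test statistic, ~N(0, 1) under the null
for any substrate count m — with kinases under `min_size` (default 3,
since one or two substrates carry no statistical weight) omitted and absent
substrate ids dropped with logging. A literal "ratio" variant,
mean(z of substrates) / mean |z|, is available behind a flag; the z-test
form is the default and the two agree in sign.

## Problem sizes of the bundled studies

The reference studies run at: 20 focused datasets (54 cells, 16–17 free
parameters, 8 multistarts per fit) for the planted-feedback LRT study; 100
full-factorial datasets (true-model evaluation only, no refitting) for the
χ² calibration study; and one 9 × 5-dose confluency panel for the
drug-sensitivity study. These sizes were chosen as the point where the
Monte-Carlo standard errors are small against the assertions being made.

## Known limitations

* Steady-state linearisation only: no kinetics, no saturation, no
  time-course; superposition is exact by construction, and with it the
  structural equivalences and non-identifiabilities described above.
* Single-perturbation inhibition semantics cannot represent drugs whose
  measured site is downstream of the drug's action point differently from
  the annotated-target convention; upstream-acting drugs are handled by
  masking, not modelling.
* No uncertainty quantification beyond profile likelihood (no bootstrap or
  posterior sampling).
* Bliss is the only synergy score; Loewe additivity is out of scope.
* Differential-expression calling (moderated t-tests, FDR) is out of scope;
  the phospho arm produces the quantities such tools consume.
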