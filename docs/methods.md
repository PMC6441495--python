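# Methods

## The model

`mtorstress` implements a dynamic model of how acute oxidative stress
(arsenite exposure at t = 0) signals through the PI3K/Akt axis to
mTORC1. Nine proteins are tracked — IR-β, IRS1, PI3K, PDK1, Akt, TSC2,
PRAS40, p70-S6K and 4E-BP1 — resolved into 25 phosphorylation and
localisation states. Each protein forms a conserved pool: states
interconvert by irreversible first-order mass-action reactions, so the
summed concentration of a pool is constant along every trajectory (this
holds exactly, by construction of the stoichiometry, and to integrator
tolerance numerically).

Kinase and complex activities are dimensionless fractional occupancies:

* `A_PI3K = [PI3K_p]/C_PI3K`, `A_PDK1 = [PDK1_mem]/C_PDK1`,
  `A_IR = [IR_beta_pY1146]/C_IR`, `A_IRS1 = [IRS1_loc]/C_IRS1`
* `A_Akt = ([Akt_pT308] + s·[Akt_pS473] + 2·[Akt_pT308_pS473])/C_Akt` —
  the phosphosites contribute additively, the doubly phosphorylated form
  counts twice; the switch `s` is 1 in variants I–III and 0 in IV–V,
  encoding whether S473 phosphorylation alone carries Akt activity
  toward mTORC1 substrates.
* `A_mTORC2 = A_PI3K`: mTORC2 is implicit and driven by PI3K.
* `A_mTORC1 = (k_aa·u_aa + k_stress_mTORC1·u_stress)·
  (1 − [TSC2]/C_TSC2)·(1 − [PRAS40]/C_PRAS40)`: mTORC1 is implicit;
  amino acids provide a constant basal drive, the stress term exists
  only in variant V, and the two endogenous inhibitors act
  multiplicatively with an efficiency proportional to the inhibitor's
  unphosphorylated fraction (full inhibition when the inhibitor equals
  its pool total). Only fully unphosphorylated TSC2 and PRAS40 inhibit:
  phosphorylation at any site is an inhibition-relief event.
* `A_S6K` counts only T389-containing p70-S6K species.

Each conversion's flux is `k · multiplicity · [substrate] · activity`,
plus an additive stress term `k_stress · u_stress(t) · [substrate]` on
reactions that carry a stress input. The six second-phosphorylation
steps of Akt, PRAS40 and p70-S6K run at twice the rate constant of the
matching first phosphorylation (one shared parameter per site pair);
dephosphorylation of a site uses one shared rate constant regardless of
the other site's state.

Drugs follow a Boolean-like scheme, active only while present:
wortmannin zeroes the entire PI3K activation flux (all terms, including
the stress input); MK-2206 multiplies every `A_Akt`-driven flux by
(1 − 0.83), the fixed partial-inhibition extent derived from slope
ratios of TSC2-pT1462 induction (see below).

Inputs: `u_stress` is a unit step at t = 0 in stressed conditions;
`u_aa = 1` throughout (cells kept in full medium); insulin is 0
throughout (overnight serum starvation). The IR/IRS1 arm is retained
structurally — it carries the p70-S6K → IRS1-pS636 feedback readout and
the IRS1-mediated PI3K activation route — but receives no insulin
drive; `A_IRS1` is a one-name extension of the activity set, added so
PI3K has a defined basal activation route.

Units: minutes; arbitrary concentration units (immunoblot data are
relative); rate constants per minute.

## Variants

| tag | stress on PI3K | stress on Akt→pS473 | stress on mTORC1 | S473 alone activates |
|-----|----|----|----|----|
| I   | –  | –  | –  | yes |
| II  | ✓  | –  | –  | yes |
| III | ✓  | ✓  | –  | yes |
| IV  | ✓  | ✓  | –  | no  |
| V   | ✓  | ✓  | ✓  | no  |

The reaction set is identical across variants; only stress-term
attachments and the `s` switch differ. With all stress strengths set to
zero, variant V's right-hand side coincides with variant I's on any
state without Akt-pS473 (where the variants' Akt-activity formulas
agree); variants III and IV coincide on such states as well.

## Free-parameter decomposition (91 parameters)

The three-condition calibration problem (arsenite, arsenite +
wortmannin, arsenite + MK-2206) for variant V has 91 free parameters:

* 26 kinetic rate constants (27 minus the insulin input strength, which
  is fixed because the insulin drive is identically zero);
* 3 stress-input strengths (PI3K, Akt-S473, mTORC1);
* 62 condition-specific initial concentrations: 21 each for the
  arsenite and MK-2206 conditions (25 species minus the three
  double-phosphos pinned to 0 at baseline and minus IR-β-pY1146, zero
  under starvation) and 20 for the wortmannin condition (additionally
  PI3K_p = 0 after the 30-min pre-inhibition; the Akt-pT308 initial is
  replaced one-for-one by a fraction parameter multiplying the arsenite
  condition's value, reflecting reduced T308 phosphorylation after
  PI3K inhibition).

Bounds (log10): generic parameters [−5, 3]; mass-action rates [−5, 1];
PI3K-activation rates [−5, −2] (preventing step-like activation of the
unobserved PI3K species); initial concentrations [−5, 1]; the
wortmannin fraction [−5, 0].

## Synthetic data generator

The generator emulates quantified immunoblot time courses: 9 readouts
(each the summed concentration of all species carrying the probed
phosphosite), 6 time points over 0–60 min (0, 2.5, 5, 15, 30, 60 — a
representative grid with a dense early response),
3 conditions, default 4 replicates. Each replicate multiplies the
simulated readout trajectories by i.i.d. mean-one log-normal factors
with CV 0.2 (immunoblot intensities are positive and roughly
scale-proportional; 20% is a typical replicate CV for quantified blots;
additive Gaussian noise is available behind a flag) and is then
normalised to the average of its own readout across the time course,
mirroring per-membrane normalisation of band intensities. Means and
SEMs are taken across replicates.

The pinned ground-truth parameter regime (module `groundtruth`) was
chosen once so that (a) arsenite induces ≥2-fold rises in Akt-pT308,
Akt-pS473, TSC2-pT1462 and p70-S6K-pT389 by 30–60 min, (b) under
wortmannin, Akt-pS473 and p70-S6K-pT389 remain stress-inducible at
reduced amplitude while Akt-pT308 induction is abolished, and (c) the
initial state is near the no-stress fixed point of the kinetics (each
phosphorylation cycle balanced at basal activities), so serum-starved
cells are at baseline. The wortmannin-condition initials are the frozen
endpoint of a 30-min pre-inhibition integration (fraction ≈ 0.496 for
Akt-pT308, PI3K_p cleared).

What the generator does **not** emulate: densitometry and image
processing, loading-control correction, readout-specific replicate
counts, non-stationary baselines, or biological variation in the
kinetics themselves. Passing recovery tests therefore show that the
calibration machinery is correct and well-conditioned under the model's
own assumptions, not that the model is identifiable from any particular
real dataset.

Two artificial constructions mirror the calibration devices: constant
no-stress companion datasets (every record frozen at its t = 0 value,
penalising spurious dynamics in the absence of stress) and the
wortmannin residual dataset (Akt-pS473, p70-S6K-pT389, 4E-BP1-pT37/46,
PRAS40-pS183 under wortmannin, tagged for constraining the non-PI3K
stress inputs).

## Objective and normalisation

χ² is the weighted sum of squared residuals over all fitted means with
σ = max(SEM, 0.05): the floor guards zero-SEM points (noise-free or
single-replicate data); the error model (SEM rather than SD) matches
data reported as mean ± SEM. Simulated readouts are normalised per
(condition, readout) by their own time-course mean before comparison,
the same transformation the data undergo; no-stress companions are
scaled with their parent condition's constant, since companion records
live on the parent's normalised scale. No per-observable scale or
offset parameters exist — condition-specific initials absorb scale.
Failed integrations return a penalty χ² of 1e12 and flag the start
rather than aborting the multistart.

## Optimisation

Latin-hypercube multistart (stratified per dimension, seeded,
reproducible) in log10 space, each start refined by SciPy's
trust-region-reflective bound-constrained least squares with
finite-difference gradients. All starts are retained and sorted; failed
starts keep the penalty value so cluster filtering sees the full
multistart distribution. The reference scale for this procedure is
500 starts; desk-scale runs in the tests and the
acceptance script use 2–10 starts with most parameters pinned at the
generating values (see "Problem sizes" below).

## Model selection

χ²-based criteria: AIC = χ² + 2k, AICc = AIC + 2k(k+1)/(n−k−1)
(undefined for n ≤ k+1), BIC = χ² + k·ln n, where n counts fitted
means (including companion records) and is held identical across
compared models. χ² stands in for −2 log L up to an additive constant
shared by all models on the same data and weights, so rankings and
relative differences are unaffected — absolute values may be offset
from likelihood-based criteria by a data-dependent constant. A
candidate model is an improvement when it lowers the incumbent's AIC by
at least 5% (boundary inclusive).

The second-input search augments the single-input model with a stress
term on each of the 37 candidate conversions in turn, refits, and
tabulates the criteria, with per-candidate seeds derived from
(seed, candidate index) so the table is reproducible and independent of
evaluation order.

## Extent of inhibition

Ordinary least-squares slopes of mean intensity versus time over the
full 0–60 min course (the default induction window). If the treated
course shows no
significant change by one-way ANOVA across time points (computed from
summary statistics: group means, SEM-derived SDs, replicate counts;
α = 0.05), inhibition is complete (1.0) — the rule that classifies
wortmannin as a full inhibitor. Otherwise the extent is
1 − slope_treated/slope_control, clipped to [0, 1]; a non-positive
control slope is an error (no induction to compare against).

## Identifiability

Profile likelihood with Δχ² = 3.84 (95% pointwise, 1 d.o.f., the
method's standard threshold). Stepping is adaptive, targeting χ² increments of
~0.1·Δχ² per step (step halved on overshoot, grown ≤0.5 on flat
stretches), at most 50 steps per direction; re-optimisation failures
flag the point and the profile continues. A side that crosses
best + Δχ² before its bound is identifiable; bounded box ranges mean a
degenerate ridge often truncates on one side, so any non-crossing side
marks the parameter non-identifiable.

The iterative fixing loop: multistart fit → profile every free
parameter → fix all simultaneously identifiable parameters at their
optima, all at once within an iteration. If nothing is fixed, the multistart solutions are
filtered by two-cluster k-means on χ² (keeping the lower-mean cluster;
identical values degenerate to keeping all), and every parameter whose
retained sample distribution is unimodal is fixed at the mode of a
Gaussian KDE (Scott bandwidth, argmax on a 512-point grid within the
sample range). Unimodality is the explicit heuristic "≥80% of samples
within ±0.5 log10 units of the KDE mode" (boundary inclusive), making
precise the qualitative notion of optima ending nearly always in the
same value range. The loop terminates when no free parameters remain,
stalls when an iteration makes no progress (a legitimate terminal
state, reported not raised), or stops at 20 iterations. Every fixing is
recorded in a replayable ledger.

## Numerical choices

* Integrator: LSODA (stiff-capable), presentation tolerances
  rtol 1e−8 / atol 1e−10; fitting uses rtol 1e−6 / atol 1e−8 for speed.
* Negative concentrations in (−1e−8, 0) are clipped to zero; larger
  negativity is an integration error.
* Inhibition factors (1 − x/C) are clamped at zero so activities are
  non-negative for any admissible state.
* Pool totals enter activities as constants computed from the initial
  state (conservation makes them invariant along trajectories).

## Problem sizes

At reference scale the calibration runs 500-start fits over the full
91-parameter space per candidate — far beyond a single-CPU desk
budget. The test
suite and the acceptance script therefore run the discrimination
experiments with kinetics and initial concentrations pinned at the
generator's values and only the stress-input strengths (plus, where
noted, one or two kinetic rates) free, with 2–10 starts and capped
optimizer iterations. This preserves the logic being tested — which
candidate input explains the residual wortmannin signal, whether the 5%
rule accepts it, and the AIC ordering of the variant ladder — while
each search over all 37 candidates completes in well under a minute.
The reported recovery and ranking results are therefore statements
about the machinery at this documented scale; absolute criterion
values additionally depend on the particular quantified datasets
fitted.

## Known limitations

* The rate-law algebra is one concrete realisation of the qualitative
  scheme (mass action, fractional-occupancy modifiers, multiplicative
  concentration-dependent inhibition); other algebraic realisations of
  the same scheme exist. The deposited BioModels version of this
  network (accession MODEL1902140002) is the natural reference for
  reconciliation; the importer accepts only this package's own SBML
  dialect, so reconciling against that file requires mapping its
  species and rate laws onto this structure manually.
* The second-phosphorylation factor 2 is applied uniformly to Akt,
  PRAS40 and p70-S6K site pairs, although the AGC-kinase rationale
  strictly covers Akt and p70-S6K only; the exact factor has little
  effect on fit quality.
* No spatial compartments, cell-volume scaling, explicit mTORC1/mTORC2
  species, Rheb, Raptor, Rictor, MK2, p38 or RAS dynamics.
* No Bayesian posterior sampling; no global optimisation beyond LHS
  multistart; no structural (algebraic) identifiability analysis —
  only practical, profile-based identifiability.
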