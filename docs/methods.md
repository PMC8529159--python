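# Methods

This note documents the models implemented in `ifnsig`, the default
parameter choices and their rationale, the synthetic-data generator, the
numerical choices, and the limitations of what the test suite demonstrates.

## Equilibrium receptor model

The ternary complex IFN·IFNAR1·IFNAR2 assembles along two paths (ligand
binds IFNAR1 first or IFNAR2 first).  Because the cycle consumes no
metabolic energy, detailed balance ties the four dissociation constants:
K₁K₃ = K₂K₄.  `AffinitySet` enforces this at construction (relative
tolerance 1e−9), and all affinity perturbations move linked constants
together: an IFNAR1 binding-energy change scales K₁ and K₄ jointly, an
IFNAR2 change scales K₂ and K₃ (this is how R120A-like and M148A-like ligand
mutants are modelled).  USP18 priming is the one deliberate exception: it
multiplies only K₄ (the IFNAR1 off-rate from the ternary complex), because
USP18 acts on the intracellular side of IFNAR2 — it is a non-equilibrium
perturbation and is stored separately (`usp18_fold`), applied at evaluation
time.

The closed-form T(I) (see README) is evaluated in the conjugate form
T = (R_T/2)·c/(Ξ + √(Ξ²−c)), c = 1−(Δ/R_T)², which is exact and avoids the
catastrophic cancellation of Ξ − √(Ξ²−c) in the low- and high-dose limits.
An independent brute-force oracle (`ternary_complexes_numeric`) solves the
two conservation equations for the free subunit densities by bisection and
is used throughout the tests; the two agree to ~1e−14 relative.

`keff` has two routes.  The reference is numeric bisection of
T(I) = T_max/2 on the rising branch.  The `closed_form` route inverts the
same condition algebraically — the branch relation gives
Ξ_target = (τ² + c)/(2τ) with τ = T_max/R_T, and Ξ(I) = Ξ_target is a
quadratic in I whose smaller root (evaluated via the product form to avoid
cancellation) is K_eff.  This inversion is exact, so the two routes agree to
machine precision; the closed form falls back to the numeric route if
rounding drives its discriminant negative.

Degenerate inputs: I = 0 returns T = 0 without evaluating Ξ; a surface with
one subunit absent (Δ = ±R_T, hence c = 0) returns T = 0 rather than
erroring.

### The Michaelis–Menten approximation and the EC₅₀ formula

T ≈ T_max·I/(K_eff+I) is exact at I = K_eff and at the plateau but carries a
finite low-dose slope bias; across the physiological affinity grid the
relative deviation below I_m/10 stays under ~30%, and under ~13% for the
default ligands.  Consequently the closed-form
pSTAT EC₅₀ = K_eff/(1 + T_max·A/K_p), which is exact *given* the MM form, is
a ~0.1% approximation only deep in the MM regime (weak membrane recruitment,
K₂ ≪ K₁, EC₅₀ far below I_m) and a few-to-tens-of-percent approximation
elsewhere.  The tests pin both regimes.

## Units and constants

Solution concentrations in molar (doses reported in pM), surface densities
in molecules·µm⁻², per-cell copies = density × area, time in minutes.  The
energy-to-affinity conversions use a reference volume v = 1 M⁻¹ (≈1.66 nm³;
some sources quote ≈1.75 nm³ for the same conversion — the constant is
configurable and nothing downstream is sensitive to the 5% difference) and a
reference area a = 10 nm², a typical protein–protein contact footprint.
With the human-measured solution affinities (IFN-α2: K₁ = 3 µM, K₂ = 5 nM;
IFN-β: K₁ = 0.1 µM, K₂ = 0.3 nM) this places K₄ at 0.3 and 0.01
molecules·µm⁻² respectively, in the range seen in single-molecule
dimerization studies.

## Default cell and the K_p calibration

The reference cell is a 6.5 µm-radius B cell (large-cell gate: 8 µm) with
~1000 copies of each receptor subunit, log-normal heterogeneity with natural
log SD 0.5, total STAT at 0.7 nM (485 copies in the 450 µm² reference
geometry), and K_p = 900 copies.  K_p is the one constant not taken from a
direct measurement: it is set so that T_max·A and K_p are comparable.  In
that intermediate regime the equilibrium model predicts a ~15% lower
saturating pSTAT for the weaker IFNAR1 binder while the measured B-cell gap
remains small — the consistency condition the flow-cytometry observations
impose.  In the limits the fold-change formula makes this transparent:
K_p/A large → the full T_max ratio appears in pSTAT_max; K_p/A small → the
gap vanishes despite different T_max.

## Kinetic network

Thirteen species (free/bound/blocked/internalized receptor states, STAT,
pSTAT, SOCS1), nineteen mass-action reactions, ligand clamped as a bath.
Design choices where the biology is aggregated:

* SOCS1 is produced first-order in pSTAT and decays first-order; it binds
  any IFNAR1-containing surface species, and a SOCS-bound ternary complex
  does not phosphorylate STAT.
* Induced internalization acts on the (unblocked) ternary complex only,
  dismantling it: the ligand is degraded, both subunits enter internal
  pools; recycling returns them at ligand-specific rates.  Whether binary
  complexes also internalize is unknown; the default is ternary-only.
* Membrane association rates are equal for both recruitment paths
  (k_a3 = k_a4 = 10 µm² min⁻¹); dissociation rates follow from K₃, K₄.
* The effective solution on-rate is 2×10⁹ M⁻¹min⁻¹ (~3×10⁷ M⁻¹s⁻¹),
  faster than a bare 3-D protein k_on to account for membrane-enhanced
  capture; at pM doses, absolute ligand capture is the rate-limiting step
  for approaching receptor-occupancy equilibrium, so this constant sets the
  low-dose equilibration timescale.
* Dephosphorylation at 0.3 min⁻¹ and k_p⁺ = k_p⁻/K_p make the pSTAT layer
  equilibrate within minutes and reduce exactly to the equilibrium formula
  at steady state with feedbacks off (the cross-module consistency test).
* Feedback rates are fitted-scale placeholders chosen to reproduce the
  reported phenomenology: IFN-β induces stronger complex internalization
  (0.012 vs 0.005 min⁻¹) and IFN-α2 recycles IFNAR2 faster (0.05 vs 0.02
  min⁻¹), so internalization *narrows* the inter-ligand gap at 60 min
  without inverting it, while SOCS1 — acting on phosphorylation, not
  complex formation — rescales both ligands' curves and preserves their
  ratio.

Integration uses LSODA with rtol 1e−8 / atol 1e−10 (copies); receptor and
STAT conservation are checked along every trajectory at rtol 1e−6, and
integration failures raise with the solver diagnostics.

## Population layer and synthetic data

Receptor copies are drawn log-normally, parameterized by median and log-SD
so σ = 0 reduces exactly to the median cell; R1 and R2 draws are independent
by default (an optional correlation parameter exists because the truth is
unknown).  Predictions average pSTAT over 30 sampled cells and multiply by a
global molecules→MFI factor of 1.5.  Cell-size scaling keeps surface
receptor density and cytoplasmic STAT concentration constant: copies ∝ r²,
S_T ∝ r³, rates untouched.

The generator emulates pSTAT1-MFI flow-cytometry panels: 9 half-log doses
(1–10⁴ pM) plus a zero-dose control, times 2.5–60 min (5 and 60 mandatory),
both ligands, replicates with multiplicative log-normal noise
(median-preserving; log-SD = √ln(1+CV²), default CV 20% — geometric-mean
MFI readouts motivate a multiplicative model, the CV is an assumption).
Scenario variants: siRNA knockdown (median scaled before simulation),
size gating (6.5 vs 8 µm), USP18 priming (fold 15–60), affinity-mutant
panels (60× IFNAR1 / 50× IFNAR2 folds), and the early/late design.  The
sidecar records the full recipe; identical recipes regenerate bit-identical
panels.  What the generator does *not* emulate: event-level cytometry
(scatter gating, compensation, autofluorescence), dose/time grids other than
assumed, and any cell-type differences beyond receptor numbers and size —
so passing recovery tests demonstrate correctness of the machinery under the
stated noise model, not robustness to real-instrument artifacts.

## Inference

The loss is the relative MAE, mean(|pred−obs|/obs), matching percentage
reporting; zero observations (the zero-dose control) are excluded with a
warning.  Point estimation: multi-start Nelder–Mead in log-parameter space
within bounds.  Posterior sampling: adaptive Metropolis in log space with
log-uniform priors — scale adaptation (Robbins–Monro toward 30% acceptance)
runs only during burn-in so the retained chains are Markovian — with a
Gaussian likelihood on log-responses and a split-chain R̂ diagnostic.  A
DREAM-style sampler would target the identical density; the simpler sampler
is adequate at this problem size.  Bootstrap validation splits replicates
within each (ligand, dose, time) stratum so every batch keeps full dose
coverage.  Wide marginals are expected ("sloppiness"); the recovery tests
use two stiff parameters (receptor median and K_p) against steady-state
panels, where each likelihood evaluation is closed-form.

## Functional mappings and discrimination metrics

Activities are normalized to [0,1] (assays report percentages, so the
proportionality constants are fixed to 1).  pSTAT copies convert to
cytoplasmic concentration through the cell volume.  IC₅₀ extraction bisects
in log-dose (an absolute tolerance in molar would swamp pM-scale answers)
and defines half-max against the curve's own plateau, flagging curves that
never double their baseline.  The anti-viral IC₅₀ ∝ EC₅₀·K_M/[S_T]
proportionality is verified across an affinity sweep anchored at the
high-affinity ligand, where the saturating pSTAT (the hidden constant in
the proportionality) is insensitive to the folds applied.

The absolute-discrimination region is the band between the two ligands'
plateau responses (plateau = the curve's achieved maximum; curves still
rising at the top dose are flagged).  The time-course index is
pSTAT(60 min)/pSTAT(5 min); a point is "sustained" if |index−1| ≤ 0.2
(configurable, verdicts stable over 0.15–0.3 on the default panels), and two
ligands "separate" at a dose only if their index intervals (mean ± SD) are
disjoint.  On the default panels the verdict is "not separable": the index
falls with dose identically for both ligands, with at most a narrow
low/intermediate-dose window of separation — which the report surfaces
rather than suppresses.

## Problem sizes

The test suite and the acceptance script use 200 random parameter sets for
the equilibrium oracle, 50 for the ODE–equilibrium cross-check, 30-cell
populations for kinetic panels (single-cell, replicate-8 panels for the
time-course analysis), and 4 chains × 5000 steps for the MCMC recovery
study; these sizes keep a full run in the minutes range on one CPU while
leaving every check statistically comfortable.

## Known limitations

* Single aggregated STAT species; no STAT1/STAT2 distinction, no IRF9, no
  endosomal signalling, no hypersensitization by pre-stimulation.
* USP18 is a quasi-static K₄ fold, valid for the high-USP18 primed state,
  not a dynamic induction model.
* The feedback and population parameters are plausible placeholders tuned to
  reported phenomenology, not fits to raw data; quantitative statements
  about real cells inherit that caveat.
* The equilibrium response depends on the subunits only through R_T and Δ²,
  so knockdown asymmetries are purely kinetic phenomena here.
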