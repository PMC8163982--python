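# Methods

## Scope and model

`gpcrbias` analyses kinetic plate-reader experiments that measure
recruitment of intracellular transducers (mini-G proteins,
β-arrestin-2) to class-B GPCRs, receptor internalisation (DERET
620/520 ratio) and cAMP dynamics (FRET, F/F0−5). The scientific
question it operationalises is the distinction between *partial
agonism* — a ligand with reduced maximal response in every pathway —
and *biased agonism* — a ligand whose agonism, after referencing to a
full agonist, genuinely differs between pathways.

### Trace preprocessing

A raw well trace is divided by its own mean signal over the
pre-stimulation baseline window (default: the 5 min before agonist
addition), giving F/F0. Each F/F0 trace is then corrected against the
pointwise mean of the assay's vehicle wells. The default correction is
division,

    R(t) = well(t) / vehicle(t) − 1,

because slow plate-reader drift acts multiplicatively on luminescence
and division cancels it exactly; subtraction is available as a
configuration switch (`vehicle_mode="subtract"`). Whether the
integrand for AUC is F/F0 − 1 or a raw-baseline-subtracted signal only
rescales AUCs proportionally under the division convention; the
division form is used throughout. Scalar summaries are signed
trapezoidal AUCs over the 30-min stimulation window, with the mean
vehicle AUC subtracted (drift typically makes it negative). Technical
replicate wells are averaged within an assay before any fitting, so
one biological replicate contributes one value — the convention used
when plate experiments are summarised per transfection.

### Concentration–response model

The 3-parameter logistic

    y = bottom + (top − bottom) / (1 + 10^(−pEC50 − x)),  x = log10[A] (M)

is fitted by trust-region least squares with an analytic Jacobian,
deterministic data-driven initialisation (plateau guesses from the
response range, pEC50 from the half-maximal crossing) and a small fixed
multi-start grid (pEC50 offsets −1, 0, +1), so refits are bit-identical.
The bottom is floated with a ≥ 0 bound by default (the data are zeroed
by construction; pass `bottom_floor=None` to float it freely); pEC50 is
bounded to [3, 13]. A 4-parameter variant with a free Hill slope
(bounds 0.2–5) is available. Flat responses return a non-converged
result with a diagnostic rather than an arbitrary EC50.

Emax normalisation follows the full-agonist convention: with exactly
one designated full agonist (by default the reference ligand) every
fitted top is expressed as a percentage of its top; when several
ligands are flagged (or auto-detected within 90% of the largest top), a
joint refit with one shared top across those ligands defines the
global maximum used as the denominator. The additive constant this
choice introduces on the log(Emax/EC50) scale cancels in every Δlog,
so bias values do not depend on it (asserted by test).

### Kinetic models and kτ

Two kinetic classes cover the observed shapes at a single saturating
concentration:

* one-phase association, y = SS·(1 − e^(−k·t)) — G-protein recruitment
  and internalisation; the fitted k at maximal stimulation is the
  association rate constant K@[max];
* bi-exponential rise-and-fall, y = D·(e^(−k1·t) − e^(−k2·t)) with
  k2 > k1 ≥ 0 — arrestin recruitment followed by dissociation. The
  k1 ↔ k2 label ambiguity (swap with sign flip of D) is canonicalised
  to k2 > k1, D > 0 for rising data. When the decline phase is absent
  the fit degenerates toward one-phase (k1 → 0) and is returned with a
  degeneracy flag, as it is when the two rates coincide within 0.1%.

Kinetic efficacy is defined as the initial rate of the fitted model at
t = 0:

    kτ = SS·k (one-phase),   kτ = D·(k2 − k1) (rise-and-fall).

This definition unifies both model classes — each has a well-defined
initial slope — and is recorded in every report header to prevent
convention drift. The bi-exponential is fitted without a baseline
term; responses are zero at stimulation onset by construction after
vehicle correction. Fits are unweighted least squares.

### Bias statistics

Per assay, pathway and metric, Δlog = log(test) − log(reference); per
assay, ΔΔlog = Δlog(pathway 1) − Δlog(pathway 2). The pathway order is
fixed in configuration and positive ΔΔlog always means bias toward the
first-listed pathway. Uncertainty is propagated by per-assay pairing
(not by the delta method on pooled fits): the mean ΔΔlog over n assays
carries a Student-t interval, mean ± t(0.975, n−1)·SEM, chosen over a
normal interval because n is typically 4–6. The *biased* call is
"the 95% CI excludes zero"; with n < 2 the call is undetermined.
Wells with non-positive kτ (non-responders) are excluded with a
warning and the pairing is re-checked. Paired two-ligand comparisons
use the standard paired t-test, with the zero-variance degenerate
cases defined explicitly (identical vectors: t = 0, p = 1; constant
shift: p = 0) and flagged. No multiple-testing correction is applied
across ligand panels; the package reports one estimate per configured
comparison.

## Synthetic data generator

The simulator emulates the assay structure, not receptor biophysics:
occupancy is instantaneous mass action, s = c/(c + 10^(−pEC50)), and
the dimensionless response is the kinetic model scaled by emax·s, with
the rise-and-fall amplitude parameterised by its *peak* height
(matching how efficacy is read from plateau/AUC summaries; the D
coefficient is back-computed). R(0) = 0 in both models. Raw signals
compose multiplicatively,

    signal(t) = B_w · (1 + drift·t) · (1 + R(t)) · (1 + ε),

with per-well baselines B_w ~ Normal(B, 0.1·B), linear drift shared by
all wells including vehicles (default −0.2%/min, making vehicle AUCs
negative as observed in practice), and Gaussian noise ε with cv 5%
multiplicative on the whole signal — plate luminescence error scales
with intensity. Rate constants are concentration-independent by
default; an occupancy-scaled mode (rates × s) reproduces
concentration-dependent internalisation kinetics. Identical seeds give
bit-identical panels (`numpy` `SeedSequence` spawning per assay).

Default design mirrors the emulated experiments: 5-min baseline,
30-min stimulation, 0.5-min sampling, 10-point concentration grid
spanning pEC50 ± 2, triplicate technical wells, 3 vehicle wells, 5–6
assay replicates. The truth table bundled with the simulator holds
literature-derived mean parameters for 22 ligand/pathway combinations
of GLP-1/glucagon/OXM-family peptides at GLP-1R and GCGR (pEC50,
Emax% and a rate constant per row); arrestin rows report only the rise
rate, so the decline rate defaults to k1 = 0.05/min — a slow
dissociation consistent with the 30-min traces the rise-and-fall model
was introduced for.

What the generator does *not* emulate: photochemical substrate decay
(drift is phenomenological and linear), well-position effects,
receptor desensitisation or trafficking dynamics
(no ternary-complex/operational-model simulation), read-to-read
correlated noise, or imaging data. Passing calibration tests therefore
demonstrates correctness of the estimators under this noise model, not
robustness to every artefact of real plates.

## Calibration studies (problem sizes)

* **Parameter recovery** — each truth row is simulated 200 times as an
  independent assay replicate together with its reference full agonist;
  per-concentration traces are summarised by an efficacy-proportional
  scalar (end-of-window mean for one-phase; smoothed-trace peak for
  rise-and-fall — raw AUC is deliberately not used here because it
  conflates rate with efficacy when ligands differ kinetically), then
  logistic-fitted and normalised to the co-simulated reference. Mean
  recovered pEC50 is within ±0.15 and Emax% within ±8 points of truth
  for all 22 rows.
* **Null calibration** — 500 experiments (6 assays, cv 5%) in which
  test and reference share identical truth in both pathways; the
  fraction of experiments the 95%-CI rule flags as biased should sit
  near the nominal 5% (accepted range 2–9%). The paired t-test type-I
  error is checked over 10,000 simulated null experiments.
* **Partial-vs-biased separation** — the test ligand's efficacy is
  halved in both pathways (partial agonism without bias): per-pathway
  Δlog kτ recovers log10(0.5) ≈ −0.301 while ΔΔlog kτ centres on zero;
  the complementary biased construction (pathway 2 × 0.25) recovers
  ΔΔlog kτ = +0.602. At cv 5% the per-seed standard deviation of
  ΔΔlog kτ is ≈ 0.027 — close to the Cramér–Rao bound for these traces
  — so a |ΔΔlog kτ| < 0.05 envelope captures roughly 90% of seeds
  rather than 95%; the separation of the two constructions remains
  unambiguous (0.0 vs +0.6). This residual spread is an information
  limit of single-concentration kinetic fits at this noise level, not
  an estimator deficiency; it is documented here rather than hidden by
  quieter simulations.

## Numerical choices and edge cases

* Trapezoidal integration for AUC (standard for plate reads; endpoint
  times interpolated linearly).
* All fits: `scipy.optimize.least_squares` (TRF) with analytic
  Jacobians, tolerances 1e-12 by default; multi-starts are
  deterministic functions of the data.
* Model-class selection for the kτ route is per-pathway configuration;
  the "auto" heuristic smooths the trace (5-point moving average) and
  calls rise-and-fall only when the maximum is interior (< 80% of the
  window) and the final value has declined below 85% of it.
* Concentrations are stored in molar and reported as pEC50; log10
  throughout. Zero concentration is a valid simulation input
  (occupancy 0) but concentration–response fits require positive
  concentrations.
* Validation errors from plate CSVs name the assay/well/column at
  fault; the CLI maps them to exit code 2, and excessive logistic
  non-convergence (> 20% of fits) to exit code 3.

## Known limitations

* The kτ definition covers the two implemented model classes only; a
  model with a nonzero initial response would need re-derivation.
* Bell-shaped (biphasic) concentration–response curves are out of
  scope; such data will fit poorly and should be flagged by the RSS
  diagnostics.
* The bias statistics assume a shared reference full agonist measured
  in every assay; experiments without one cannot be referenced.
* No operational-model (τ/K_A) bias estimation and no ANOVA post-hoc
  machinery — standard libraries serve those needs.
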