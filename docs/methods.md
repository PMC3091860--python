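# Methods

## Models

All models are integrated in scaled (nondimensional) units: time in days,
beta cells in units of the initial count (so beta is the surviving
fraction), and cell/peptide/antibody variables scaled so the healthy B-cell
and antibody baselines equal 1.  `ScaleSet`/`nondimensionalize` map
dimensional systems onto this convention; trajectory equivalence to 1e-6
relative is the correctness gate for the transformation.

**Full one-clone model.**  Effector T cells self-renew with Michaelis–Menten
dependence on autoantigenic peptide (half-maximal at the EC50 `k_pep`, the
reciprocal-avidity knob), turn over at `delta_T` and saturate through
quadratic intra-clonal competition `eps_comp·T²` (which both bounds the
T-cell pool and creates bistability).  B cells receive a bone-marrow
inflow `sigma_B`, expand in proportion to peptide (`rho_B·p·B`), and mature
into plasma cells at a rate proportional to both peptide and T cells
(`mu_mat·p·T·B`, cytokine help at quasi-steady state).  Antibody is secreted
by plasma cells and, with the small factor `f_ratio`, by B cells; the
`f_ratio·B` term sets the basal antibody level.  Beta cells die by mass
action (`kappa·T·beta`, no replication source, hence beta is non-increasing
along every trajectory) and killing releases peptide (`R_pep·T·beta`), the
positive feedback that drives the disease.

**Reduced model.**  With peptide and B cells at quasi-steady state and beta
frozen at the fraction `eta`, the dynamics collapse to (t, q) = (T, plasma).
Peptide becomes `p = pep_gain·eta·t` with `pep_gain = R_pep·beta0/delta_p`,
so the t-nullcline is a set of vertical lines and the phase plane shows a
healthy state (t = 0), a saddle, and an autoimmune state whenever
`k1 < k1*(eta)`.  For this transcription the fold has the closed form
`k1* = eta·pep_gain/eps_comp·(sqrt(alpha) − sqrt(delta_T))²` (tangency of
the activation curve to the loss line); the package *detects* the fold
numerically by bisection on the equilibrium count and uses the closed form
only as a cross-check (it agrees to the bisection tolerance, k1* = 1.4175 at
`eta` = 1 for the defaults).  Declining beta shrinks `k1*(eta)`
proportionally, which is how disease progression eventually extinguishes the
autoimmune state: the full model's trajectory tracks the quasi-static
autoimmune state until the fold is reached, then returns to the healthy
branch.

**Two-clone model.**  Two antigen specificities (clone 1: lower avidity,
conventional-autoantibody-like; clone 2: higher avidity), each split into a
low- and a high-avidity subclone.  Each subclone is activated by its own
clone's peptide; peptide `p_i` is released when clone-i cells kill beta
cells; each clone carries its own B/plasma/antibody compartments (13 ODEs —
antibody is dynamic because clone-1 immunoglobulin turns over at only
0.001/day and is never at quasi-steady state on the simulated horizon).
Relative-effect weights multiply each subclone's contribution to maturation,
killing and peptide release: `(a2, 1, b1·a2, b2) = (0.8, 1, 1.0, 2)` along
(t_1l, t_1h, t_2l, t_2h).  Competition is within-clone only.  The quadratic
competition term is transcribed per subclone with a partial sibling overlap,
`eps_i·t_ij·(t_ij + cross_comp_i·t_sibling)`: with full overlap
(`cross_comp = 1`, a single shared pressure) the temporarily disadvantaged
high-avidity subclone is driven to numerical extinction during the
years-long low-avidity era and can never stage the documented late
take-over; the partial overlap for clone 2 (0.66) keeps it present at a few
percent of the clone and lets dominance be exchanged as beta declines.
Clone 1 uses full overlap (1.0), which is what makes its composition switch
abruptly with the `k_1l` preset.

**In-vitro model.**  B cells mature at a fixed co-culture T-cell count
(`mu_mat·T0·B`) with no antigen drive (no expansion term in the dish);
states are (B, P, S, C) with S the instantaneous secretion rate
`s_Ig(f·B + P)` carried as a state so it can be fitted directly, and C the
accumulated immunoglobulin decaying at `delta_A`.

## Parameters

Fixed standard values (per day, scaled): `alpha` 4, `delta_T` 0.1,
`delta_B` 0.02 (35-day half-life), `mu_mat` 2.858, `delta_P` 0.2 (3.5-day
half-life), `delta_A` 0.034 (IgG), `f_ratio` 0.1, `delta_p` 0.1; two-clone
expansions (7, 6, 4, 2), turnovers (0.1, 0.15, 0.1, 0.2) — the higher
avidity subclone of each clone lives shorter (activation-induced cell
death) — `delta_B` (0.02, 0.04), maturation (7.36, 8.28), `delta_P`
(0.2, 0.4), `delta_A` (0.001, 0.034), relative effects a2 = 0.8 and
(1.25, 2).  `validate_params` enforces the avidity ordering (k strictly
decreasing along t_1l→t_2h), non-decreasing killing weights and the
turnover ordering.

The remaining scaled constants are reconstructions, chosen once so that the
scaled units and documented qualitative behaviours hold, and frozen:

* `sigma_B` 0.02 and `s_Ig` 0.34 normalize the healthy baselines to 1;
* `eps_comp` 60, `R_pep` 3.0 (`pep_gain` 30) place the bistable range at
  k ≲ 1.42 with onset attainable for k ≲ 0.43, a safe band at the top of
  the admissible EC50 range (0, 1.4], and a self-extinguishing bootstrap
  for k ≳ 0.45 from the default seed T(0) = 1e-3;
* `rho_B` 0.095 sits just inside the no-runaway bound
  `rho_B < sqrt(4·mu_mat·delta_B/pep_gain)`: antigen-driven B expansion is
  what elevates antibodies (see below) and the bound guarantees the B pool
  can never grow without limit;
* killing efficacy default `kappa` 6.5e-3 makes the standard clone
  (P1: k = 0.25) reach onset at 10.7 years; P2 = (0.22, 2.6e-3) is the
  persistent-antibody variant;
* two-clone: `eps` (90, 120), `R_pep` (4.0, 1.7), EC50s
  (k_1l, 0.62, 0.30, 0.045) with presets k_1l ∈ {0.7, 0.8, 1.1}.  The
  clone-2 low-avidity subclone keeps the standard clone's expansion,
  turnover and killing weight; its EC50, competition and peptide gain belong
  to the two-clone calibration, which was tuned to reproduce the documented
  preset contrast (see Limitations).

## Antibody elevation and the regime map

With the standard turnover values the saturated-maturation limit pins the
plasma-driven antibody level at exactly the basal level
(`delta_B/(f_ratio·delta_P) = 1`), so sustained elevation comes from
antigen-driven expansion of the B pool.  Inside the no-runaway bound the
attainable quasi-static plateau is about 2–6× basal across the admissible
avidity range; the package therefore defines **elevated** as A > 2× the
closed-form healthy baseline (configurable).  The landscape readouts probe
elevation at six months, at onset and at the 30-year horizon, and classify
each (k, kappa) cell into: (i) elevated throughout without onset,
(ii) onset with persistent elevation, (iii) elevated until onset then basal,
(iv) onset without ever being elevated, or healthy-silent.  Cells whose
elevation fades before a late onset are grouped with (iii).  The "steady
state" column of the sweep is the 30-year-horizon state (the observation
window); the long-run steady state of any single cell is available through
`steady_state` (plateau detection: max |dx/dt| < 1e-8 sustained over a
1-year window, 200-year cap, flagged rather than silent on failure).

## Numerical choices

LSODA with rtol 1e-8/atol 1e-10 for the one-clone and reduced models; BDF
for the two-clone model (LSODA step-floods in its near-neutral coexistence
regime).  Onset is refined by root finding on the dense beta interpolant;
ties resolve to the first touch.  Fixed points come from structural seeds
(roots of the per-capita growth balance) plus 64 polished random starts,
deduplicated at 1e-6, with central-difference Jacobians (step
1e-6·(1+|x|)) and a "marginal" label when the leading eigenvalue is within
1e-7 of zero.  Continuation is natural-parameter with step halving near
folds (branches here fold at most once); the fold locator bisects the
positive-equilibrium count to 1e-6 relative.  Components in [−1e-9, 0) are
treated as zero in readouts.  Fitting uses bounded trust-region least
squares (multistart for the Hill fit, seeded and deterministic; log-scale
residuals for the immunoglobulin channels) and reports curvature-based
standard errors, flagging rank-deficient designs.

## Synthetic data

The generator emulates the two fitting inputs: 20-day co-culture time
courses (11 points; multi-compartment exponential-saturation shapes) and
12-point log-spaced Hill dose-response curves.  Default noise is
multiplicative log-normal at a given coefficient of variation (assay-like,
positivity-preserving); additive Gaussian is available.  Every dataset
carries its generating parameters, and generation is bit-reproducible under
a fixed seed.  What passing recovery tests show is that the estimation
machinery is consistent and well-conditioned under idealized iid scatter;
they do not certify performance on real assay data, which carry systematic
errors (plate effects, censoring, non-constant CV) that the generator
deliberately omits.  At 5% noise the in-vitro fit recovers `mu_mat`,
`delta_P`, `s_Ig`, `f_ratio` and `delta_A` to <10% median relative error;
`delta_B` is a small component of the B-cell decay rate `mu_mat·T0 +
delta_B` and is not separately identifiable at that noise level (median
error ~60%), which the recovery harness reports rather than hides.

## Problem sizes

Default study sizes: 40×40 landscape at a 30-year horizon (~1 minute on one
core), 12-year two-clone runs (<1 s each), 50-replicate Hill recovery and
20-replicate in-vitro recovery (~1 minute together).  These sizes are the
package defaults used by the analysis drivers, the tests and the
acceptance script.

## Limitations

* The displayed equations of the source models are transcribed from their
  verbal description; term forms (competition, maturation) follow that
  glossary, and the handful of unprinted scaled constants are
  reconstructions calibrated to the documented qualitative behaviours, not
  to digit-level curves.
* The two-clone preset contrast (k_1l = 1.1 crossing the 30% threshold
  while 0.8 does not; switch at ~5 years; strongest clone-2 maturation in
  the 1.1 preset) is reproduced, but the top preset (0.7) plateaus just
  above the threshold at 12 years instead of crossing it, and the early
  brief rise of the high-avidity subclones makes their *global* maxima
  occur early even though dominance is exchanged late — the switch is
  therefore quantified by the dominance crossing, not by peak order.
* Memory T-cell pools, beta-cell regeneration, regulatory T cells, thymic
  input, B cells as antigen-presenting cells and spatial islet structure
  are out of scope; antibody persistence after onset is correspondingly
  confined to regime (ii).
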