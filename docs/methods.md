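# Methods

## Dose–response model and relative potency

Viability (percent of the solvent control) is modelled as
`y(x) = a·[c − (c−1)·exp(−b·x^d)]` with concentration `x` in mg/L
throughout.  `a > 0` is the control level, `a·c` the asymptote (`c < 1`
for cytotoxicity), `b > 0` the potency in (mg/L)^−d and `d > 0` the
steepness.  At `x = 0` the model equals `a` exactly; for `c < 1` it is
monotone non-increasing.

Single-compound fits minimise least squares over replicate-mean responses
(technical replicates averaged within biological replicates, then across
them).  The model is ill-conditioned in `(b, d)`, so fitting is
parameterised in `(a, c, log b, log d)` and multi-started over a log-spaced
`b` grid spanning six decades around the half-effect scale and
`d ∈ {0.5, 1, 2, 4}`; the six best starts by raw RSS are polished with a
trust-region reflective solver (`ftol` 1e−12).  Compounds whose replicate
means never fall 10 % below the control level are refused with an explicit
"no cytotoxicity signal" error and enter the mixture bookkeeping with
RPF 0 instead of being dropped.

The parallel fit shares `a, c, d` across compounds with one `b` per
compound, initialised from the single fits (with each single `b` rescaled
through its half-effect dose when the shared `d` start differs) plus a
`d`-grid fallback.  Relative potency factors are
`RPF_i = (b_i/b_ref)^(1/d)` — the unique definition that makes
"dose of *i* ≡ RPF·dose of the reference" exact under this model, verified
in the tests by checking that `x → RPF·x` maps the reference curve onto
each compound's curve.

**Identifiability of `b`.**  Because `b` carries units of (mg/L)^−d, its
value is only comparable across fits at a common `d`; with `d` free, the
Cramér–Rao relative SD of `b` is ≈ 0.2 at plate-level noise (residual
SD 5 on a 3×6 design) regardless of grid placement.  The parameter-recovery
study therefore assesses `b` with the steepness held at the design value
(`fix_d`), while potency *ratios* — the quantity the RPFs need — are
assessed with `d` freely estimated (shared across compounds), where they
recover to a few percent.

## Concentration-addition prediction and the additivity call

A fixed-ratio mixture is described on the active-substance dose axis: dose
`x` means the active at `x` and component *i* at `ρ_i·x` mg/L.  The CA
prediction evaluates the reference curve at the equivalent dose
`x_eq = Σ_i RPF_i·ρ_i·x`.  This closed form is checked against an
independent brute-force oracle that solves `Σ_i dose_i / EC_y(i) = 1` for
the response `y` by root bracketing; agreement is at solver precision
(< 1e−8).

The additivity verdict codifies a curve-position comparison: residuals
(observed − predicted viability) are formed per concentration and
biological replicate, restricted to concentrations whose predicted effect
lies in the 10–90 % window (outside it the model is flat and residuals are
uninformative), averaged per biological replicate, and tested against zero
with a one-sample t-test (α = 0.05).  Significantly negative residuals
(lower viability than predicted) give *more than additive*; positive,
*less than additive*; otherwise *additive*.  With no concentration in the
window the verdict is *indeterminate* — reported explicitly, never
defaulted.  Zero-variance (noise-free) inputs are decided on the residual
sign alone.

## Transwell transport reduction

Cumulative transported amount with sink-condition aliquot replacement:
`Q_k = c_k·V_receiver + Σ_{j<k} c_j·v_sample` (mg/L·µL = ng, reported in
µg).  Relative transport is `100·Q_k/(c₀·V_donor)`; values above 100 %
are flagged in the log as mass-balance violations, and negative measured
concentrations are clipped to zero with a warning.  The efflux ratio is
the secretory (BL→AP) over absorptive (AP→BL) relative transport at the
matched final (8 h) timepoint, rounded to 3 decimals to match conventional
reporting.  `Papp = (ΔQ/Δt)/(A·c₀)` uses the OLS slope over all
timepoints (not a two-point difference) — it uses the whole 2/4/6/8 h
design and is standard Caco-2 practice.  Insert area defaults to the
12-well transwell value 1.12 cm².

Barrier QC passes only when TEER at both 0 h and 8 h is at least
250 Ω·cm² and the FITC-dextran Papp is at most 1e−6 cm/s — conventional
Caco-2 acceptance values, both configurable; missing measurements give
*not assessed*, never a silent pass.

## Statistics

Endpoint assays use a linear mixed-effects ANOVA: fixed treatment effect,
random intercept per biological replicate, residual at the
technical-replicate level, REML estimation with the variance component
floored at zero (statsmodels `MixedLM`; when the component sits at the
boundary or the profile is singular the model is refit as OLS, which also
makes the single-comparison case reduce exactly to the pooled two-sample
t-test).  Residual degrees of freedom (`n − rank(X)`) are used.  Dunnett
many-to-one adjustment evaluates `P(max_j |T_j| ≥ |t_i|)` under the joint
multivariate-t law of the contrasts: for (near-)equicorrelated contrast
correlations — the balanced case, ρ = 0.5 — by Gauss–Hermite ×
Gauss–Legendre quadrature over the shared normal factor and the χ scale
(deterministic, ~1e−6 accurate); otherwise by seeded Monte Carlo with
200 000 draws.  One-sided testing targets decreases relative to the
control (the direction of interest for viability, anisotropy and ΔRLU
declines).  Simultaneous confidence bounds use the Dunnett critical value.
Under the null (3×6 design, seven treatments plus control) the simulated
family-wise error rate is within a few thousandths of the nominal 0.05.

Transport time courses are compared as whole curves: a mixed model with
treatment, time, treatment×time fixed effects and a random intercept per
insert, and per-treatment joint Wald contrasts over the main-effect plus
interaction coefficients, Holm-adjusted across treatments.  The Wald
statistic is referred to `F(q, n_units − n_treatments)`: the treatment
contrast is a *between-insert* comparison, and with triplicate inserts the
usual residual-df reference is strongly anti-conservative (simulated null
rejection ≈ 0.10–0.17 at α = 0.05), while the between-unit denominator is
slightly conservative (≈ 0.015) — the honest choice at these sample
sizes.  Holm adjustment follows the step-down rule
`p_(i) → max_{j≤i}(m−j+1)·p_(j)` capped at 1 (via statsmodels).

## Synthetic-data generator

The generator emulates the study design end to end; a single seed fans out
to independent per-stream child seeds (`SeedSequence`), and identical
configuration plus seed reproduces outputs bit for bit.

*Viability plates*: model value plus an additive normal biological-replicate
intercept (default SD 2) plus residual noise (default SD 5), 3 biological ×
6 technical replicates on a grid that must include 0.

*Transport*: two well-stirred compartments (500 µL apical, 1500 µL
basolateral, 1.12 cm² membrane) exchanging analyte with directional
permeabilities `P(AP→BL) = P·(1 − φ·e)` and `P(BL→AP) = P·(1 + φ·e)`,
where `e = IC50/(IC50 + [S])` is the efflux activity remaining at
surfactant concentration `[S]`.  Above the critical micelle concentration
the donor's free fraction falls to `1/(1 + K_mic·([S] − CMC))`.  Optional
first-order ester hydrolysis converts parent to a separately tracked
metabolite (own efflux weight, default 0.7) in both compartments.
Integration is a fixed-step explicit update at 0.01 h — the rates are far
from stiff and sampling events must land exactly on the schedule — with
the 2/4/6/8 h aliquots (200 µL apical / 600 µL basolateral) removed and
replaced by blank medium instantaneously; a negative mass aborts with a
step-size diagnostic.  Mass (donor + receiver + removed aliquots +
metabolite) is conserved to floating-point roundoff.  Defaults
`P = 7.8e−6 cm/s`, `φ = 0.45`, `IC50 = 1 mg/L`, `CMC = 50 mg/L`,
`K_mic = 0.01 L/mg` were calibrated once so the reduced efflux ratio is
≈ 0.89 uninhibited, ≈ 0.40 at the product-ratio surfactant load, with
absorption reduced again above the CMC.  Measurement noise is
multiplicative lognormal (CV-parameterised) on recorded concentrations —
the scale-proportional error of plate readers and LC-MS quantification —
applied to measurements only, so the internal ledger stays exact.

*Anisotropy*: quadruples are constructed by inverting the definition at a
chosen total intensity — `I_VV = T(1+2r)/3`, `I_VH = T(1−r)/(3G)`,
`I_HV = G·I_HH` — so the reduction returns `r` exactly at zero noise
(untreated cells are generated at r = 0.150).  Scenario noise defaults to
CV 0.005 per intensity (≈ 0.004 SD on `r`), consistent with treatment
effects of 0.01–0.03 being resolvable at n = 3.

*ATPase plates*: `RLU(well) = RLU(Na₃VO₄) − activity`, with activity
`basal` untreated, `basal·stimulation` under verapamil and
`basal·stimulation·(1 − f([test]))` for test articles co-incubated with
verapamil, `f` a Hill inhibition curve.  Na₃VO₄ wells therefore carry the
highest expected RLU, and the estimator
`1 − ΔRLU(test+verapamil)/ΔRLU(verapamil)` recovers the programmed
inhibition fraction exactly at zero noise.

**What the generator does not emulate**: LC-MS peak shapes and extraction
recovery, cell-to-cell passage variability, paracellular leakage changes,
transporter expression gradients along the monolayer, or luciferase
kinetics.  Passing tests demonstrate that the reductions and inference are
correct under the stated mechanisms and noise models — not that those
mechanisms exhaust real Caco-2 biology.

## Problem sizes and determinism

The simulation studies use 200 replicate datasets for recovery and power
rates, 1000 null studies for the family-wise error calibration, and 20
plates for the ATPase recovery mean; these sizes give Monte-Carlo SEs well
below the margins being checked while keeping a full run to a couple of
minutes on one CPU.  Every stochastic component accepts a seed, and all
seeds in the test suite and reproduction script are fixed.

## Known limitations

- RPFs assume parallel curves; strongly non-parallel compounds violate the
  dose-scaling premise and the shared-shape fit will show it as inflated
  RSS rather than refusing outright.
- The additivity call tests the *mean* residual inside the effect window;
  a mixture that crosses the CA curve (more potent at low dose, less at
  high) can average to "additive".
- The transport simulator treats compartments as well stirred and the
  monolayer as a single barrier; unstirred water layers and intracellular
  accumulation are not represented.
- Degrees-of-freedom handling in the mixed models is residual-based
  (endpoint) and between-unit (time courses), not Satterthwaite/
  Kenward–Roger; at the balanced designs used here the endpoint
  calibration is verified by simulation and the time-course reference is
  deliberately conservative.
- At n = 2 inserts per arm (one of the absorptive designs), curve
  contrasts have a single between-unit degree of freedom and are reported
  but weakly powered.
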