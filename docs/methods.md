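# Methods

## Model

The package models a closed (batch) *E. coli* culture in which an F plasmid
spreads by conjugation while the F-pilus-specific filamentous phage M13
spreads by infection. The state is nine-dimensional: a resource pool `r`
(arbitrary units, a.u.), seven cell compartments (per mL) and free phage
(per mL). Donors D conjugate with recipients R, producing transconjugants T
(which mature into donors at rate λ_T) and leaving the donor temporarily
exhausted (X, recovering at λ_X). Phage can only adsorb to plasmid-bearing
donors; newly infected cells N become phage producers I after a first-order
latent period (λ_N), and infected donors that conjugate pass through an
exhausted infected state XI. Infected hosts are not lysed: they keep growing
at a penalised rate P_ψ·ψ(r) and secrete phage continuously.

All rates share a hyperbolic (Monod) resource dependence
`rate(r) = rate_max · r/(Q+r)`, and growth additionally carries the logistic
factor `(1 − Σn/K)`, where Σn is the total cell density. Phage production is
`ψ_P(r)·(n_I+n_XI)·(1 − n_P/K_P)`. Resource is consumed in proportion to
growth, `e` units per cell division, including the same logistic factor, so
`dr/d(Σn) = −e` exactly while both limits are away from saturation: the
culture saturates at roughly `min(K, n_0 + r_0/e)` cells/mL.

Model assumptions worth keeping in mind:

* lags are exponential (first-order compartments), not fixed delays;
* infection is a single mass-action step β(r)·n_D·n_P that lumps surface
  binding, entry and the assay's inability to distinguish them;
* transconjugants produced by infected donors are born uninfected — the
  phage does not co-transfer;
* no phage-resistant mutants, no stochasticity (deterministic ODEs).

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| psi_max | max cell growth rate | min⁻¹ | 0.035 |
| gamma_max | max conjugation rate | mL cell⁻¹ min⁻¹ | 3×10⁻¹⁰ |
| beta_max | max phage infection rate | mL phage⁻¹ min⁻¹ | 3×10⁻¹¹ |
| psiP_max | max phage production | phages cell⁻¹ min⁻¹ | 6 |
| Q | resource at half-max rate | a.u. | 1 |
| e | resource per division | a.u. mL cell⁻¹ | 3.5×10⁻⁸ |
| K | cell carrying capacity | cells mL⁻¹ | 3×10⁹ |
| K_P | phage carrying capacity | phages mL⁻¹ | 4×10¹¹ |
| lambda_T | transconjugant maturation | min⁻¹ | 1/90 |
| lambda_X | exhausted-donor recovery | min⁻¹ | 1/30 |
| lambda_N | latent-period exit | min⁻¹ | 1/30 |
| P_psi | growth penalty when infected | — | 0.6 |
| P_gamma | conjugation penalty when infected | — | 0.1 |

The defaults are the published simulation values for this system. `P_gamma`
is the canonical name for the conjugation penalty; configuration files may
spell it `P_lambda`. λ_T, λ_X, λ_N, K, K_P and Q are treated as externally
determined (literature or direct measurement) and are never fitted. Pure
rates may be set to exactly 0 to switch a process off (used heavily by the
conservation tests); capacities, Q, e and the penalties must stay positive.

## Inoculation presets

The presets convert the bench pipetting protocol (volumes from saturated
overnight cultures into 50 mL of fresh broth) into densities, assuming a
saturated culture sits at K = 3×10⁹ cells/mL and a phage stock at 10¹¹/mL:

* `COND1` (variants `1:0` … `1:1000`): donor/recipient mixtures totalling
  10⁶ cells/mL, 700 min, no phage.
* `COND2A` (dilutions 10⁰…10⁻²): donors 3×10⁷·10⁻ⁱ /mL, phage 10⁷/mL, 500 min.
* `COND2B` (dilutions 10⁰…10⁻⁴): donors 3×10⁶/mL, phage 10⁸·10⁻ⁱ /mL, 500 min.
* `COND2C` (dilutions 10⁰…10⁻²): pre-infected overnight culture diluted into
  fresh broth; the whole inoculum is placed in the producer compartment n_I
  (overnight infection far exceeds the 30-min latent period) with free phage
  at the saturated ratio, n_P/n_I = K_P/K.
* `COND3`: the `COND1` mixtures plus phage at 10⁷/mL at t = 0.

All presets start at r₀ = 100 a.u. and sample every 20 min; t = 0 is the
phage-inoculation time where phage is involved. Durations (700 min for
COND1/COND3, 500 min for COND2*) cover saturation in every preset.

## Numerics

Integration uses LSODA (adaptive, stiffness-switching) at rtol 10⁻⁸ and
atol 10⁻² (cells or phage per mL), reporting on the sampling grid.
Trajectories are integrated in raw coordinates; tiny negative overshoots are
clamped to zero on output and a run is rejected if any coordinate falls below
−10⁶·atol. Inside the right-hand side the Monod factor is evaluated at
max(r, 0) so a transient negative resource cannot flip rate signs. The
reduced systems are evaluated by embedding into the nine-dimensional state
and projecting, which makes them bitwise-identical to the full system on
their shared coordinates.

A fixed-step forward-Euler integrator (`euler_oracle`) cross-validates the
adaptive solver. Deviations between trajectories are measured per compartment
against the compartment's dynamic range (max over time of either trajectory,
floored at 1 unit/mL) — a pointwise-relative measure is ill-posed for
compartments that decay to ~0, such as donors under heavy infection. Under
this metric the Euler oracle at dt = 0.01 min agrees with LSODA to
1.2×10⁻⁴–2.9×10⁻⁴ on COND1/COND2C and to 1.1–2.7×10⁻³ on
COND2A/COND2B/COND3; the larger values are plain first-order truncation
error over 500–700 min of near-exponential growth (global relative error
≈ ψ²·dt·t/2 ≈ 2–3×10⁻³, halving when dt is halved). Expecting better than
10⁻³ from forward Euler at this step on these conditions is not realistic.

## Synthetic qPCR data

Marker mapping: tolC counts one copy per cell over all seven compartments
(no replication-fork correction), traI one copy per plasmid-bearing cell
(F is single-copy), M13 counts free phage only. The idealized calibration
`Ct = ct_ref − log2(N/N_ref)` (defaults ct_ref = 35 at N_ref = 10³
copies/mL) assumes perfect doubling efficiency; zero abundance has no Ct and
is carried as a censored NaN, never an exception. Noise is i.i.d. Gaussian in
Ct space, default sd 0.5 cycles with triplicate series, so replicate ranges
sit around one cycle — matching the replicate scatter such assays typically
show. Equivalently, abundance noise is multiplicative log-normal: the
generator can never produce a negative abundance. One integer seed drives
everything through per-(locus, replicate) substreams, so any subset of the
dataset reruns identically.

What the generator does not emulate: amplification curves and per-run primer
efficiencies, between-flask biological variability, inoculum pipetting error,
plate or batch effects, and detection limits (censoring arises only from
exactly-zero abundance). Passing recovery tests on these data therefore show
the estimator is self-consistent under the model's own noise assumptions —
not that the model is correct for any particular bench dataset.

## Staged calibration

The full model is over-parameterised for any single experiment, so
calibration runs in four stages, each fixing everything established earlier:

1. growth (COND1 pure donor, conjugation-only system): ψ_MAX and e;
2. conjugation (COND1 ratios, tolC+traI jointly): γ_MAX;
3. infection (COND2A + COND2B, tolC+M13, infection-only system): β_MAX,
   ψP_MAX, P_ψ;
4. competition (COND3, all three loci, full system): P_γ.

The loss is ordinary least squares on log₁₀ abundance — identical, up to the
factor log₁₀2, to least squares on ideal Ct — pooling all curves and loci of
a stage; zero/censored points are excluded, never log-transformed. qPCR data
span four decades, and cycle-space residuals weight them evenly.
Optimisation is trust-region least squares (scipy) over log₁₀-transformed
parameters within bounds (ψ_MAX ∈ [10⁻⁴,1], e ∈ [10⁻¹⁰,10⁻⁵],
γ_MAX ∈ [10⁻¹⁴,10⁻⁷], β_MAX ∈ [10⁻¹⁵,10⁻⁸], ψP_MAX ∈ [10⁻²,10²],
penalties ∈ (10⁻⁴,1]), multi-started from the initial guess plus four
log-spaced quantiles of the bound box, best residual kept; convergence at
relative objective change 10⁻¹⁰ or 500 evaluations. Results objects carry
the estimates, the fixed parameters, the residual norm, identifiability
warnings (fewer than two ratio datasets; no recipients; no phage; estimates
at a bound) and the decreasing trace of accepted objective values.
A non-convergent stage aborts downstream stages rather than silently
propagating a bad fix.

On noiseless synthetic data the pipeline returns the generating values to
optimizer precision for all seven fitted parameters, at the default problem
sizes (one 36-point pure-donor curve; four ratio curves; eight infection
curves; five competition curves — single replicates).

## Design choices

* Stage models are organised statsmodels-style (model object from data,
  `fit()` → results object with `summary()`), with plain functions
  (`fit_growth`, …, `run_full_calibration`) layered on top.
* The logistic factor is applied exactly as the model equations state it —
  including on resource consumption, which therefore vanishes at carrying
  capacity.
* "Saturation" operationally means the last sampling time of a preset;
  `saturation_summary` also reports when total-cell growth first falls below
  10⁻³·ψ_MAX·K per minute.
* The encounter-rate ratio (γ_MAX/β_MAX)·(n_R/n_P) is exposed with both
  factors; the donor density and the shared Monod factor cancel exactly.
* Phage burden divides free phage by total cells; at saturation of a
  pre-infected culture every cell is infected, so the distinction from
  per-infected-cell burden vanishes.

## Known limitations

* **The conjugation penalty barely moves the phage curve.** Because phage
  are produced by the whole infected pool n_I + n_XI, and conjugation of
  infected donors only cycles cells between I and XI, P_γ cannot suppress
  phage production; its entire observable effect (via recipient depletion
  and the uninfected-transconjugant detour) is a few percent on any locus —
  about 0.07 cycles. One might expect the opposite (a "conjugating instead
  of producing" penalty); that behaviour would require phage production from
  n_I alone, a different model. Consequently P_γ is recovered exactly from
  noiseless data but is effectively unidentifiable at realistic Ct noise
  (sd 0.5): across seeds, noisy estimates scatter to the parameter bounds.
* **e is only marginally identified by a single growth curve.** The
  resource-limited plateau r₀/e + n₀ ≈ 2.86×10⁹ sits just 5% (0.02 log₁₀)
  below the carrying capacity K = 3×10⁹, while the plateau's standard error
  with sd-0.5 triplicates is ≈0.025 log₁₀. The growth-stage objective is
  bimodal (resource-limited vs K-limited saturation), and with noise the
  degenerate mode can genuinely attain the lower residual. The fitted e then
  collapses to its lower bound and is flagged `at_bound`.
* **Staging amplifies carried-forward error.** γ_MAX is recovered within a
  few percent when ψ_MAX and e are known exactly, but the transconjugant
  signal accrues mostly near saturation, where the e-controlled shutdown of
  γ(r) dominates: a −5% error in ê can move γ̂ by tens of percent. Median
  noisy-recovery error across 10 seeds is well inside 25% for ψ_MAX, e,
  β_MAX, ψP_MAX and P_ψ, but not for γ_MAX and P_γ — an intrinsic property
  of the staged design at this noise level, not of the optimizer.
* Forward-Euler cross-validation at dt = 0.01 min resolves these systems to
  ~10⁻³ relative, not better (first-order truncation; see Numerics).
* No confidence intervals or profile likelihoods are computed; estimates are
  point values with residual diagnostics.
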