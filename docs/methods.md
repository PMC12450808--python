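# Methods

## Model

The economic engine is a partitioned survival analysis (PartSA) with
three health states — progression-free (PFS), progressed disease (PD),
dead. Unlike a Markov model it uses no transition probabilities: state
membership at time t is read directly off the two marginal survival
curves, `p_pfs = min(S_pfs, S_os)`, `p_pd = S_os − p_pfs`,
`p_dead = 1 − S_os`. The central assumption is that the two curves
jointly describe the cohort; nothing constrains individual paths, and
if the extrapolated PFS curve crosses OS the engine clamps
(`p_pd = 0`) and logs it.

Outcomes and costs are integrals of occupancy-weighted rates over the
horizon, discounted at d(t) = (1+r)^(−t/12):

- LY = (1/12)·∫ S_os·d dt, QALY = (1/12)·∫ (u_pfs·p_pfs + u_pd·p_pd)·d dt;
- drug cost capped at `cap_months` accrues on `p_pfs·d` only while
  t ≤ cap (set `cap_months = inf` for the no-cap scenario); uncapped
  drug and other pre-progression costs accrue on `p_pfs·d`;
  post-progression cost on `p_pd·d`;
- the terminal (end-of-life) cost multiplies each cycle's death
  increment S_os(tᵢ) − S_os(tᵢ₊₁), discounted at the cycle end — the
  natural reading of a cost incurred in the month before death.

### Numerical choices

Integration is trapezoidal on the cycle boundaries by default, which is
the half-cycle-corrected version of per-cycle multiplication and
converges to the continuous integral at O(Δt²); a `left` rule is
provided for reproducing models built without half-cycle correction.
Discounting is continuous-in-time at each boundary by default, with an
`annual` stepwise option, since published models state only the annual
rate. With exponential curves the engine agrees with direct quadrature
of the continuous-time integrals to < 0.3% relative at a one-month
cycle (tested). Defaults mirror the published evaluation this package
re-implements: 38-year horizon, one-month cycle, 2% annual discount on
costs and outcomes, 50–100k USD/QALY WTP band, 150 JPY/USD applied once
at ingestion so the model is single-currency.

ICERs are only reported as ratios when meaningful: (ΔC<0, ΔQ>0) and
(ΔC>0, ΔQ<0) are labelled dominance, ΔQ = 0 is labelled
`undefined_ratio`, and no division occurs in either case.

## Pseudo-IPD reconstruction

`reconstruct_ipd` implements the interval-wise Guyot-style algorithm.
Per risk-table interval: an initial censoring guess is apportioned from
the at-risk decrement not explained by the KM drop; censoring times are
placed at evenly spaced interior quantiles; events at each digitized
drop come from the survival ratio against the running KM estimate, with
fractional drops carried in an accumulator and the running estimate
updated from the integers actually emitted (both directions of rounding
drift self-correct). The censoring count is iterated (cap 30) until the
implied number at risk at the interval end matches the published count;
because adding one censor can flip one event rounding, a final
reconciliation freezes the event counts and adjusts censorings so the
published decrement is conserved exactly, flagging the interval in
`unmatched_intervals` only if that too is impossible. An optional total
event count adjusts the tail: surplus curve drops are re-labelled
censored, missing events are assigned to end-of-study survivors.
Boundary-time events open the *later* interval, consistent with the
at-risk convention n(τ) = #{follow-up ≥ τ} used both by the KM
estimator and by the synthetic risk tables. Round-trip fidelity (KM of
the reconstruction vs the source curve) is < 0.02 absolute survival on
all tested fixtures (n ∈ {100, 300, 1000}, censoring 0–0.05/month),
typically < 0.01.

## Parametric fitting

Six accelerated-failure-time families; the generalized gamma uses the
Prentice (μ, σ, Q) parameterization, which is numerically stable and
nests Weibull (Q = 1), log-normal (Q → 0, handled analytically below
|Q| = 1e−6) and gamma (Q = σ). Gompertz allows a negative shape, giving
a survival plateau exp(rate/shape) (a cure-like tail); the simulator
refuses such parameters unless administrative censoring makes all
observation times finite.

The likelihood is maximized on an unconstrained internal scale (log for
positive parameters) by Nelder–Mead from several deterministic
moment/grid starts followed by an L-BFGS-B polish; multiple starts are
what protects the Gompertz and generalized-gamma surfaces from local
optima. Standard errors are delta-method SEs from the inverse of a
central-difference observed information matrix on the internal scale; a
non-positive-definite information matrix marks the fit non-converged.
Zero survival times (possible after reconstruction) are shifted to half
the smallest positive time and logged. On families lifelines also
implements, the optima and SEs agree to machine precision (tested).

Model selection ranks converged fits by AIC with BIC tie-break and
reports landmark extrapolated survival; it is deliberately advisory —
extrapolation differences between families dwarf in-sample fit
differences, which is exactly what the scenario analysis quantifies.

## Sensitivity analyses

- **DSA**: each parameter set to its low/high with others at base; the
  tornado is sorted by |ICER(high) − ICER(low)|.
- **Scenario**: one family refitted to all four curves and the model
  re-run; non-convergence yields a flagged row, never a dropped one.
- **PSA**: 5,000 second-order Monte Carlo draws by default. Costs with
  95% CIs use gamma distributions moment-matched via
  sd = (CI_high − CI_low)/3.92 (normal-approximation divisor), shape =
  (mean/sd)², scale = sd²/mean; prices and utilities use a symmetric
  triangular with mode at base and ±10% endpoints. Survival-curve
  uncertainty is **off** by default (published input tables typically
  state no distribution for survival parameters); an optional mode
  draws internal parameters from the fit's multivariate normal.
- **CEAC**: fraction of draws with λ·ΔQ − ΔC strictly positive; an NMB
  of exactly 0 counts as not cost-effective (a determinism tie-break,
  immaterial under continuous sampling).
- **Threshold price**: bisection on the capped drug price until the
  re-run ICER is within 1 USD/QALY of the target; requires the ICER to
  cross the target inside the bracket and reports both end ICERs
  otherwise. Note that a per-month post-PD cost shared by both arms
  does *not* cancel in ΔC unless the arms also share PD occupancy, so
  the threshold price does shift (downward) when that shared cost
  rises; exact invariance holds only for equal-occupancy fixtures.

## Synthetic data

`simulate_arm` draws death times from the OS family and an independent
latent progression time from the PFS family; the PFS event time is
their minimum (progression or death, whichever first). This makes the
OS marginal exact and guarantees PFS ≤ OS per subject; the PFS marginal
is then S_prog·S_os rather than the raw PFS family — adequate for
artifact plumbing, and the reason calibrated parameter sets (not
simulations) define the baseline study. One shared censoring time per
subject combines exponential dropout with an administrative cut-off.
Emitted artifacts are *exact*: true KM step coordinates and true
at-risk counts with no digitization or rounding noise, the cleanest
substrate for testing the reconstruction. Real digitized figures add
pixel error and rounded risk tables, so passing round-trip tests bound
algorithmic error only, not digitization error.

Cost samples use the same moment-matched gamma as the PSA.

## Baseline calibration

The published evaluation the baseline study emulates used digitized
KEYNOTE-590 curves and claims-derived costs; neither the coordinates
nor the adopted curve parameters are printed. `pypartsa.baseline`
therefore ships a labelled synthetic calibration: log-logistic scales
pinned at clinically typical medians for this indication (base case OS
12.4/9.8 months, PFS 6.3/5.8; CPS ≥ 10 subgroup 13.9/8.8, 7.5/5.5) and
shapes solved by root-finding so the model's *discounted* restricted
mean state durations match the published per-state totals (12.67/12.54
and 8.53/9.85 months, etc.), with the PFS calibration performed under
the engine's min-clamp. Cost and utility inputs are the published
parameter table. The resulting LY and cost decomposition track the
published base case closely; the QALY increment differs (0.42 vs a
printed 0.38, ICER ~151k vs 176k) because the printed QALYs are lower
than utilities × printed state durations imply, an inconsistency this
package does not attempt to reproduce.

## Problem sizes

Tests and the acceptance script run reconstruction at n ≤ 1000,
recovery studies at n = 2000 × 20 seeds, PSA at 5,000 draws, and
pipeline fixtures at n = 250–300 per arm with 200–1000 PSA draws —
sizes chosen so the full suite completes in well under a minute of
model time while keeping Monte Carlo error far below the asserted
tolerances.

## Known limitations

- PartSA has no within-model link between PFS and OS beyond the clamp;
  structural uncertainty between families is addressed only by scenario
  analysis.
- No covariate adjustment, spline/flexible-parametric models, EVPI, or
  adverse-event costs (the emulated evaluation excluded them).
- The Guyot reconstruction assumes non-informative censoring within
  risk intervals and exact risk-table counts; rounded published tables
  degrade fidelity gracefully but untested.
- Subgroup analyses are configuration changes (different curves/costs),
  not dedicated machinery.
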