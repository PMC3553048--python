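# Methods

## Model

A patient's residual tumour after curative-intent treatment is modelled as
K latent clonogens, each independently regrowing to a detectable
recurrence after a time with survival A₀(t); the observed time-to-event is
the minimum over clonogens, so the marginal survival is the probability
generating function (pgf) of K evaluated at A₀(t).  The population is
thereby a mixture of cured patients (K = 0, improper tail) and
susceptibles.  Group 0 is the Poisson benchmark K ~ Poisson(ω₀), giving
S₀(t) = exp(−ω₀(1 − A₀(t))) with cure fraction π₀ = e^{−ω₀}.  Group 1
draws K from the Katz family (ω₁, θ) — the discrete family with
Pr(x+1)/Pr(x) = (ω+θx)/(1+x), ω > 0, θ < 1 — whose pgf gives

S₁(t) = [(1 − θA₁(t))/(1 − θ)]^{−ω₁/θ},  A₁(t) = A₀(t)^{e^α},

with the θ→0 limit handled analytically (|θ| < 1e−10 dispatches to the
Poisson form).  The Katz family separates the cure fraction
(1−θ)^{ω₁/θ} from the dispersion of the count among susceptibles
(variance/mean = 1/(1−θ)): θ > 0 is a heterogeneous multi-clonogen
(Negative Binomial) burden, θ < 0 an under-dispersed (Binomial) one, with
the single-clonogen (Bernoulli) model as the extreme case.

Three interpretable parameters index departures from the null of
identical survival: α (latent progression shift; α > 0 means earlier
relapses in group 1), θ (burden dispersion), γ = log(ω₁/ω₀) (cure-burden
shift).  H₀: θ = α = γ = 0.

## The score test

The score of the log-partial likelihood at H₀ has components

V_r = Σ_j δ_j w_r(t_j) (G_j − S⁽¹⁾(t_j)/S⁽⁰⁾(t_j)),  r ∈ {α, θ, γ},

with w_α(t) = 1 + log(1 − Θ̂₀(t−)/ω̂₀), w_θ(t) = 1 − Θ̂₀(t−)/ω̂₀,
w_γ ≡ 1, where Θ̂₀ is the pooled-sample Nelson–Aalen estimator and
S⁽ʳ⁾(t) = n⁻¹ Σ_k Y_k(t)G_k^r are risk-set moments of the group
indicator.  The observed information is I_rs = Σ_j δ_j w_r w_s v_j with
v_j = S⁽²⁾/S⁽⁰⁾ − (S⁽¹⁾/S⁽⁰⁾)², the hypergeometric-type risk-set variance
of G.  S_H0 = V′Î⁻¹V is referred to χ²(3); the γ-direction alone is the
classical logrank test (identical to it by construction, verified against
lifelines to 1e−8 in the tests).

Conventions that matter:

- **Plug-in ω̂₀ includes the final jump.**  ω̂₀ is the right-continuous
  Nelson–Aalen value at the last failure time, while the weights use the
  left-continuous Θ̂₀(t−).  This guarantees 1 − Θ̂₀(t_j−)/ω̂₀ > 0 at every
  event time, keeping the log weight finite; excluding the jump would make
  the weight at the last failure undefined.  Validity additionally
  requires that susceptibles fail within follow-up (see the simulator's
  administrative cutoff).
- **Sign of the information.**  The risk-set variance form v_j ≥ 0 is
  used so that Î is symmetric positive semi-definite and S_H0 a
  non-negative quadratic form (observed information = minus the Hessian).
- **Ties.**  Tied events are pooled into one jump d_k/Y(t_k); an event
  tied with a censoring keeps the censored subject in the risk set
  (events-first convention).  Times are compared exactly; no tolerance
  merging.
- **Degenerate designs.**  The statistic is refused (with a diagnostic
  error) when the condition number of Î exceeds 1e12 — e.g. fewer than
  three distinct event times, or a group contributing no events — rather
  than silently pseudo-inverted.  The CLI still reports the logrank test
  in that case.
- Katz pmf values are computed by the recurrence in log space; for θ < 0
  the pmf exists only when −ω/θ is a positive integer (checked to relative
  1e−9), while pgf, p₀ and moments remain defined for any θ < 1.

## Simulation design

The generator reproduces a two-arm study: n = 100 subjects per group
(configurable), group 0 from the Poisson benchmark with baseline cure
π₀ ∈ {0.30, 0.50, 0.70} (ω₀ = −ln π₀), and a unit-exponential latent
baseline A₀(t) = e^{−t} (pluggable).  Event times are drawn by inverse
transform on the marginal improper survival: a uniform draw at or below
the group's cure fraction yields the CURED sentinel (infinite event time),
avoiding any need for the group-1 count to have a realisable pmf (the
equal-cure ω₁ = −ω₀θ/ln(1−θ) is generally a non-integer Binomial size for
θ < 0, yet S₁ is a perfectly valid survival function).

**Alternative scenarios.**  Over-dispersed cells use θ = 0.78 with the
equal-cure ω₁ scaled by e^γ ∈ {1, 1.2} (so the group-1 cure fraction is
π₀^{e^γ}) and latent shift e^α ∈ {1, 1.25, 1.5} with A₁ = A₀^{e^α}.
Under-dispersed cells use the single-clonogen model: K₁ ~ Bernoulli(p)
with p = 1 − π₁ and π₁ = π₀^{e^γ} (Katz θ = −p/(1−p), ω₁ = p/(1−p)), and
the latent shift applied with the opposite sign, A₁ = A₀^{e^{−α}}.  These
two under-dispersed conventions are deliberate: the cure-matched Bernoulli
and the e^{−α} shift are the conditions that reproduce the study's full
under-dispersed power tables (score and logrank columns alike), whereas a
fixed θ = −1 with equal-cure ω₁ does not except at 50 % cure, where the
two coincide (there ω₁ = 1 and the Katz exponent −ω₁/θ = 1).  Both remain
available: `count_model="katz"` with any θ, and `shift_sign` ∈
{"model", "as_printed"}.

**Censoring.**  "No censoring" still censors cured subjects
administratively at τ with A₀(τ) = 10⁻⁶ (τ ≈ 13.8), so every record is
finite and P(susceptible outlives τ) < 10⁻⁴.  Random censoring is
C ~ Exp(ζ) truncated at τ, with ζ solved by Brent root-finding so that
the *susceptible-conditional* censored fraction ∫ζe^{−ζt}S_u(t)dt —
averaged over the two groups, S_u = (S−π)/(1−π) — equals the target
(0 or 30 %).  The cure fraction is thus excluded from the censoring
percentage.

**Power study.**  500 replicates per cell at nominal level 0.05;
per-replicate generators are spawned from the master seed via
`numpy.random.SeedSequence`, so every number is reproducible from one
integer.  Both tests are evaluated on the same replicates.  Degenerate
replicates are counted separately (none occur at the study sample size).
The 36-cell alternative grid (`POWER_TABLE_GRID`) covers the uncensored
panels: {over-dispersed, single-clonogen} × π₀ ∈ {0.30, 0.50, 0.70} ×
e^α ∈ {1, 1.25, 1.5} × e^γ ∈ {1, 1.2}; censored variants are obtained via
`censor_target=0.30`.

## What the generator does and does not emulate

It emulates exactly the mechanistic data-generating process the test is
derived from: marginal improper survival, balanced two-group design,
independent exponential + administrative censoring.  It does not emulate
features of real registry data — covariate-dependent censoring, ties from
coarse time grids, unbalanced or small groups, model misspecification of
the latent baseline.  Passing tests therefore demonstrate calibration and
power *under the model*; robustness to those violations is untested here
(the test's rank invariance gives some protection against baseline
misspecification, as the statistic depends on times only through ranks).

## Numerical choices and limitations

- p-values are kept at full double precision; rounding is presentation-only.
- The information solve uses `numpy.linalg.solve` after the explicit
  condition-number guard; small negative quadratic forms from roundoff are
  clipped at 0.
- Monte-Carlo scales: 500 replicates reproduce the study; the invariance
  and calibration test batteries use 1000 small replicates.  Monte-Carlo
  SE of a rate p at 500 replicates is √(p(1−p)/500) ≈ 0.02 near p = 0.5.
- Two groups only; no stratification or covariates; no parameter
  estimation under the alternative (point estimates of θ, α, γ would
  require a dedicated fitting procedure).  The test presumes follow-up
  long enough for susceptibles to fail — with heavy administrative
  truncation ω̂₀ underestimates ω₀ and calibration degrades.
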