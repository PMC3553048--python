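# curescore

A model-based score test for detecting **complex survival differences**
between two groups of early-stage cancer patients, where a substantial
fraction of patients is cured by primary treatment.

## The problem

In early-stage disease a marker (a mutation, a copy-number loss, a
histopathological feature) may change survival in ways the logrank test is
blind to: it can alter the *cure fraction*, the *distribution of residual
tumour burden among the uncured*, or the *dynamics of progression* —
producing crossing or late-diverging survival curves with little or no
average hazard shift.

`curescore` models each patient's residual tumour as a latent number K of
clonogens (cells able to regrow the tumour), each clonogen independently
producing a detectable recurrence after a time with survival A₀(t).  The
marginal survival is then the probability generating function of K at
A₀(t).  With K ~ Poisson(ω₀) (the benchmark, group 0):

    S₀(t) = exp(−ω₀ (1 − A₀(t))),         cure fraction e^{−ω₀},

and with K following the flexible Katz count family (ω₁, θ) and a
log-linear latent shift A₁(t) = A₀(t)^{e^α} (group 1):

    S₁(t) = [(1 − θ A₁(t)) / (1 − θ)]^{−ω₁/θ},   cure fraction (1−θ)^{ω₁/θ}.

The Katz family, defined by Pr(x+1)/Pr(x) = (ω + θx)/(1 + x), spans
Binomial (θ<0), Poisson (θ=0) and Negative Binomial (θ>0) counts and lets
two groups share a cure fraction while differing in burden dispersion.

## The statistic

With γ = log(ω₁/ω₀), the null hypothesis of no survival difference is
H₀: θ = α = γ = 0.  The score test evaluates the partial-likelihood score
at H₀ — no estimation under the alternative is needed.  Writing NA(t−) for
the left-continuous pooled Nelson–Aalen cumulative hazard and
ω̂₀ = NA(t_max) for its total, the score is a triple of weighted
logrank-type sums over event times t_j,

    V_r = Σ_j δ_j w_r(t_j) (G_j − Ȳ₁(t_j)/Ȳ(t_j)),

with weights w_α = 1 + log(1 − NA(t−)/ω̂₀), w_θ = 1 − NA(t−)/ω̂₀, w_γ = 1,
and S_H0 = V′ Î⁻¹ V is asymptotically χ²(3) under H₀.  The γ-direction
alone is exactly the classical logrank test, which is reported alongside.

## Worked example

Simulate one study cell — 50 % baseline cure, over-dispersed group-1
burden (θ = 0.78, same cure fraction), earlier relapses (e^α = 1.5) — and
test it:

```bash
curescore simulate --seed 42 --cure 0.5 --theta 0.78 --e-alpha 1.5 --out example.csv
curescore test example.csv
```

```
Katz cure-model score test (H0: theta = alpha = gamma = 0)
==============================================================
subjects: 200  (group 0: 100, group 1: 100)   events: 96
plug-in omega0_hat (total cumulative hazard): 0.6516
--------------------------------------------------------------
test                     statistic   df       p-value
score (3 df)               20.0670    3     0.0001644
logrank                     1.2224    1        0.2689
--------------------------------------------------------------
score vector (alpha, theta, gamma): [16.8703  9.0524  5.3893]
```

The two groups share the cure fraction (both 0.50) and differ only in
burden dispersion and progression dynamics: the logrank test sees nothing
(p = 0.27), while the 3-df score test rejects decisively (p = 0.00016) —
the α- and θ-direction components of the score vector carry the signal.
`omega0_hat ≈ 0.65` estimates the mean clonogen count under the null
(ln 2 ≈ 0.69 here).

The same analysis is available programmatically, statsmodels-style:

```python
from curescore import CureScoreModel
res = CureScoreModel.from_dataframe(df).fit()   # columns time, status, group
print(res.summary()); res.p_value, res.logrank.p_value
```

Power studies: `curescore power --cure 0.5 --theta 0.78 --e-alpha 1.5
--reps 500 --seed 1` estimates rejection rates of both tests for one
scenario cell; `--full-grid` runs the whole 36-cell alternative grid.

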