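# condtau

Conditional multivariate Kendall's tau: kernel estimation, plug-in
bandwidth selection, and Wald-type tests for linear restrictions on
conditional rank correlations.

## The problem

Given p ≥ 2 continuous responses **Y** = (Y₁, …, Y_p) and a scalar
covariate Z, how strongly do the responses move together *at a given level
of Z*, and does that strength change with Z?  The conditional copula C_z
of **Y** given Z = z carries the answer; its multivariate Kendall's tau

τ_z = (2^{p−1} − 1)⁻¹ ( 2^p ∫ C_z dC_z − 1 )

summarises the simultaneous concordance of all p responses at z, in
[−1, 1] for every dimension.  Typical users are biostatisticians and
epidemiologists asking questions such as "does the association between a
stress hormone and cognitive scores change with body-mass index?", and
more generally anyone with multivariate outcomes and a continuous effect
modifier.

`condtau` provides:

* **Estimation** — the kernel-weighted estimator
  τ̂_{z,h} = (2^{p−1}−1)⁻¹ ( 2^p/(1−Σwᵢ²) Σ_{i,j} wᵢwⱼ 1{**Y**ᵢ<**Y**ⱼ} − 1 )
  with Nadaraya–Watson weights wᵢ ∝ k((z−Zᵢ)/h) (Epanechnikov kernel);
* **Bandwidth selection** — a pointwise plug-in minimising a
  jackknife-estimated MSE (Silverman variance pilot, bandwidth-pair
  jackknife for the h² smoothing bias);
* **Testing** — the Wald statistic
  J = (Rτ̂−r)'(R V̂ R')⁻¹(Rτ̂−r) for any linear null H₀: Rτ_z = r on the
  taus at m conditioning points (χ²/F reference with q = rank(R) degrees
  of freedom), with restriction builders for constant conditional
  dependence, conditional independence, equality to the unconditional tau,
  and equality across two samples; V̂ by permutation of margin-adjusted
  tuples, delete-one jackknife, or pairs bootstrap;
* **Simulation** — exact Archimedean samplers (Clayton, Gumbel, Frank, and
  mixtures, frailty construction, covariate-dependent parameters), twelve
  built-in data-generating models, four two-sample scenarios, closed-form
  and Monte-Carlo truth oracles, and a rejection-frequency experiment
  driver for size/power tables.

## Worked example

Simulate 250 observations from a bivariate Gumbel copula whose parameter
is constant in Z (θ = e^{0.5}+1, so the true conditional tau is
1 − 1/(e^{0.5}+1) ≈ 0.6225 at every z), with covariate-dependent margins:

```sh
$ condtau simulate --model 3 --n 250 --seed 7 --out m3.csv
wrote m3.csv (model 3, n=250, seed=7)

$ condtau estimate --input m3.csv --z 3.5
tau(3.5) = 0.547476  [h=0.216843, n_eff=26.5, p=2, raw=0.547476]
```

The estimate at z = 3.5 is 0.547: the plug-in bandwidth h = 0.217 leaves
an effective window of ~27 observations, so a sampling error of this size
(truth 0.6225, sd ≈ 0.12) is expected.  Now test whether the conditional
tau is constant in Z — here the null is true:

```sh
$ condtau test --input m3.csv --hypothesis constant_dependence -B 500 --seed 11
Wald test [constant_dependence]
  conditioning points (12): 2.0970, 2.3956, 2.6079, 2.9159, 3.1396, 3.4935, ...
  bandwidth: 0.7438
  tau estimates: +0.6597, +0.6251, +0.5944, +0.5617, +0.5862, +0.6674, ...
  J = 10.7217 on 11 df (permutation covariance, B=500)
  p-value = 0.4869
```

Twelve conditioning points (5% of n) at covariate quantiles; the tau curve
wobbles around 0.62 within its sampling noise, J = 10.7 on 11 df, and the
p-value 0.49 correctly fails to reject constancy.  The same command with
`--input2` tests equality of two samples' tau curves, and

```sh
condtau experiment --model 6 --n 250 -S 200 --seed 1 --out table.csv
```

reproduces a size/power table cell (rejection percentages at the 1/5/10%
levels) for any built-in model or scenario.

The library API mirrors the CLI: `generate_model`, `select_bandwidth`,
`conditional_kendall_tau`, `wald_test`, `rejection_frequency_experiment`,
all under `import condtau`.

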