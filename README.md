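# riskvoi

Value-of-information analysis for the **development phase** of clinical risk
prediction models.

A risk model fitted on a finite development sample gives uncertain
predictions: a different sample would have produced a different model and,
for some patients, a different treatment decision. `riskvoi` quantifies the
decision-theoretic cost of that uncertainty on the **net benefit** (NB)
scale of decision curve analysis, as the **expected value of perfect
information (EVPI)**: the expected gain in NB from using the *correct*
(strongly calibrated) model instead of the best option available under
current information. It is aimed at model developers deciding whether a
model can advance to validation, should be abandoned, or needs a larger
development sample.

## The model

At risk threshold *z*, treating a patient trades one true positive against
*z*/(1 − *z*) false positives, so for a sample of *n* patients with
predicted risks *π*ᵢ and outcomes *Y*ᵢ,

    NB̂_model(z) = (1/n) Σᵢ I(πᵢ > z) [ Yᵢ − (1 − Yᵢ) z/(1−z) ],

compared against treating no one (NB ≡ 0) and treating everyone. Adopting a
Bayesian view, the unknown correct risks *p*θᵢ replace *Y*ᵢ, and the
posterior P(θ | D) is sampled by refitting the entire model-development
recipe on reweighted data — Bayesian bootstrap (Dirichlet(1,…,1) weights),
ordinary bootstrap (multinomial weights), or a likelihood-based
multivariate-normal draw of logistic coefficients. Averaging over draws
gives posterior-mean net benefits NB̄_model, NB̄_all, and NB̄_max (the NB of
treating exactly those whose correct risk exceeds *z*), and

    EVPI(z)   = NB̄_max(z) − max{0, NB̄_model(z), NB̄_all(z)}
    EVPI_r(z) = [NB̄_max − max(0, NB̄_all)] / [max(0, NB̄_model, NB̄_all) − max(0, NB̄_all)]

EVPI ≥ 0 holds *exactly* per draw (the optimal rule dominates every
alternative term by term); the relative EVPI is ≥ 1 where defined, +∞ when
the model adds nothing but the correct model would, and undefined when even
perfect information adds nothing. Harrell's bootstrap optimism correction
for the empirical decision curve and c-statistic shares the same resampling
loop (`joint_loop`).

## Worked example

Generate a synthetic development sample in the regime of a 30-day
mortality model after myocardial infarction (n = 1000, ~7% event rate,
mixed continuous/binary predictors with truncation and spline transforms),
then run the EVPI analysis with 1000 Bayesian-bootstrap draws:

```sh
riskvoi simulate --preset gusto_like --n 1000 --seed 7 --out ami_dev.csv
riskvoi evpi --input ami_dev.csv --n-draws 1000 --scheme bayesian_bootstrap \
             --seed 7 --out-dir ami_voi --thresholds 0.02
```

Selected rows of `ami_voi/voi_results.csv`:

```
 threshold  nb_model_bar  nb_all_bar  nb_max_bar     evpi   evpi_r  mc_se
      0.01      0.051628    0.051622    0.051786 0.000158 26.55230 0.000005
      0.02      0.042540    0.041945    0.043124 0.000584  1.98013 0.000013
      0.05      0.023690    0.011690    0.025310 0.001620  1.13502 0.000028
      0.10      0.010434   -0.043216    0.012182 0.001748  1.16750 0.000031
      0.20      0.002301   -0.173618    0.003542 0.001241  1.53954 0.000028
```

At the prespecified 2% threshold the model is the best current-information
strategy (NB̄ 0.0425 vs 0.0419 for treat-all), but knowing the correct model
would add a further 0.000584 in NB per patient — a relative EVPI of 1.98,
i.e. perfect information would roughly double the model's expected gain over
the no-model baseline. At this sample size, substantial uncertainty remains
and a larger development sample is worth considering before validation.
The Monte Carlo standard error (`mc_se`) is ~2% of the EVPI, so 1000 draws
are ample. The same pipeline is available in Python via
`riskvoi.compute_voi`; `riskvoi optimism` adds the Harrell-corrected
decision curve and c-statistic (here: apparent c 0.716, optimism 0.035,
corrected 0.681), and `riskvoi sweep` tracks EVPI across development-sample
sizes.

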