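# confbayes

Bayesian modelling and simulation of **informational social conformity**
in two-alternative forced-choice (2AFC) perceptual tasks.

When someone judges a noisy stimulus, then learns that a majority of
peers chose the other option, how often *should* they switch — and how
often do they? Treating each group member as an unbiased observer with
perceived correct rate *p<sub>c</sub>*, the posterior probability that
following the majority is correct, with *n* members (including oneself)
on one side and *m* on the other, is the equal-weight Bayesian Nash
Equilibrium (BNE) benchmark

```
p(correct | n, m) = pc^m (1-pc)^n / [ pc^m (1-pc)^n + (1-pc)^m pc^n ]
```

Real decision makers may over- or under-weight their own signal. The
weighted model raises the private-signal terms to a power β:

```
p_β(correct | n, m) = pc^m (1-pc)^β (1-pc)^(n-1)
    / [ pc^m (1-pc)^β (1-pc)^(n-1) + pc^β pc^(n-1) (1-pc)^m ]
```

β = 1 recovers the BNE; β > 1 overweights private information (less
conformity); β < 1 overweights social information (more). For
0.5 < *p<sub>c</sub>* < 1 the posterior is strictly decreasing in β, so
β is identifiable from observed conformity rates — by direct inversion
(`invert_beta`) or by maximum likelihood over trials
(`BetaWeightEstimator`, an sklearn-style estimator with `fit` /
`predict_proba` and fitted `beta_`, `se_` attributes).

The package is aimed at computational cognitive scientists who want to
(a) compute these posteriors, (b) simulate synthetic three-arm cohorts
of probability-matching agents performing the scripted-peer conformity
task, and (c) run the standard nonparametric behavioral pipeline
(Wilcoxon, Kruskal-Wallis, Friedman, Mann-Whitney contrasts with
Benjamini-Hochberg FDR) on trial-level CSV data — simulated or real.
See `docs/methods.md` for the model's assumptions and limitations.

## Worked example

Posteriors from the command line (printed at 6 d.p.):

```bash
$ confbayes bne --pc 0.5524 --n 1 --m 3
0.603661
$ confbayes bne --pc 0.5524 --n 1 --m 3 --beta 1.815
0.562002
```

With a subjective accuracy of 55.24%, a Bayesian who is outvoted 3-to-1
should follow the majority 60.4% of the time; an agent weighting its
private signal β ≈ 1.8 times as much conforms only 56.2% of the time.

Simulate a full three-arm cohort (20/21/20 subjects × 60 trials, arms
calibrated to a published tDCS study's group summaries) and summarize
conformity by net public information (NPI = signed count of peers
agreeing minus disagreeing with the first response):

```python
>>> from confbayes import simulate_experiment, summarize, estimate_beta_mle
>>> from confbayes.simulate import npi_to_nm
>>> data = simulate_experiment(seed=42)
>>> print(summarize(data)["by_npi"].round(3).to_string(index=False))
 npi  anodal_mean  anodal_se  anodal_n  sham_mean  sham_se  sham_n  cathodal_mean  cathodal_se  cathodal_n
  -3        0.575      0.035        20      0.581    0.032      21          0.612        0.038          20
  -1        0.400      0.035        20      0.434    0.035      21          0.540        0.034          20
   1        0.956      0.012        20      0.959    0.010      21          0.989        0.005          20
   3        0.984      0.006        20      1.000    0.000      21          1.000        0.000          20
```

Rows are NPI levels, columns are group mean (between-subject SE, n) of
the subject-level conformity proportions: near-ceiling conformity on
congruent trials (NPI > 0), graded conformity under conflict, and the
cathodal > sham > anodal ordering on incongruent trials. Recover the
sham arm's private-information weight from its incongruent trials:

```python
>>> inc = data[(data["group"] == "sham") & (data["npi"] < 0)]
>>> beta, se = estimate_beta_mle(
...     [(*npi_to_nm(v), c) for v, c in zip(inc["npi"], inc["conformed"])],
...     p_c=0.5524)
>>> print(f"sham beta = {beta:.3f} (SE {se:.3f})")
sham beta = 1.892 (SE 0.382)
```

consistent with the generating value β ≈ 1.82 (private information
overweighted, conformity below the Bayesian benchmark).

Other CLI entry points: `confbayes design` (balanced trial schedules),
`confbayes simulate` (trial-level CSV), `confbayes analyze` (summary
tables + test battery), `confbayes fit-beta`, and `confbayes run`
(end-to-end report directory with seed/config-hash metadata).

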