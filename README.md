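# tobitkit

Tobit (censored-normal) models for two everyday analyses that break when a
measurement scale has a **ceiling or floor**: the dependent-sample
(paired) *t*-test and moderated regression.

When a scale is too easy or too hard, a mass of respondents lands on the
maximum or minimum score.  Those bound values are proxies for unobserved
true scores, and analysing them as if they were true scores biases mean
differences, regression slopes and — especially — interaction
coefficients, inflating Type-I error far past its nominal level.
`tobitkit` is for behavioural, psychological and medical researchers (and
methodologists benchmarking such analyses) who need censoring-aware
versions of these two tests plus the machinery to verify their operating
characteristics by simulation.

## The models

Observed scores are clipped latent true scores:

```
y = a    if y* <= a        (floor)
y = y*   if a < y* < b
y = b    if y* >= b        (ceiling)
```

**Paired t-test.**  The pre/post true scores are bivariate normal with
means (μ₁, μ₂) and covariance [[v₁, c], [c, v₂]].  The likelihood uses the
bivariate density for interior pairs, a density × conditional tail
probability when one score is censored, and a quadrant (rectangle)
probability when both are.  The mean-difference test divides μ̂₂ − μ̂₁ by
its observed-information standard error, referred to t(N−1), with effect
size d = (μ̂₂ − μ̂₁)/√(v̂₁ + v̂₂ − 2ĉ).

**Moderated regression.**  y\* = β₀ + β₁x\* + β₂z\* + β₃x\*z\* + e with
(x\*, z\*) bivariate normal.  Censoring confined to y gives the classical
Tobit likelihood; censoring in x\* and/or z\* (which propagates into the
interaction term) is handled by integrating the censored exogenous
dimensions out of the joint likelihood (Gauss–Legendre quadrature), or by
Gibbs sampling with data augmentation of all censored true scores.

Both models fit by maximum likelihood (`fit()`) or MCMC (`fit_bayes()`,
diffuse N(0, 10⁶) priors on locations and Gamma(0.001, 0.001) priors on
precisions; inference via 95% percentile credible intervals and the
Gelman–Rubin PSRF convergence diagnostic).

## Worked example

```python
import numpy as np
from tobitkit import PairedCondition, gen_paired, PairedTTest, TobitPairedTTest

# pre/post scores with a ceiling: true effect d = 0.5, 20% of pre-test
# scores at the ceiling, post-test SD 1.5x the pre-test SD
cond = PairedCondition(d=0.5, sdr=1.5, rho=0.5, cp=0.2, n=200, seed=42)
sample = gen_paired(cond)
print("true mean difference:", round(cond.mu2, 3))

naive = PairedTTest(sample).fit()
print("conventional:", round(naive.mean_diff, 3), "p =", round(naive.p_value, 4))

fit = TobitPairedTTest(sample).fit()
tt = fit.ttest()
print("tobit ML    :", round(tt.mean_diff, 3), "p =", round(tt.p_value, 4),
      "d =", round(tt.cohens_d, 3))

bayes = TobitPairedTTest(sample).fit_bayes(seed=1)
print("tobit Bayes :", round(bayes.mean_diff, 3),
      "95% CrI:", tuple(round(v, 3) for v in bayes.mean_diff_interval()))
```

Output:

```
true mean difference: 0.661
conventional: 0.234 p = 0.0
tobit ML    : 0.624 p = 0.0 d = 0.551
tobit Bayes : 0.642 95% CrI: (0.452, 0.844)
```

The conventional analysis underestimates the true mean difference 0.661 by
almost two thirds (ceiling clipping shrinks the post-test mean more than
the pre-test mean); both Tobit fits recover it to within sampling error,
with the ML effect size near the generating d = 0.5.

The command line mirrors the library:

```bash
tobitkit paired --csv scores.csv --pre y1 --post y2 --ceiling 12 --estimator ml
tobitkit modreg --csv data.csv --y post --x pre --z vocab \
    --y-ceiling 12 --x-ceiling 12 --estimator bayes --seed 7
tobitkit simulate --design paired --method conventional \
    --d 0 --sdr 1.5 --rho 0.5 --cp 0.1 --n 100 --reps 1000 --seed 1
```

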