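# hubbell

Neutral-theory analysis of microbiome species abundance distributions:
sampling-formula fits, exact neutrality tests, and treatment-level
statistics, built for 16S OTU tables such as subgingival plaque surveys.

## The scientific problem

Is a microbial community assembled by deterministic niche forces
(competition, habitat filtering) or by the stochastic demography of
Hubbell's unified neutral theory (ecological drift, immigration,
speciation)? The neutral theory is a quantitative null model: it predicts
the full probability distribution of a sample's species abundance
configuration `D = (n_1, ..., n_S)` from two parameters, so an observed OTU
table can be *tested* against it rather than merely described.

Two sampling formulas are implemented:

- **Ewens formula** (no dispersal limitation, immigration probability
  m = 1):

  `Pr(D | θ, J) = J! θ^S / (∏_i n_i · ∏_a φ_a! · ∏_{k=1}^{J} (θ + k − 1))`

  where `J` is the number of reads, `S` the number of species, `φ_a` the
  number of species with abundance `a`, and `θ` the fundamental biodiversity
  number (`θ = J_M ν / (1 − ν)` for metacommunity size `J_M` and speciation
  rate `ν`). `S` is sufficient for `θ`; the MLE solves
  `S = Σ_{k=0}^{J−1} θ/(θ+k)`.

- **Etienne formula** (dispersal limitation through the immigration
  parameter `I = m(J−1)/(1−m)`):

  `Pr(D | θ, m, J) = J!/(∏ n_i ∏ φ_a!) · θ^S/(I)_J · Σ_{A=S}^{J} K(D,A) I^A/(θ)_A`

  with `K(D,A)` built from unsigned Stirling numbers of the first kind; it
  reduces to the Ewens formula as m → 1. `(θ, m)` are fitted jointly by
  maximum likelihood.

Per sample, the **exact neutrality test** (a Monte-Carlo / parametric
bootstrap hybrid) simulates artificial communities at the fitted
`(θ, I, J)`, evaluates each one's likelihood `P_s` under the same formula,
and refers the deviance `D = 2(ln P_0 − mean ln P_s)` — null model
`L_0` = neutral simulation average, alternative `L_1` = observed sample
`P_0` — to χ²(1). Samples with (BH-adjusted) p > 0.05 *pass*, i.e. are
consistent with neutrality. Group-level routines then compare passing rates
between clinical treatments with Fisher's exact test and the fitted θ
values with one-way ANOVA plus Bonferroni pairwise contrasts.

## Worked example

```python
import numpy as np
from hubbell import (fit_etienne, exact_neutrality_test,
                     simulate_local_community, m_to_I)
from hubbell.synthetic import niche_community

neutral = simulate_local_community(15.0, m_to_I(0.9, 1500), 1500,
                                   np.random.default_rng(2), "neutral")
niche = niche_community("lognormal", {"S_star": 100, "sigma": 2.0}, 3000,
                        np.random.default_rng(404), "niche")
for sample in (neutral, niche):
    fit = fit_etienne(sample)
    v = exact_neutrality_test(sample, fit, n_sims=100, seed=7)
    print(sample.sample_id, round(fit.theta, 3), round(v.deviance_D, 2),
          round(v.p_value, 4))
```

prints (as in `examples/02_exact_neutrality_test.py`):

```
 neutral: theta= 19.348 m=0.29109  logL_obs=   -82.30  mean sim logL=   -81.64
          D=  -1.32  p=1.0000  rank_p=0.376  PASSES (consistent with neutrality)
   niche: theta= 20.226 m=0.34069  logL_obs=  -108.52  mean sim logL=  -114.73
          D=  12.42  p=0.0004  rank_p=0.911  REJECTED
```

The neutral sample's likelihood is typical of its own fitted model (D ≤ 0,
p = 1: passes). The niche sample's abundance distribution is *more*
probable than neutral demographic noise allows — the signature of
niche-regularised abundances — and is rejected (p = 0.0004). The `rank_p`
column is the ordinary Monte-Carlo rank of the observed likelihood among
the simulated ones, reported as a diagnostic.

The other scripts in `examples/` demonstrate parameter fitting
(`01`), the treatment-level statistics including the pairwise Fisher tests
on passing counts 3/17, 5/22, 6/22 → p = 1, 0.704, 1 (`03`), and the full
pipeline on a synthetic study with a ground-truth confusion table (`04`).

A thin CLI wraps the pipeline for shell use:

```bash
hubbell fixture --out fx --seed 1
hubbell run-all --otu fx/fixture.shared --treatments fx/treatments.tsv \
        --sims 100 --seed 1 --out results_dir
```

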