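# Methods

## Model and procedure

The package treats each community sample (one column group of an OTU table)
as an abundance configuration `D = (n_1 ≥ n_2 ≥ ... ≥ n_S ≥ 1)` with
`J = Σ n_i` reads. Zero-count taxa are dropped per sample before any
likelihood is computed: the sampling formulas are defined on present
species only, and absence in a finite sample carries no information the
formulas can use.

**Ewens likelihood and θ estimation.** The Ewens sampling formula gives the
neutral probability of `D` without dispersal limitation. Its log is
evaluated entirely through log-gamma (no raw factorials; `J` reaches 10^4).
Because `S` is sufficient for θ, the MLE is the root of
`S = Σ_{k=0}^{J−1} θ/(θ+k)`, found by Brent's method on log θ over
[1e−8, 1e8] (the score is strictly increasing in θ, so the bracket is
safe); tolerance 1e−12 on log θ. Boundary cases: `S = J` (all singletons)
has θ̂ = +∞ and `S = 1` has θ̂ = 0; both are returned with a `degenerate`
flag and logL = 0 (the limiting probability is 1), and reported as "NA"
rather than a capped number.

**Etienne likelihood.** The dispersal-limited formula needs the
coefficients `K(D, A)` for `A = S..J`, which sum over allocations of
immigrant ancestors `a_i` to species. They are computed as the sequential
convolution of per-species vectors
`c_i(a) = ln[ s(n_i, a) (a−1)! / (n_i−1)! ]`, `a = 1..n_i`, where
`s(n, a)` are unsigned Stirling numbers of the first kind. Two numerical
commitments matter here:

- Stirling rows are built by the recurrence `s(n+1,a) = s(n,a−1) + n·s(n,a)`
  in log space (they overflow double precision for n > 170 in linear
  space) and cached; a new row grows from the largest cached row below it.
- The convolution itself is carried out exactly in log space with
  log-sum-exp over a strided matrix, chunked to bound memory. Because every
  summand is positive and finite in log space, no underflow is possible and
  no arbitrary-precision fallback is required. `K(D, A)` depends only on
  the abundance multiset, so it is computed once per sample and reused for
  every likelihood evaluation during fitting and testing.
- The Pochhammer term `ln (I)_J` is computed as an explicit sum
  `Σ ln(I + k)` rather than a difference of log-gammas: for m near 1,
  I ~ 10^12 and the gammaln difference loses ~1e−3 absolute accuracy to
  cancellation, which would mask the m → 1 convergence to the Ewens
  likelihood; the explicit sum is accurate to ~1e−11.

**Joint (θ, m) fitting.** The negative log-likelihood is minimised by
Nelder-Mead on the unconstrained scale `(ln θ, logit m)`, with
`ln I = ln(J−1) + logit m` computed directly from the optimiser variable
(no cancellation as m → 1; logit m capped at ±60 to keep I inside double
range). Three restarts from m₀ ∈ {0.5, 0.9, 0.999}, θ₀ at the Ewens MLE;
tolerance 1e−8 on the log-likelihood, at most 2000 evaluations per restart.
`S = 1` samples are fitted but flagged `weakly_identified` (m carries
almost no information there). The convolution order over species does not
change `K` (asserted in tests).

**Neutral community simulator.** The null datasets are drawn by the
sequential urn / genealogy scheme consistent with the Etienne formula:
individual j immigrates with probability `I/(I+j−1)`, otherwise copies a
uniformly chosen earlier individual; each immigrant lineage draws its
species from a Chinese-restaurant process with concentration θ over
lineages. With the I = +∞ sentinel (m̂ at the boundary) every individual
immigrates and the scheme reduces to the plain Ewens sampler. Each
replicate uses its own RNG stream keyed by (seed, replicate index), so
batches are reproducible independent of execution order. The simulator is
validated against the likelihoods it must match: the closed-form
`Pr(single species of 2 | θ=1, I=1) = 3/4` and the Ewens richness
expectation `E[S] = Σ θ/(θ+k)`.

**Exact neutrality test.** For each observed sample: simulate `n_sims`
communities (default 100; 1000 available) at the fitted `(θ̂, Î, J)`;
evaluate each simulated community's log-likelihood at the generating
`(θ̂, m̂)` with its own `K` coefficients; form the deviance
`D = 2(ln P_0 − mean ln P_s)` and refer it to χ²(1), one-sided (negative D
is clamped to 0, p = 1). In the likelihood-ratio convention the *null*
model `L_0` is the neutral expectation — the simulation average — and the
observed sample is the alternative `L_1`; rejection therefore means the
observed configuration is significantly **more probable** than typical
neutral draws. That is the niche signature this test detects: a
niche-regularised community carries less demographic randomness than
neutrality predicts, so it sits near the mode of the fitted sampling
distribution while genuine neutral draws scatter into less probable
configurations. The averaging is done on log-likelihoods, not on raw
likelihoods (which underflow at J ~ 10³); this is recorded as an
interpretation of "mean likelihood".

Two deliberate consequences of this construction:

- **One-sided blind spot.** A community *less* probable than typical
  neutral draws (for example a near-perfectly even abundance vector) gives
  D < 0 and passes. The rank-based Monte-Carlo p-value (`rank_p`, the
  position of `ln P_0` among the `ln P_s`) is reported alongside every
  verdict as a diagnostic for exactly this case; it is not the decision
  rule because the stated procedure is the χ²₁ deviance.
- **Conservatism under the null.** `ln P_0` is evaluated at parameters
  maximised on the observed sample while the `ln P_s` are not, which biases
  D upward slightly; measured type-I error at α = 0.05 on neutral fixtures
  (J = 100, θ = 10, m = 0.9, 100 simulations, 50 replicates) is 0.10,
  inside the binomial envelope [0, 0.16] around the nominal level.

A `refit_sims` mode re-estimates `(θ, m)` on every artificial community
instead (removing that asymmetry at ~100× the cost); it is provided for
sensitivity analysis, with the plug-in mode as default.

**Multiple testing and group statistics.** All samples analysed in one run
form a single Benjamini-Hochberg family per formula (the step-up rule via
statsmodels, cross-checked against hand-derived values in tests); the final
pass/fail call uses the adjusted p at α = 0.05. Passing rates are compared
pairwise between treatments with the two-sided point-probability Fisher
exact rule — sum the hypergeometric probabilities of all tables no more
probable than the observed one (relative tolerance 1e−7), the convention of
R's `fisher.test`, which returns p = 1 exactly when the observed table is
the hypergeometric mode. θ values are compared by one-way fixed-effects
ANOVA on the raw scale (no transform) followed by pooled-variance t-tests
with Bonferroni multiplication by the number of pairs; degenerate θ
estimates (±∞ sentinels) are excluded with a warning.

## Synthetic data: what it emulates and what it does not

`hubbell.synthetic` generates study-shaped fixtures: three treatments
(Healthy 17, BoP 22, NonBoP 22 samples), read depths uniform on 500–4000
(`paper_scale` lifts the cap to 10130, the full observed range), richness
in the tens to low hundreds, and a global pool of 673 OTU labels with
lognormal weights used to place each sample's species into shared table
columns. Each sample is neutral with probability `neutral_fraction`
(default 0.25, near the ~23% neutrality passing rate observed in oral
communities) with θ drawn per treatment — Healthy ~ N(15, 5), disease
groups ~ N(27, 6), mirroring the observed healthy-vs-disease diversity
contrast — and m uniform on (0.8, 0.9999); otherwise it is
niche-structured: lognormal relative abundances (σ = 2 default) or
geometric (ratio 0.3 default), multinomially sampled to depth J. A truth
table records each sample's generator and parameters.

The fixtures contain no sequencing error, chimeras, OTU-clustering
artifacts, or subject-level pairing (two sites per subject are treated as
independent, as the analysis itself does). Passing tests on fixtures
therefore demonstrates the statistical machinery — calibration, power
against the implemented niche generators, parameter recovery — not the
behaviour of the method on real amplicon data. Power is strongly
shape-dependent: measured at 100 simulations per test, lognormal σ = 2
communities at depths 500–4000 are rejected at ~60%, while geometric
ratio-0.3 communities (S ≈ 7 realised species, extreme dominance) are
rejected at only ~20% even at J = 2000 — strong dominance is exactly what
a dispersal-limited neutral model can mimic, so low-richness geometric
SADs are a weak alternative for this test.

## Problem sizes used in the test suite

Stochastic properties are asserted at desk scale, chosen so the whole suite
and the acceptance script each run in minutes on one CPU: type-I
calibration uses 50 neutral fixtures at J = 100 with 100 simulations each;
power uses 20 geometric fixtures at J = 2000; parameter recovery uses 50
communities at (θ = 20, m = 0.9, J = 500); normalization oracles enumerate
all integer partitions up to J = 8 (Ewens) and J = 6 (Etienne); the
simulator/likelihood agreement uses 10⁵ two-individual draws. Larger runs
(e.g. 1000 simulations per sample) use the same code paths through the
`n_sims` parameter.

## Known limitations

- The χ²₁ reference for a Monte-Carlo mean comparison is heuristic; the
  deviance is not an actual likelihood-ratio statistic with known
  asymptotics. The measured calibration above, not theory, is the
  justification for using it at α = 0.05, and `rank_p` is the
  conventional alternative.
- m̂ is weakly identified when m is near 1 or S is small; recovery tests
  bound its median, not individual estimates. θ̂ and m̂ are correlated, so
  single-sample m values should be read qualitatively.
- Samples are treated as independent even when subjects contribute several
  sites; no mixed-effects structure is modelled.
- Raw-read processing (quality control, OTU picking, taxonomy) is out of
  scope; the package starts from an OTU table.
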