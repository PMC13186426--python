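# Methods

## Model

Tracts are modelled as exchangeable draws from a finite mixture of
multivariate Bernoulli distributions. With `n` tracts and `p` binary
disadvantage indicators, the observed-data likelihood is

```
L(pi, theta | X) = prod_i sum_k pi_k prod_j theta_{j|k}^{x_ij} (1 - theta_{j|k})^{1 - x_ij}
```

augmented with latent allocations `z_i` (`P(z_i = k) = pi_k`) for
computation. Priors: `K ~ Poisson(lambda)` truncated to `{1..K_max}`,
`pi | K ~ Dirichlet(gamma, ..., gamma)`, `theta_{j|k} ~ Beta(alpha, beta)`,
with defaults `lambda = 1`, `K_max = 50`, `gamma = alpha = beta = 1`. The
Poisson prior penalizes extra components a priori (ratio `lambda / (K+1)`
per added component), so the posterior concentrates on parsimonious K while
`K_max` merely truncates.

Because the Dirichlet and Beta priors are conjugate, `pi` and `theta` are
integrated out exactly. The sampler state is `(K, z)` only, with the
collapsed joint

```
log p(X, z | K) = log Γ(Kγ) − log Γ(Kγ + n)
                + Σ_k [log Γ(n_k + γ) − log Γ(γ)]
                + Σ_{k,j} [log B(α + s_jk, β + n_k − s_jk) − log B(α, β)]
```

evaluated from the sufficient statistics `n_k` (rows per component) and
`s_jk` (per-component column sums); no likelihood evaluation ever rescans
`X`.

### State-space convention

Components are labeled `1..K` and **empty components are allowed**: `K` is
the model dimension carrying the truncated-Poisson prior, and the quantity
reported per retained draw (`k_trace`) is the count of *nonempty*
components, which is what profile selection uses. An alternative bookkeeping
that deletes empty components after every sweep was considered and rejected:
ad-hoc label compaction changes the density on the labeled state space and
breaks detailed balance. With empties allowed, every move below is exactly
reversible, and the sampled posterior is verified against exhaustive
enumeration over all `(K, z)` on small instances.

### Moves

Each sweep applies one move drawn from `move_mix`, default
(0.70, 0.10, 0.10, 0.10):

* **Gibbs reallocation pass** (0.70): every row is removed from the
  sufficient statistics and redrawn from its collapsed full conditional
  `p(z_i = k | z_{-i}) ∝ (n_k^{-i} + γ) Π_j (α + s_jk^{-i})^{x_ij}
  (β + n_k^{-i} − s_jk^{-i})^{1−x_ij} / (α + β + n_k^{-i})`, where the
  denominator appears once per variable. The pass is a compiled (numba)
  kernel driven by pre-generated uniforms, so all randomness flows from one
  generator.
* **Block reallocation** (0.10): choose an ordered component pair
  `(k1, k2)`; each member of `k1` is proposed to move to `k2` with
  probability 1/2; accepted with the collapsed-joint ratio times the
  subset-proposal ratio `2^{n_k1 − n_k2 − m}`.
* **Eject** (0.10): propose `K → K+1` by splitting a uniformly chosen
  source component; each member moves to the new (last-labeled) component
  with probability `u ~ Beta(a_e, a_e)` (`a_e = 1`, i.e. uniform), and `u`
  is marginalized out of the proposal density, giving the Beta-function
  weight `B(a_e + m, a_e + n_0 − m)/B(a_e, a_e)` in the Metropolis–Hastings
  ratio together with the collapsed-joint ratio and the prior ratio
  `lambda / (K+1)`. Proposals at `K = K_max` auto-reject.
* **Absorb** (0.10): the exact reverse — merge the *last* component into a
  uniformly chosen receiver; its acceptance ratio is the reciprocal
  structure of eject. Proposals at `K = 1` auto-reject. Restricting
  absorption to the last label makes the eject/absorb pair bijective
  without any relabeling step; label mobility is provided by the Gibbs and
  block moves, and exactness is enforced by the enumeration test rather
  than argued informally.

Chains are initialized overfitted at `K = K_max` with uniform random
allocations; absorb moves prune redundant components within the burn-in.

### Tempering

`n_chains` chains (default 4) target the posterior raised to temperatures
`t_c = 1/(1 + 0.3(c−1))`; proposal terms are never tempered. After every
sweep, `swap_attempts_per_sweep` adjacent-pair swaps are attempted with the
standard acceptance `min(1, exp((t_c − t_{c+1})(logπ_{c+1} − logπ_c)))`.
Only cold-chain states are retained. On well-separated study-scale data the
cold posterior is sharply peaked and swaps are rare; the ladder mainly helps
on small or weakly separated instances. The degenerate ladder
`n_chains = 1` reduces to the plain collapsed sampler.

Default run lengths (11,000 sweeps, 1,000 burn-in, thin 10) are
desk-scale choices; the recovery analyses in the tests and the acceptance
script use 3,800 sweeps (burn-in 800, thin 5) at n = 1478, which match the
exact row-wise membership posterior to three decimals on the shipped
fixtures.

## Post-processing

`K_map` is the modal nonempty-component count (ties to the smaller value).
Conditional on `K_map`, draws with a different nonempty count are excluded
(their number is logged). The pivot is the retained `K_map` draw with the
highest log posterior. Each draw is aligned to the pivot by the label
permutation minimizing positional disagreement — the ECR relabeling —
solved *exactly* as a `K_map × K_map` assignment problem on the label
co-occurrence matrix (`scipy.optimize.linear_sum_assignment`), not
greedily. Parameter summaries are Rao-Blackwellized conditional posterior
means, `E[theta_{j|k} | z] = (α + s_jk)/(α + β + n_k)` averaged over
aligned draws (lower variance than re-sampled theta draws, identical
expectation); membership probabilities are per-tract label frequencies.
Output profiles are ordered by decreasing posterior share, so profile 1 is
always the largest — a presentation convention only. Hard assignment is by
row argmax with ties to the lowest profile index.

## Preprocessing

Raw indicators are dichotomized at their empirical state medians (mean of
the central order statistics at even n). Direction rules: standard
variables code 1 strictly above the median; median household income is
reverse-coded (at/above the median codes 0, below codes 1 = low income);
incomplete plumbing, whose state median is 0, codes 1 for any positive
value. Ties at the median on standard variables code 0 — the sole stated
tie rule (income) places ties on the non-disadvantaged side, and the same
convention is extrapolated to the other variables. Tracts with missing
values are dropped with a logged count rather than imputed. Proportion
variables are validated to `[0, proportion_scale]` (set
`proportion_scale=100` for percent-scale extracts); income is exempt.

## Synthetic data

The tract generator draws `z_i ~ Categorical(pi_true)` and
`x_ij ~ Bernoulli(theta_true[j, z_i])`. The default study-scale truth uses
n = 1478, p = 14, K_true = 5 with exposure probabilities 0.08/0.92 arranged
in fixed archetype patterns (an all-advantaged profile, an all-disadvantaged
profile, and three mixed patterns) and weights (0.32, 0.25, 0.20, 0.14,
0.09) — dimensions and share ordering mirroring the Massachusetts analysis
this package targets. The raw-table generator emulates the skewed bounded
ACS margins: the latent binary exposure selects the upper or lower half of
a right-skewed Beta(1.3, 6) marginal (lower/upper half of a lognormal for
income, whose disadvantage direction is reversed; zero versus positive for
plumbing), so dichotomizing at the empirical medians recovers the latent
binary matrix except for tracts near the median when a column's marginal
exposure rate deviates from 1/2. The generator is deliberately not a model
of real ACS sampling error or spatial autocorrelation: passing recovery
tests shows the estimator works when the model holds and identifies
distinct exposure patterns, not that five profiles exist in any particular
real extract.

The patient generator produces `outcome ~ Bernoulli(logistic(intercept +
profile effect + covariate effects))` over declared categorical level sets
(year of diagnosis, age group, insurance, facility type). The default
intercept `log(0.823/0.177)` matches an ~82% marginal prevalence of
guideline-concordant care.

## Outcome regression

Dummy-coded design with intercept; profile 1 and the alphabetically first
level of each covariate are the default references. Priors are independent
Normal(0, 2.5²) on indicator coefficients and Normal(0, 10²) on the
intercept — weakly informative, guarding against separation in sparse
profile-by-covariate cells. Because all predictors are categorical, rows
are collapsed to unique covariate patterns with binomial likelihoods, making
posterior evaluations O(#patterns) rather than O(n). The exact posterior is
sampled by random-walk Metropolis with proposal covariance
`(2.38²/d) · H⁻¹`, `H` the log-posterior Hessian at the mode (found by
BFGS + Newton-CG); chains start from mode-centred overdispersed points.
Acceptance sits near 0.25 and effective sample sizes are reported (arviz).
Posterior-mode estimates with near-flat priors (`prior_scale = 1e6`)
coincide with the Newton–Raphson MLE, which the tests verify against an
independent implementation. Patients are linked to profiles by hard
assignment (two-stage analysis); propagating membership uncertainty into
the regression is out of scope and can attenuate estimates when
assignment probabilities are low.

## Yost-type SES comparator

Seven SES variables (median household income, education, share below 150%
poverty, median house value, median gross rent, unemployment, working-class
occupation) are sign-aligned so larger = higher SES, standardized, and
projected on the leading eigenvector of their correlation matrix; the
component is oriented to correlate positively with income, and tracts are
cut into score quintiles (1 = lowest SES, stable-order ties). The variable
list and the disadvantage set are overridable, since published
constructions differ in which columns feed each slot.
`compare_indices` cross-tabulates quintiles against profiles with a
chi-square association statistic — descriptive only.

## Numerical and degenerate-case choices

* All collapsed-math ratios are computed in log space; impossible
  configurations propagate `-inf` rather than raising, so Metropolis
  ratios evaluate rejections naturally.
* `k_trace` ties in `K_map` selection break toward the smaller K.
* Zero-variance binary columns are permitted in the sampler; zero-variance
  SES variables are an error in the PCA (undefined correlation).
* Crude odds ratios raise on zero cells unless a continuity correction
  (0.5 added to every cell) is requested.
* Pipeline stage seeds are spawned deterministically from the single run
  seed (`numpy SeedSequence` spawn keys), so a config reproduces every
  output bit-identically.

## Known limitations

* Emissions are conditionally independent Bernoullis; bounded continuous
  indicators are dichotomized, losing within-side information. A Beta
  emission mixture would use the full distributions and is out of scope.
* The two-stage outcome analysis conditions on hard assignments.
* No spatial structure: tracts are exchangeable given their profile.
* MC³ swap rates collapse on large, well-separated data; the ladder is
  then inert (harmless, but no acceleration).
* The enumeration-backed exactness guarantee applies to instances small
  enough to enumerate; at scale, correctness evidence is indirect
  (recovery, agreement with the row-wise oracle posterior, stats
  consistency).
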