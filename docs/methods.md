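# Methods

## The estimation problem

Marked animals are released in yearly cohorts; some are later found dead
(dead-recovery or band-recovery data), and in the joint design some are
also re-sighted alive.  Under the Seber parameterization the parameters
are the interval survival probability `s`, the probability `r` that an
individual dying in an interval is found and reported in that interval,
and (joint data) the per-occasion live re-encounter probability `p`.  All
parameters are time-constant here; a recovery can happen only in the
interval of death, and at most once per individual.

The same likelihood can be reached by three routes, and this package
implements all of them so that they can be compared on identical data:

1. **State-space models** with explicit latent states sampled by MCMC.
   - *Single state*: `z ∈ {alive, dead}` with Bernoulli survival and a
     Bernoulli recovery trial on the death interval.  For joint data the
     recorded histories are split into a binary live-encounter layer and a
     binary dead-recovery layer, each with its own Bernoulli observation
     model, so the single-state formulation handles joint data too.
   - *Classical multistate*: latent states {alive, recently dead, long
     dead}, transition matrix rows (s, 1−s, 0), (0, 0, 1), (0, 0, 1), and
     a stochastic observation matrix in which only "recently dead"
     individuals can be recovered (with probability `r`); live
     individuals are seen with probability `p` in the joint variant.
   - *Reparameterized multistate* ("BPA" variant): the recovery event is
     folded into the state process — states {alive, recently dead and
     recovered, other dead}, transition row (s, (1−s)r, (1−s)(1−r)) — so
     the observation matrix for the recovery becomes deterministic.
2. **Marginalized (forward-algorithm) likelihoods** that sum the latent
   states out, so MCMC acts on (s, r, p) only; optionally evaluated on
   pooled unique histories weighted by their frequencies.
3. **Multinomial m-array likelihoods** over release-by-first-reencounter
   count tables, with cell probabilities `s^(k−t−1)(1−s)r` (single state)
   or alternating products of the transition matrix with a diagonal
   detection matrix (multistate, with live re-encounters re-releasing the
   individual).

For time-constant parameters every capture history factorizes exactly
into m-array cells, so all routes give *identical* log-likelihood values
(the multinomial coefficient, constant in the parameters, is dropped).
The test suite asserts this equivalence to 1e-10 and checks that each
route's probabilities over all possible observation patterns sum to one
by exhaustive enumeration at T=4.

## Samplers

All parameters carry Uniform(0,1) = Beta(1,1) priors.

**State-space models** alternate a systematic single-site Gibbs scan over
the unknown latent states with conjugate parameter draws.  Every
parameter is a Bernoulli/categorical success probability, so its full
conditional given the latent states is Beta(1 + successes, 1 + failures);
with no trials the draw falls back to Beta(1,1), which is the exact
conditional.  Latent sites are redrawn one at a time in occasion order
from the full conditional given their temporal neighbours and the
observations; individuals recovered dead have fully determined latent
trajectories and are never updated.  A site whose full conditional has
zero support is left unchanged and counted.

This single-site scan is deliberate: it is the update scheme of the
general-purpose BUGS-family samplers, and it is the mechanism of the
documented failure of the classical multistate model.  Because "recently
dead" must be followed by "long dead" with probability one, a single-site
move can never place a death at an interior occasion unless the successor
site is already "long dead"; from an all-alive start, deaths can enter
only at the final occasion, and from other starts the death time is
essentially frozen at its initialization.  The resulting posteriors are
strongly biased and initialization-dependent while still passing R-hat.
The package reproduces this behaviour and does not attempt to repair it
(joint block updates of latent trajectories are out of scope); the
reparameterized variant, whose dead states mix freely, is the in-scope
fix.

**Marginalized and multinomial models** are fitted by random-walk
Metropolis on logit-transformed parameters, updated one coordinate at a
time with the flat-prior Jacobian included.  Step sizes adapt in batches
of 50 iterations toward an acceptance rate of 0.35 during burn-in only,
so the post-burn-in chains are valid MCMC.

**Initialization.**  Parameter chains start from prior draws.  Latent
states are initialized by one of three strategies for individuals whose
fate after the last encounter is unknown: `alive` (survive to the study
end), `dead` (die immediately after the last encounter), or `random`.
`random` draws the death occasion uniformly from {last encounter + 1,
..., T} together with the survive-to-end outcome, so every legal
completion has positive probability; the boundary case of an individual
encountered on the final occasion is necessarily left alive.

**Diagnostics.**  Three chains by default; convergence is declared at
rank-normalized split-chain R-hat < 1.1 (arviz), credible intervals are
equal-tailed 2.5–97.5% quantiles of the pooled post-burn-in draws, and
the efficiency metric is the minimum-over-parameters bulk ESS per second
of sampling time.  Default chain lengths reflect how fast each family
mixes: state-space models run 5000 iterations with 2000 burn-in,
marginalized/multinomial models 3000 with 1000, and the joint
single-state state-space model (helped by the live-encounter
information) 3000 with 1000; the "desk" profile used by the tests and
the acceptance script halves both numbers.

## Synthetic data

The generator is the study design itself, not an approximation of it:
per-occasion cohorts of newly marked individuals (default 8 occasions,
100 releases on occasions 1–7, 700 individuals), latent survival
simulated first, then the recovery layer, then (joint data) the live
encounter layer.  Generating parameters are drawn per dataset from
s ~ U(0.1, 0.9), r ~ U(0.05, 0.4), p ~ U(0.1, 0.9).  One RNG stream per
dataset, seeded from (master seed, replicate index), makes every
replicate independently reproducible, and the fixed draw order couples
the dead-recovery and joint simulations at p = 0.

What the generator does *not* emulate — and hence what passing
calibration tests cannot certify for field data — includes temporal or
individual heterogeneity in any parameter, emigration/site fidelity,
mis-assigned recovery intervals (deaths recovered long after the death
interval), tag loss, and non-independence among individuals.

## The simulation study

Each replicate simulates one dataset and fits all requested models to it.
Replicates in which any model fails the R-hat check are discarded and a
fresh dataset is simulated (replacement is global across models, keeping
paired comparisons valid), with an error after five times the requested
replicate count.  For the pathological classical multistate model the
convergence diagnostic is not trustworthy (trapped chains agree with each
other), so the pathology analyses can keep all replicates instead.
Aggregates report signed mean bias, mean absolute bias (both labelled,
since the two conventions are easily conflated), and the fraction of 95%
intervals containing the truth.

Reduced-scale defaults are 50 replicates with halved chain lengths; the
acceptance script uses 100 replicates for the calibrated models (binomial
SE ≈ 0.022 for a proportion near 0.95), 20 for the pathology target, and
the tests use 25–50 depending on the per-fit cost of the model family.

## Numerical choices

- Forward recursions run in linear probability space with per-occasion
  rescaling, accumulating the log normalization, so long histories do not
  underflow; a zero normalizer marks an impossible history (−inf).
- The single-state forward pass uses a two-component filter — alive, and
  "death already accounted for" — rather than the literal three-state
  algebra; equality with the three-state filter is a regression test.
- The multinomial kernel treats 0·log 0 as 0 and returns −inf for a
  positive count in a zero-probability cell.
- With time-constant parameters the multistate m-array cell probabilities
  depend only on the release-to-reencounter lag, so the alternating
  matrix products are computed once per lag.
- Gibbs sweeps and forward passes are numba-compiled; uniforms are drawn
  outside the kernels from per-chain `numpy` Generators so runs are
  bit-reproducible from the seed.

## Known limitations

- Time- or individual-varying parameters, group/age-stratified m-arrays,
  fidelity estimation, goodness-of-fit tests, and repaired (blocked)
  samplers for the classical multistate model are out of scope.
- Individuals marked on the final occasion carry no information and are
  dropped from m-arrays (they open no release row).
- Coverage estimates from tens of replicates carry binomial Monte-Carlo
  error of several percentage points; the study harness reports the
  replicate count alongside every aggregate for this reason.
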