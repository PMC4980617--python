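# Methods

## Model summary and assumptions

coevonet models behaviour selection as a co-evolutionary loop between a slow
tie structure and fast encounters.  The central assumptions are:

* **Closed population.**  The agent set is fixed; no birth, death or
  migration.
* **Two timescales.**  Contacts are sustained relationships updated by
  preference ranking once per step; interactions are one-step stochastic
  encounters sampled anew each step.  Only interactions transmit influence,
  and only agents who interacted in a step can form a new contact in it.
* **Binary behaviour, scalar disposition.**  Behaviour is a single 0/1 state
  under Ising-type peer pressure; the continuous disposition γ is exogenous
  and only enters the switching probabilities.
* **Quenched social background.**  The background proximity B is drawn once
  per run and never changes; all network adaptation is driven by behaviour
  co-occurrence through the mixture P = α·match + (1 − α)·B.
* **Reciprocity and capacity.**  A tie exists only while both agents rank
  each other within their top q, and degrees can never exceed q (checked at
  every step).  After the reciprocity pruning no "second-best" refill is
  attempted; spare capacity waits for future encounters.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N | 500 (200 in the shipped analyses) | population size |
| z, p_w | 10, 0.03 | substrate mean degree and rewiring probability |
| c_d | 0.25 | background proximity lost per degree of separation |
| c_ζ | 0.1 | quenched uniform noise amplitude on B |
| floor | 0.2 | lower clip of B; also the value for disconnected pairs |
| β, ε, δ | 0.8, 0.03, 2 | neighbour interaction probability, incidental-meeting floor, decay distance |
| C | 0.1 | switching-probability scale (equilibrium behavioural noise) |
| α | 0.2 | behaviour weight in the proximity mixture |
| μ, σ | 10, 3 | degree-preference distribution |
| C₁, C_f | 2.5, 0.25 | disposition-density endpoint values (initial/final) |
| equilibration, forcing | 200, 1000 steps | protocol lengths |

Choices that the model description leaves genuinely open, and how they were
fixed here:

* **Background decrement c_d = 0.25.**  α = 0.2 is meant to buy a tie
  "between one and two degrees" of background separation, i.e.
  c_d ∈ [α/(2(1−α)), α/(1−α)] = [0.125, 0.25].  We use the upper end: a
  behaviour match is worth exactly one degree (≈1.2 including typical noise).
  Smaller values let the match bonus out-rank several degrees of background
  structure; the 200-step equilibration then sorts the network almost
  completely by behaviour (conditional probability at distance 1 ≈ 0.99),
  a saturated state with no headroom for any further clustering response.
  At c_d = 0.25 the equilibrium is homophilous but unsaturated (CP(1) ≈ 0.8
  at a prevalence of 0.5).
* **Forcing endpoint C_f = 0.25.**  The final density 2.25(1 − x)² + 0.25
  leaves 21.9% of the disposition mass above 0.5, which the
  disposition-threshold (network) variant converts into a ≈ 25 percentage
  point prevalence drop; variants with peer influence deepen the drop by a
  further 10–15 points (coupled and mean-field end near 10%).
* **Switching form.**  p_start = C·γ·f and p_stop = C·(1 − γ)(1 − f): the
  simplest form that is monotone in both arguments, symmetric between the
  behaviours, bounded by C, and vanishing for fully committed agents.  Its
  single-agent stationary state is P(s = 1 | γ, f) = γf / (γf + (1−γ)(1−f)).
* **Mean-field stop probability** uses the complement 1 − S/N.
* **Equilibration dynamics.**  Every variant equilibrates under the fully
  coupled dynamics; the variant's modified rules apply during the forcing
  phase only.  All variants of a run index therefore start from the same
  equilibrated state and consume identical substrate, background, degree
  and forcing random substreams (cross-variant differences are attributable
  to dynamics alone).

## Disposition forcing as a controlled Markov chain

Each forcing step perturbs every γᵢ by sign(dev)·|dev|·η, where dev is the
empirical-minus-target CDF deviation evaluated at γᵢ (its sign points toward
the nearest density deficit) and η is log-normal with median `step_scale`
and log-sd 0.5; rounds repeat until the one-sample KS test against the
analytic target accepts at the 90% level, with at least one round per step.
Two numerical points matter:

* **At least one round per step.**  If the chain only moved when the KS test
  failed, a monotonically moving target would leave the sample permanently
  pinned one full KS critical distance behind it (measured: D ≈ 0.086 at
  n = 200, inflating the final upper-tail mass from 0.219 to 0.29).
* **Step scale 0.05.**  The controller's median drift per round must outrun
  the target CDF's per-step motion (≈ 3×10⁻⁴); at `step_scale` = 0.01 the
  residual one-sided lag is D ≈ 0.057 (+4 percentage points of final
  prevalence in every variant), at 0.05 it collapses to D ≈ 0.017 while
  individual steps stay small (≈ 2×10⁻³ per round).

The parabolic coefficients (a, b, c) are solved in closed form from
a(2b − 1) = C₁ − C₂ and a(b − 1/3) = C₁ − 1; infeasible endpoint pairs
(density dipping below zero) raise a configuration error naming the values.
Initial dispositions are drawn by inverse-CDF sampling on a 4097-point
monotone grid.

## Metrics and normalisation

* **Prevalence** S(t)/N.
* **Eigenvector centrality**: leading eigenvector of the contact adjacency
  matrix (dense symmetric eigensolver restricted to the top eigenpair),
  nonnegative, max component scaled to 1 — the convention of the igraph
  implementation, against which the test suite cross-checks.  On disconnected
  graphs the vector localises on the spectrally dominant component; group
  means are therefore noisy on small, fragmented networks.
* **Conditional smoking probability** P(d): over all ordered pairs (i, j) at
  shortest-path distance exactly d with s&#11388; = 1, the fraction with sᵢ = 1;
  NaN (never zero) when the conditioning set is empty.  A per-ego variant is
  available behind a flag.  Note that P(d) conflates clustering with overall
  prevalence: when prevalence falls several-fold, P(d) can decline even
  while clustering *relative to prevalence* (the smoker–smoker relative
  risk) rises.
* **Normalisation**: per-run series are normalised to their forcing-onset
  baselines (EVC as ratios, CP as relative changes) before any cross-run
  averaging.  Baselines average the last 25 equilibration steps; final
  values the last 50 steps.  Bootstrap bands (percentile, 2000 resamples)
  share one resample set across levels, so 99% bands contain 95% bands by
  construction.

## Problem sizes in the shipped analyses

The package default is N = 500; the shipped test-suite and acceptance
analyses run at N = 200 with 20-run ensembles for prevalence, 8-run aligned
ensembles for the four-variant comparison, and 10 seeds for the
equilibrium-noise bound — sizes at which the transition statistics are
stable (across-run SD of final prevalence ≈ 2 percentage points) on a single
desktop CPU.

## Known limitations

* The equilibrium fluctuation of the smoker count is an extreme-value
  statistic scaling like 1/√N: at N = 200 the maximum deviation from the
  median over 500 steps reaches 7–9.5% of N (10 seeds), and ≈ 4–7% at
  N = 500.  The bilinear switching rule carries a peer-feedback variance
  amplification (stationary susceptibility ≈ 1/(1 − 4·E[γ(1 − γ)])) that a
  differently normalised rule would not.
* The pooled conditional probability declines during the transition at this
  scale (see the metrics note above); the clustering signal appears in the
  relative-risk formulation and in the eigenvector-centrality split, not in
  the raw P(d) level.
* On a frozen contact network (interaction variant) homophilous local fields
  largely mirror each agent's own state, so local influence adds little
  beyond the disposition threshold; with network evolution or a global field
  the influence contribution roughly doubles the threshold-only drop.
* Behaviour is binary, ties are unweighted and symmetric, and dispositions
  are exogenous — deliberate simplifications of the behavioural repertoire.
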