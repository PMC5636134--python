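# Methods

## The model

`codasmoke` implements a Continuous Opinions, Discrete Actions (CODA) model
of adolescent smoking initiation. Each agent *i* carries

* an unobservable **opinion** `p_i ∈ [0, 1]` — the probability the agent
  assigns to smoking being preferable to non-smoking; and
* an observable binary **action** `δ_i ∈ {+1, −1}` — smoker or non-smoker.

Agents never see each other's opinions, only actions. After observing a
peer's action, an agent revises its opinion by Bayes' rule using two
likelihoods shared by the whole population and constant in time:

* `α = Pr(peer seen smoking | observer values smoking more)`,
* `β = Pr(peer seen not smoking | observer values non-smoking more)`.

Writing the update in odds form eliminates the unknown marginal action
probabilities, giving closed-form posteriors

```
smoker observed:      p' = α p / ((1−β)(1−p) + α p)        (odds × α/(1−β))
non-smoker observed:  p' = (1−α) p / (β(1−p) + (1−α) p)    (odds × (1−α)/β)
```

The sum `α + β` fully determines the direction of movement: above 1 the
population consists of **imitators** (a smoker sighting raises the smoking
opinion, a non-smoker sighting lowers it), below 1 of **contrarians**
(directions flip), and exactly 1 is a fixed point for every prior.
Opinions 0 and 1 are absorbing. The regime classifier uses a tolerance of
1e-9 around the threshold, purely to absorb floating-point noise; the
threshold itself is analytic and exact.

Opinions are stored as probabilities rather than log-odds: priors live in
roughly [0.01, 0.99] and runs are bounded (72 updates at ~0.1 expected
updates per agent-month), so no dynamic-range problem arises. The odds
form exists as a checked equivalent path in the tests, not as the primary
representation.

### Degenerate corners

When both numerator and denominator of a posterior vanish (e.g. `p = 0`
with `β = 1` on the smoker branch), the observation carries no usable
information at an absorbing prior: the update returns the prior unchanged
(the scalar API also warns). This keeps updates total and the absorbing
states consistent. The odds multiplier, by contrast, raises `ValueError`
when its denominator vanishes (`β = 1` on the smoker branch, `β = 0` on
the non-smoker branch), because an infinite odds factor has no usable
numeric representation.

## Population dynamics

A cohort is 2500 agents (a 50×50 grid kept as pure metadata — under the
random-interaction rule topology plays no role, and a test verifies the
grid shape is inert), followed monthly for 72 months (ages 12–17). All
agents start with the same opinion `p0`; initial actions are drawn iid
Bernoulli(`p0`) so that initial prevalence matches the initial opinion in
expectation — some initial smokers must exist for the simulated prevalence
to meet cohort starting values.

Each month:

1. a simple random sample (without replacement) of
   `round(0.10 × n)` **updaters** is drawn; each observes the
   start-of-month action of one uniformly random partner (≠ self) and
   applies the Bayes update. Snapshot observation makes within-month
   processing order irrelevant.
2. **Cessation:** updating smokers quit with probability 4.2% per month,
   independent of their opinion. Quitters carry a one-month cooldown.
3. **Initiation:** updating non-smokers not in cooldown start smoking with
   probability equal to their freshly updated opinion. The model treats
   opinions as probabilities precisely because opinions do not translate
   into behaviour deterministically; this rule is the reading under which
   an opinion of 0.02 generates a realistic trickle of initiation. Smoking
   status then persists until cessation ("the pool of potential smokers"
   is the non-smokers; quitters re-enter it after one month).
4. Cooldowns from previous months decrement before fresh quitters receive
   theirs, so a quitter is protected for exactly the following month.

Whether quitters' opinions reset on quitting is not specified by the
underlying theory; here opinions persist — only the action changes.

Prevalence (fraction of agents with action +1) is recorded at each month
end: 72 data points per run, with the month-0 value kept in metadata.
Replicate averages use deterministic seed-sequence spawning from the run
seed; `n_reps=1` uses the root stream directly so it is bit-identical to a
single run. The monthly step is compiled (numba) with a partial
Fisher-Yates sampler; there is a single dynamics code path, fully
deterministic given the seed.

### Emergent behaviour at the calibrated point

At (α, β, p0) = (0.7, 0.8, 0.02) prevalence rises from 2% and plateaus
near 3%: with ~3% smokers, ~97% of observations are of non-smokers, each
multiplying an updater's odds by (1−α)/β = 0.375, so opinions decay toward
0 and initiation slows while the cessation hazard drains the smoker pool.
Two consequences worth knowing:

* the α+β = 1 line is a no-drift null for **opinions** (they stay exactly
  `p0`; asserted in the tests), but not for **prevalence**: with cessation
  off, initiation is one-way and prevalence accumulates to ≈0.15 by month
  72. A prevalence-level version of that null is asserted in the
  acceptance suite and fails by construction; it is retained, failing, as
  documentation of the discrepancy rather than silently reinterpreted.
* prevalence is far more sensitive to α than to β at the calibrated
  point: the non-smoker multiplier's relative leverage is Δα/(1−α) vs
  Δβ/β (≈2.3× larger for α at (0.7, 0.8)), and α also scales the
  smoker-branch boost α/(1−β). Measured at 200 replicates, the ±10% α fan
  separates by ~0.008 prevalence (≈60 paired SEs) while the ±10% β fan
  moves only ~0.0003 (≈2.5 paired SEs) — a real but noise-level effect.
  The corresponding acceptance check for β is left failing with the
  measured numbers.

## Calibration

Observed data are 6 annual prevalence points per cohort. The simulated
values aligned to the beginning of each cohort year are months 1, 13, 25,
37, 49, 61 of the month-end series (six evenly spaced year-starts inside
the 6-year horizon; the year-end alternative, months 12…72, is exposed via
`alignment="year_end"`). The objective is the sum of squared errors over
those six points; the reported fit statistic is the least-squares
pseudo-R², `1 − SSE/SST` with SST the total sum of squares of the
observations (undefined for constant observations, in which case the
fitter reports NaN).

The search space is the explicit lattice α, β ∈ {0.00, 0.01, …, 1.00}
(two-decimal accuracy) × a p0 grid (default {0.010, 0.011, …, 0.030};
initial opinions in the published table vary per cohort in 0.01–0.02, so
p0 is searched rather than pinned; a single-value grid pins it).
`GridSpec.exhaustive()` scans the full lattice at 200 replicates per
point — faithful but expensive (~10⁵ lattice points). The default
`two_stage_search` screens a coarse 0.1-step α, β lattice × p0 ∈
{0.010, 0.015, …, 0.030} at 20 replicates, then refines ±0.05 around the
winner at 0.01 steps (p0 ±0.002 at 0.001 steps) with the full 200
replicates — ~6 minutes per distinct cohort on one CPU, and the ±0.05
neighbourhood guarantees the refinement can reach the true lattice point
whenever the coarse screen picks its nearest coarse neighbour.

Numerical conventions: every lattice point is evaluated with the same
replicate seed streams (common random numbers), which removes most
Monte-Carlo noise from the comparison and makes the argmin stable; an
evaluation cache keyed by (α, β, p0, replicates, seed) is shared across
cohorts; ties break to the lexicographically smallest (α, β, p0);
identical inputs give identical results.

## Synthetic data

The calibration target in the original analysis is a survey series (NSDUH
annual cigarette-use prevalence, 9 cohorts starting 2001–2009) that is not
redistributable here. `synthetic.generate_cohorts` produces datasets of
exactly that shape from the model itself at known (α, β, p0) — defaults
(0.7, 0.8, 0.02), the cross-cohort mean fitted values — with a
200-replicate truth series, optional truncated-Gaussian observation noise
on the annual points (default off; the original fit used survey point
estimates directly, so noise exists only to make recovery tests honest
about sampling error) and optional per-cohort parameter jitter (default
off) to emulate cross-cohort spread. All cohorts share one truth series
stream, so noiseless cohorts are identical; the manifest records the
generating parameters for recovery scoring, and generation is byte-
reproducible from the spec.

Passing recovery tests on these data show that the pipeline can identify
its own parameters from survey-shaped input at survey-scale magnitudes;
they do not show that the model describes real adolescents, and the
synthetic data contain none of NSDUH's design effects (weighting,
nonresponse, true period effects).

## Sensitivity sweeps

One-at-a-time relative sweeps of α or β: an odd number of points (default
5) spanning ±10% around a center (default: the mean fitted values),
clamped to [0, 1] with clamping recorded in metadata. All swept values
share the base seed, so the center trajectory is bit-identical to the
unswept run and differences across the fan are parameter effects rather
than noise.

## Problem sizes used in the shipped checks

Unit tests run mostly on 100-agent populations and small lattices; the
acceptance-style checks use the full study conditions (2500 agents, 72
months, 200 replicates, 9 cohorts, two-stage search), chosen to keep a
complete run at desk scale. The exhaustive two-decimal scan is implemented
and switchable (`--exhaustive`) but is not part of the default checks.

## Known limitations

* Homogeneous likelihoods: all agents share one (α, β); heterogeneity and
  dynamic friendship networks are out of scope.
* The interaction graph is fully mixed (random interaction); the grid is
  metadata only and no neighbourhood rule is implemented.
* Cessation is age- and opinion-independent, and applies only to smokers
  selected as updaters in a month.
* The opinion→behaviour rule (initiation with probability equal to the
  updated opinion) is one reading of "opinions are probabilities"; under
  it, β exerts little influence on prevalence at the calibrated point, and
  prevalence plateaus near 3% rather than climbing to the double-digit
  levels real cohorts reach by age 17.
* Pseudo-R² is the least-squares 1 − SSE/SST on six points; with so few
  points it is a descriptive, not inferential, statistic.
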