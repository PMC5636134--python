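# codasmoke

Agent-based **C**ontinuous **O**pinions, **D**iscrete **A**ctions (CODA)
modelling of adolescent smoking initiation: a Bayesian opinion-dynamics
simulator, grid-search calibration to annual cohort prevalence, sensitivity
sweeps, and a synthetic survey-data generator — for epidemiologists and
computational social scientists studying peer influence on health
behaviour.

## The model in brief

Each of 2500 simulated adolescents holds a hidden opinion
`p ∈ [0, 1]` — the probability that smoking (S) beats non-smoking (N) in
their personal value function — while displaying only a binary action
`δ ∈ {+1, −1}` (smoker / non-smoker). After observing a random peer's
action, an agent updates its opinion by Bayes' rule with shared likelihoods
`α = Pr(δ_j = +1 | i values S more)` and `β = Pr(δ_j = −1 | i values N
more)`. In odds form the unknown action marginals cancel:

    smoker observed:     p ← α p / ((1−β)(1−p) + α p)
    non-smoker observed: p ← (1−α) p / (β(1−p) + (1−α) p)

`α + β` is the behavioural switch: `> 1` imitators, `< 1` contrarians,
`= 1` a fixed point for every prior. Each month 10% of the population
updates; updating smokers quit with probability 4.2%/month (re-entering the
potential-smoker pool after one month) and updating non-smokers initiate
with probability equal to their updated opinion. Monthly prevalence over 72
months (ages 12–17) is compared, at the six year-start months, to annual
cohort survey data, and (α, β, p0) are fitted per cohort by exhaustive grid
search (α, β to two decimals) minimising squared error, reported with the
pseudo-R² `1 − SSE/SST` and the regime label.

## Worked example

Generate two survey-shaped synthetic cohorts at known ground truth and
recover the parameters on a small lattice (`examples/03_calibrate_synthetic.py`):

```text
ground truth: alpha=0.7, beta=0.8, p0=0.02
cohort c1 annual prevalence: [0.0203, 0.0263, 0.0289, 0.0296, 0.0291, 0.0284]
                   mean        c1        c2
alpha            0.7000       0.7       0.7
beta             0.8000       0.8       0.8
p0               0.0200      0.02      0.02
alpha_plus_beta  1.5000       1.5       1.5
pseudo_r2        0.9594  0.959351  0.959351
sse              0.0000  0.000003  0.000003
regime              NaN  imitator  imitator
```

The fitter lands on the generating lattice point; pseudo-R² ≈ 0.96 says the
six annual comparison points are reproduced almost exactly, and
`alpha_plus_beta = 1.5 > 1` classifies the population as imitators — peer
behaviour pulls opinions toward conformity. The other examples show single
opinion updates (`01`), a full cohort simulation printing prevalence by age
(`02`), and a ±10% sensitivity fan over α (`04`).

The same pipeline is scriptable from the shell:

```bash
codasmoke generate --n-cohorts 9 --seed 1 --out-dir data/
codasmoke calibrate --data data/cohorts.csv --out-dir fits/ --seed 101
codasmoke sweep --parameter alpha --n-reps 200 --out sweep.csv --plot sweep.png
codasmoke classify --alpha 0.7 --beta 0.8
```

`calibrate` defaults to a two-stage search (coarse 0.1-step screen at 20
replicates, 0.01-step refinement at 200 replicates); `--exhaustive`
switches to the full two-decimal 101×101 lattice. Every output file gets a
`.meta.json` provenance sidecar sufficient to regenerate it.

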