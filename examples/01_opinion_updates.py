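"""How a single adolescent's smoking opinion responds to peer observations.

Applies the Bayesian update with the mean fitted likelihoods (alpha=0.7,
beta=0.8, an imitator population: alpha+beta=1.5>1) to a sceptical prior,
showing the asymmetry between meeting a smoker and meeting a non-smoker.
"""

from codasmoke import (
    NONSMOKER,
    SMOKER,
    LikelihoodPair,
    classify_regime,
    odds_multiplier,
    update_opinion,
)

lik = LikelihoodPair(alpha=0.7, beta=0.8)
print(f"likelihoods: alpha={lik.alpha}, beta={lik.beta}, "
      f"alpha+beta={lik.total} -> {classify_regime(lik).value}")
print(f"odds multipliers: smoker x{odds_multiplier(SMOKER, lik):.3f}, "
      f"non-smoker x{odds_multiplier(NONSMOKER, lik):.4f}")

p = 0.02  # initial opinion: 2% credence that smoking beats not smoking
print(f"\nprior opinion p = {p}")
print(f"after meeting a smoker:      p -> {update_opinion(p, SMOKER, lik):.5f}")
print(f"after meeting a non-smoker:  p -> {update_opinion(p, NONSMOKER, lik):.6f}")

p_run = p
for k in range(1, 6):
    p_run = update_opinion(p_run, SMOKER, lik)
    print(f"after {k} consecutive smoker observations: p = {p_run:.4f}")

# A single smoker sighting more than triples the odds (x3.5); a non-smoker
# sighting shrinks them (x0.375).  Because alpha+beta>1 the population
# imitates: opinions chase whatever behaviour is observed.
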