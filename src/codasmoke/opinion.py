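"""Bayesian opinion updates with asymmetric likelihoods (CODA core).

In the Continuous Opinions and Discrete Actions (CODA) framework each agent
holds an unobservable *opinion* ``p`` in [0, 1] — here, the probability the
agent assigns to smoking being preferable to non-smoking — while displaying
only a binary *action*: smoker (+1) or non-smoker (-1).  Agents update their
opinion by Bayes' rule after observing a peer's action, using two shared
likelihoods:

* ``alpha`` — probability a peer is seen smoking, given the observer values
  smoking more;
* ``beta`` — probability a peer is seen not smoking, given the observer
  values non-smoking more.

The unknown marginal action probabilities cancel when the update is written
in odds form, leaving closed-form posteriors:

* after observing a smoker:      ``p' = a*p / ((1-b)*(1-p) + a*p)``
* after observing a non-smoker:  ``p' = (1-a)*p / (b*(1-p) + (1-a)*p)``

The sum ``alpha + beta`` controls the direction of the update.  Above 1
agents are *imitators* (observing a smoker raises the smoking opinion);
below 1 they are *contrarians*; exactly 1 is a fixed point for every prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "SMOKER",
    "NONSMOKER",
    "LikelihoodPair",
    "Regime",
    "posterior_after_smoker",
    "posterior_after_nonsmoker",
    "update_opinion",
    "odds_multiplier",
    "classify_regime",
]

#: Discrete action values: +1 = smoker, -1 = non-smoker.
SMOKER: int = 1
NONSMOKER: int = -1

_REGIME_TOL = 1e-9


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class LikelihoodPair:
    """Shared conditional likelihoods (alpha, beta) of the population.

    Both are probabilities; they are common to all agents and constant in
    time (the population is assumed homogeneous).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _check_prob(self.alpha, "alpha")
        _check_prob(self.beta, "beta")

    @property
    def total(self) -> float:
        """alpha + beta — the quantity that decides the update regime."""
        return self.alpha + self.beta


class Regime(str, Enum):
    """Qualitative update regime implied by alpha + beta vs the threshold 1."""

    IMITATOR = "imitator"
    NEUTRAL = "neutral"
    CONTRARIAN = "contrarian"


# -- vectorised kernels (no validation; used by the simulator) ---------------


def _post_smoker_arr(p: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    num = alpha * p
    den = (1.0 - beta) * (1.0 - p) + num
    safe = den > 0.0
    out = np.where(safe, num / np.where(safe, den, 1.0), p)
    return out


def _post_nonsmoker_arr(p: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    num = (1.0 - alpha) * p
    den = beta * (1.0 - p) + num
    safe = den > 0.0
    out = np.where(safe, num / np.where(safe, den, 1.0), p)
    return out


# -- public scalar API --------------------------------------------------------


def posterior_after_smoker(p: float, lik: LikelihoodPair) -> float:
    """Posterior opinion after observing a smoking peer.

    Degenerate 0/0 corners (e.g. ``p=0`` with ``beta=1``) carry no usable
    information at an absorbing prior; the prior is returned unchanged with
    a warning.
    """
    _check_prob(p, "p")
    num = lik.alpha * p
    den = (1.0 - lik.beta) * (1.0 - p) + num
    if den == 0.0:
        warnings.warn(
            f"degenerate smoker-observation update at p={p}, "
            f"(alpha, beta)=({lik.alpha}, {lik.beta}); prior returned unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
        return p
    return num / den


def posterior_after_nonsmoker(p: float, lik: LikelihoodPair) -> float:
    """Posterior opinion after observing a non-smoking peer."""
    _check_prob(p, "p")
    num = (1.0 - lik.alpha) * p
    den = lik.beta * (1.0 - p) + num
    if den == 0.0:
        warnings.warn(
            f"degenerate non-smoker-observation update at p={p}, "
            f"(alpha, beta)=({lik.alpha}, {lik.beta}); prior returned unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
        return p
    return num / den


def update_opinion(p: float, observed: int, lik: LikelihoodPair) -> float:
    """Bayesian opinion update after observing a peer's action (+1 or -1)."""
    if observed == SMOKER:
        return posterior_after_smoker(p, lik)
    if observed == NONSMOKER:
        return posterior_after_nonsmoker(p, lik)
    raise ValueError(f"observed action must be +1 or -1, got {observed!r}")


def odds_multiplier(observed: int, lik: LikelihoodPair) -> float:
    """Factor by which an observation multiplies the prior odds p/(1-p).

    ``alpha/(1-beta)`` for a smoker observation, ``(1-alpha)/beta`` for a
    non-smoker.  A factor above 1 raises the opinion.  Raises ``ValueError``
    when the relevant denominator vanishes (infinite/undefined odds).
    """
    if observed == SMOKER:
        if lik.beta == 1.0:
            raise ValueError(
                "odds multiplier undefined: beta=1 makes the smoker-branch "
                "odds infinite"
            )
        return lik.alpha / (1.0 - lik.beta)
    if observed == NONSMOKER:
        if lik.beta == 0.0:
            raise ValueError(
                "odds multiplier undefined: beta=0 makes the non-smoker-branch "
                "odds infinite"
            )
        return (1.0 - lik.alpha) / lik.beta
    raise ValueError(f"observed action must be +1 or -1, got {observed!r}")


def classify_regime(lik: LikelihoodPair, tol: float = _REGIME_TOL) -> Regime:
    """Classify (alpha, beta) as imitator / neutral / contrarian.

    The analytic threshold is ``alpha + beta = 1``; ``tol`` absorbs floating
    point noise around it.
    """
    s = lik.total
    if s > 1.0 + tol:
        return Regime.IMITATOR
    if s < 1.0 - tol:
        return Regime.CONTRARIAN
    return Regime.NEUTRAL
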