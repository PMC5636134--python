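"""Monthly-step agent-based simulator of adolescent smoking initiation.

A population of adolescents (default 2500, laid out on a 50x50 grid that is
pure metadata under random interaction) all start with the same smoking
opinion ``p0``.  Each month a random 10% of the population each observe one
uniformly random other agent's current behaviour and update their opinion by
the CODA Bayes rule.  Behaviour then resolves:

* updating smokers quit with a fixed monthly hazard (default 4.2%) and are
  barred from re-starting for exactly one month (the quit cooldown);
* updating non-smokers outside cooldown start smoking with probability equal
  to their freshly updated opinion.

Prevalence (the fraction of agents whose action is "smoker") is recorded at
every month end, giving 72 points over the ages-12-to-17 horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .opinion import NONSMOKER, SMOKER, LikelihoodPair

__all__ = [
    "SimulationConfig",
    "Population",
    "PrevalenceSeries",
    "init_population",
    "step_month",
    "simulate_cohort",
    "average_replicates",
    "replicate_matrix",
]

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one cohort run.

    ``grid_shape`` must tile ``n_agents`` but plays no dynamical role under
    random interaction; it is kept as metadata for forward compatibility
    with neighbourhood interaction rules.
    """

    p0: float
    lik: LikelihoodPair
    n_agents: int = 2500
    grid_shape: tuple[int, int] = (50, 50)
    interaction_fraction: float = 0.10
    cessation_rate: float = 0.042
    horizon_months: int = 72
    seed: "int | np.random.SeedSequence | None" = None

    def __post_init__(self) -> None:
        for name in ("p0", "interaction_fraction", "cessation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        rows, cols = self.grid_shape
        if rows * cols != self.n_agents:
            raise ValueError(
                f"grid_shape {self.grid_shape} does not tile n_agents={self.n_agents}"
            )
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents to pick interaction partners")
        if self.horizon_months < 1:
            raise ValueError("horizon_months must be >= 1")

    @property
    def n_updaters(self) -> int:
        return int(np.rint(self.interaction_fraction * self.n_agents))

    def to_dict(self) -> dict:
        return {
            "p0": self.p0,
            "alpha": self.lik.alpha,
            "beta": self.lik.beta,
            "n_agents": self.n_agents,
            "grid_shape": list(self.grid_shape),
            "interaction_fraction": self.interaction_fraction,
            "cessation_rate": self.cessation_rate,
            "horizon_months": self.horizon_months,
            "seed": None if self.seed is None else repr(self.seed),
        }


@dataclass
class Population:
    """Array-of-struct state: one entry per agent.

    ``quit_cooldown`` is positive only for agents who quit within the last
    month; smokers always carry cooldown 0.
    """

    opinion: np.ndarray  # float64, shape (n,)
    action: np.ndarray  # int8 in {+1, -1}, shape (n,)
    quit_cooldown: np.ndarray  # int32 >= 0, shape (n,)

    @property
    def n_agents(self) -> int:
        return self.opinion.shape[0]

    def prevalence(self) -> float:
        return float(np.count_nonzero(self.action == SMOKER)) / self.n_agents


@dataclass
class PrevalenceSeries:
    """Month-end smoker-proportion trajectory, months 1..horizon.

    The month-0 (initial) prevalence is kept separately in
    ``initial_prevalence`` so that the series has exactly ``horizon_months``
    data points.
    """

    values: np.ndarray
    cohort_id: str | None = None
    initial_prevalence: float | None = None
    n_reps: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("prevalence values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def months(self) -> np.ndarray:
        """1-based month indices."""
        return np.arange(1, len(self) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort_id": self.cohort_id if self.cohort_id is not None else "",
                "month": self.months,
                "prevalence": self.values,
            }
        )


def _as_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _replicate_streams(seed, n_reps: int) -> list[np.random.SeedSequence]:
    """Stateless seed-sequence spawning: child i of the root seed.

    Equivalent to ``SeedSequence(seed).spawn(n_reps)`` but reproducible even
    when the caller passes a SeedSequence that has spawned before.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        np.random.SeedSequence(entropy=root.entropy, spawn_key=root.spawn_key + (i,))
        for i in range(n_reps)
    ]


def init_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """All agents share opinion ``p0``; initial actions are iid Bernoulli(p0).

    Some initial smokers must exist for prevalence to match cohort starting
    values, hence the Bernoulli draw rather than an all-non-smoker start.
    """
    n = config.n_agents
    opinion = np.full(n, config.p0, dtype=np.float64)
    action = np.where(rng.random(n) < config.p0, SMOKER, NONSMOKER).astype(np.int8)
    cooldown = np.zeros(n, dtype=np.int32)
    return Population(opinion=opinion, action=action, quit_cooldown=cooldown)


@numba.njit
def _month_kernel(rng, opinion, action, cooldown, alpha, beta, cessation_rate, m):
    """One month of dynamics, in place.  Compiled: this is the hot loop.

    Event order: (1) m distinct updaters (partial Fisher-Yates) each observe
    the start-of-month action of a uniform random partner and update their
    opinion; (2) updating smokers face the cessation hazard; (3) eligible
    non-smoking updaters (cooldown 0 at month start) initiate with
    probability equal to the freshly updated opinion; (4) old cooldowns
    decrement, then fresh quitters receive cooldown 1.  Partner actions come
    from a snapshot, so within-month processing order cannot matter.
    """
    n = opinion.shape[0]
    u_select = rng.random(m)
    u_partner = rng.random(m)
    u_behave = rng.random(m)  # one draw per updater: cessation XOR initiation

    idx = np.arange(n)
    updaters = np.empty(m, np.int64)
    for k in range(m):
        j = k + int(u_select[k] * (n - k))
        if j > n - 1:
            j = n - 1
        tmp = idx[k]
        idx[k] = idx[j]
        idx[j] = tmp
        updaters[k] = idx[k]

    action_snap = action.copy()
    partners = np.empty(m, np.int64)
    observed = np.empty(m, np.int8)
    p_old = np.empty(m, np.float64)
    p_new = np.empty(m, np.float64)
    quit_flag = np.zeros(m, np.bool_)
    init_flag = np.zeros(m, np.bool_)

    for k in range(m):
        i = updaters[k]
        r = int(u_partner[k] * (n - 1))
        if r > n - 2:
            r = n - 2
        j = r + 1 if r >= i else r  # uniform over the other n-1 agents
        partners[k] = j
        obs = action_snap[j]
        observed[k] = obs
        p = opinion[i]
        p_old[k] = p
        if obs == 1:
            num = alpha * p
            den = (1.0 - beta) * (1.0 - p) + num
        else:
            num = (1.0 - alpha) * p
            den = beta * (1.0 - p) + num
        q = num / den if den > 0.0 else p  # degenerate 0/0 corner: keep prior
        p_new[k] = q
        opinion[i] = q
        if action_snap[i] == 1:
            if u_behave[k] < cessation_rate:
                quit_flag[k] = True
        elif cooldown[i] == 0 and u_behave[k] < q:
            init_flag[k] = True

    # decrement old cooldowns before assigning fresh ones, so a quitter is
    # protected through the whole following month
    for i in range(n):
        if cooldown[i] > 0:
            cooldown[i] -= 1
    for k in range(m):
        if init_flag[k]:
            action[updaters[k]] = 1
    for k in range(m):
        if quit_flag[k]:
            i = updaters[k]
            action[i] = -1
            cooldown[i] = 1
    return updaters, partners, observed, p_old, p_new, quit_flag, init_flag


def step_month(
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    trace: dict | None = None,
) -> Population:
    """Advance the population by one month, in place.

    See :func:`_month_kernel` for the event order.  If ``trace`` is a dict
    it is filled with the updater/partner indices, observed actions and the
    opinions before/after — the simulator's own bookkeeping, exposed for
    testing the single-interaction direction law.
    """
    updaters, partners, observed, p_old, p_new, quit_flag, init_flag = _month_kernel(
        rng,
        population.opinion,
        population.action,
        population.quit_cooldown,
        config.lik.alpha,
        config.lik.beta,
        config.cessation_rate,
        config.n_updaters,
    )
    if trace is not None:
        trace.update(
            updaters=updaters,
            partners=partners,
            observed=observed,
            opinion_before=p_old,
            opinion_after=p_new,
            quitters=updaters[quit_flag],
            initiators=updaters[init_flag],
        )
    return population


def simulate_cohort(
    config: SimulationConfig,
    cohort_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> PrevalenceSeries:
    """Run one cohort for ``horizon_months`` months (default 72).

    Returns the month-end prevalence series; the initial (month-0)
    prevalence travels in the series metadata.
    """
    if rng is None:
        rng = _as_rng(config.seed)
    population = init_population(config, rng)
    p_init = population.prevalence()
    values = np.empty(config.horizon_months, dtype=float)
    for t in range(config.horizon_months):
        step_month(population, config, rng)
        values[t] = population.prevalence()
    return PrevalenceSeries(
        values=values, cohort_id=cohort_id, initial_prevalence=p_init, n_reps=1
    )


def average_replicates(
    config: SimulationConfig, n_reps: int, cohort_id: str | None = None
) -> PrevalenceSeries:
    """Pointwise mean of ``n_reps`` independent cohort runs.

    Replicate RNG streams are spawned deterministically from ``config.seed``
    (seed-sequence spawning), so the result is reproducible and replicates
    are independent.  With ``n_reps=1`` the root stream is used directly,
    making the result bit-identical to :func:`simulate_cohort`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_reps == 1:
        return simulate_cohort(config, cohort_id=cohort_id)
    children = _replicate_streams(config.seed, n_reps)
    total = np.zeros(config.horizon_months, dtype=float)
    init_total = 0.0
    for child in children:
        series = simulate_cohort(config, rng=np.random.default_rng(child))
        total += series.values
        init_total += series.initial_prevalence
    return PrevalenceSeries(
        values=total / n_reps,
        cohort_id=cohort_id,
        initial_prevalence=init_total / n_reps,
        n_reps=n_reps,
    )


def replicate_matrix(config: SimulationConfig, n_reps: int) -> np.ndarray:
    """All replicate trajectories as an (n_reps, horizon) array.

    Used for Monte-Carlo error estimation (each row is one independent
    cohort run under the spawned seed stream of :func:`average_replicates`).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_reps == 1:
        return simulate_cohort(config).values[None, :]
    children = _replicate_streams(config.seed, n_reps)
    out = np.empty((n_reps, config.horizon_months), dtype=float)
    for i, child in enumerate(children):
        out[i] = simulate_cohort(config, rng=np.random.default_rng(child)).values
    return out
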