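"""Synthetic cohort-prevalence data with known ground truth.

The real calibration target is a survey series (annual cigarette-use
prevalence for cohorts of adolescents followed from age 12 to 17, nine
cohorts starting 2001-2009).  That survey is not bundled; instead this
module generates datasets of exactly that shape from the model itself under
known (alpha, beta, p0), optionally adding truncated Gaussian observation
noise on the annual points.  Because the generating parameters are recorded
in a manifest, the full pipeline — simulate, calibrate, classify — can be
scored on parameter recovery without any download.

What this emulates: the 9-cohorts x 6-annual-points layout and magnitudes.
What it does not: survey design effects (weighting, nonresponse) or true
calendar-period effects; synthetic cohorts differ only through observation
noise or the optional parameter jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import CohortData, extract_annual_points
from .opinion import LikelihoodPair
from .simulate import SimulationConfig, average_replicates

__all__ = ["SyntheticSpec", "generate_cohorts", "fixture_small"]

_FIXTURE_SEED = 20011214  # frozen: fixture_small must be byte-stable


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth generating parameters for a synthetic survey dataset.

    Defaults are the cross-cohort mean fitted values of the published
    random-interaction analysis: alpha 0.7, beta 0.8, initial opinion 0.02,
    with 200 replicate rounds averaged into the truth series.
    """

    n_cohorts: int = 9
    true_alpha: float = 0.7
    true_beta: float = 0.8
    true_p0: float = 0.02
    n_reps_truth: int = 200
    obs_noise_sd: float = 0.0
    param_jitter_sd: float = 0.0
    start_year: int = 2001
    n_agents: int = 2500
    grid_shape: tuple[int, int] = (50, 50)
    horizon_months: int = 72
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if self.n_reps_truth < 1:
            raise ValueError("n_reps_truth must be >= 1")
        if self.obs_noise_sd < 0 or self.param_jitter_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _truth_annual(spec: SyntheticSpec, alpha, beta, p0, sim_seed) -> np.ndarray:
    config = SimulationConfig(
        p0=p0,
        lik=LikelihoodPair(alpha, beta),
        n_agents=spec.n_agents,
        grid_shape=spec.grid_shape,
        horizon_months=spec.horizon_months,
        seed=sim_seed,
    )
    return extract_annual_points(average_replicates(config, spec.n_reps_truth))


def generate_cohorts(spec: SyntheticSpec) -> tuple[list[CohortData], dict]:
    """Generate the cohorts plus a ground-truth manifest.

    All cohorts share one replicate-averaged truth series (common simulation
    seed stream), so with zero noise and zero jitter every cohort's annual
    vector is identical.  Observation noise is truncated to keep prevalence
    in [0, 1]; the noise stream is independent of the simulation stream.
    """
    root = np.random.SeedSequence(spec.seed)
    sim_ss, noise_ss, jitter_ss = root.spawn(3)
    noise_rng = np.random.default_rng(noise_ss)
    jitter_rng = np.random.default_rng(jitter_ss)

    base_annual = None
    cohorts: list[CohortData] = []
    manifest_cohorts = []
    for k in range(spec.n_cohorts):
        if spec.param_jitter_sd > 0:
            a = float(np.clip(spec.true_alpha + jitter_rng.normal(0, spec.param_jitter_sd), 0, 1))
            b = float(np.clip(spec.true_beta + jitter_rng.normal(0, spec.param_jitter_sd), 0, 1))
            annual = _truth_annual(spec, a, b, spec.true_p0, sim_ss)
        else:
            a, b = spec.true_alpha, spec.true_beta
            if base_annual is None:
                base_annual = _truth_annual(spec, a, b, spec.true_p0, sim_ss)
            annual = base_annual
        if spec.obs_noise_sd > 0:
            annual = np.clip(
                annual + noise_rng.normal(0, spec.obs_noise_sd, size=annual.shape), 0, 1
            )
        cohort_id = f"c{k + 1}"
        cohorts.append(
            CohortData(
                cohort_id=cohort_id,
                annual_prevalence=tuple(float(v) for v in annual),
                start_year=spec.start_year + k,
            )
        )
        manifest_cohorts.append(
            {"cohort_id": cohort_id, "alpha": a, "beta": b, "p0": spec.true_p0}
        )
    manifest = {
        "spec": {
            "n_cohorts": spec.n_cohorts,
            "true_alpha": spec.true_alpha,
            "true_beta": spec.true_beta,
            "true_p0": spec.true_p0,
            "n_reps_truth": spec.n_reps_truth,
            "obs_noise_sd": spec.obs_noise_sd,
            "param_jitter_sd": spec.param_jitter_sd,
            "start_year": spec.start_year,
            "n_agents": spec.n_agents,
            "horizon_months": spec.horizon_months,
            "seed": spec.seed,
        },
        "cohorts": manifest_cohorts,
    }
    return cohorts, manifest


def fixture_small() -> list[CohortData]:
    """Tiny deterministic dataset (2 cohorts, 20-replicate truth) for fast tests.

    Repeated calls return byte-identical data; a frozen seed guarantees it.
    """
    spec = SyntheticSpec(n_cohorts=2, n_reps_truth=20, seed=_FIXTURE_SEED)
    cohorts, _ = generate_cohorts(spec)
    return cohorts
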