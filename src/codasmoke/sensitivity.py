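"""One-at-a-time sensitivity sweeps of the likelihoods alpha and beta.

A sweep perturbs one likelihood by up to +/-10% (relative) around a fitted
center while holding everything else fixed, and records the replicate-
averaged prevalence trajectory at each swept value — a fan of trajectories
whose spread shows how sensitive simulated smoking prevalence is to that
likelihood.  Default centers are the cross-cohort mean fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .opinion import LikelihoodPair
from .simulate import PrevalenceSeries, SimulationConfig, average_replicates

__all__ = ["SweepSpec", "SweepResult", "sweep_values", "run_sweep"]


def sweep_values(center: float, relative_span: float, n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric relative grid around ``center``, clamped to [0, 1].

    Returns ``(values, clamped)`` where ``clamped`` flags entries that hit a
    probability bound.
    """
    if n_points < 1 or n_points % 2 == 0:
        raise ValueError("n_points must be a positive odd number so the center is included")
    raw = center * (1.0 + relative_span * np.linspace(-1.0, 1.0, n_points))
    values = np.clip(raw, 0.0, 1.0)
    return values, values != raw


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a one-parameter sweep."""

    parameter: str  # "alpha" or "beta"
    center: float
    base_config: SimulationConfig
    relative_span: float = 0.10
    n_points: int = 5
    n_reps: int = 200

    def __post_init__(self) -> None:
        if self.parameter not in ("alpha", "beta"):
            raise ValueError(f"parameter must be 'alpha' or 'beta', got {self.parameter!r}")
        if not 0.0 <= self.center <= 1.0:
            raise ValueError("center must lie in [0, 1]")
        if self.relative_span < 0:
            raise ValueError("relative_span must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        sweep_values(self.center, self.relative_span, self.n_points)  # validates n_points


@dataclass
class SweepResult:
    """Fan of replicate-averaged trajectories, one per swept value."""

    spec: SweepSpec
    values: np.ndarray
    clamped: np.ndarray
    trajectories: dict  # swept value -> PrevalenceSeries

    @property
    def center_series(self) -> PrevalenceSeries:
        mid = self.values[len(self.values) // 2]
        return self.trajectories[mid]

    def to_frame(self) -> pd.DataFrame:
        """Long format: parameter, value, month, prevalence."""
        frames = []
        for v in self.values:
            s = self.trajectories[v]
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": self.spec.parameter,
                        "value": v,
                        "month": s.months,
                        "prevalence": s.values,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the fan of replicate-averaged simulations.

    Every swept value reuses the base config's seed (common random numbers),
    so the center trajectory is bit-identical to the unswept base run.
    """
    values, clamped = sweep_values(spec.center, spec.relative_span, spec.n_points)
    trajectories = {}
    for v in values:
        if spec.parameter == "alpha":
            lik = LikelihoodPair(float(v), spec.base_config.lik.beta)
        else:
            lik = LikelihoodPair(spec.base_config.lik.alpha, float(v))
        config = replace(spec.base_config, lik=lik)
        trajectories[float(v)] = average_replicates(config, spec.n_reps)
    return SweepResult(
        spec=spec, values=values.astype(float), clamped=clamped, trajectories=trajectories
    )
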