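"""Benchmark harness: scaled RMSE metric and the two table experiments.

The accuracy metric is a root-mean-square error on concentrations scaled by
1e5, so a value of 1.0 corresponds to a 10 uM error.  Multi-run results
take the square root of the grand mean of squared scaled errors over all
runs and samples; a ``sqrt=False`` variant (plain mean of squared errors)
is kept for comparison.

Two standard experiments are provided:

* the quiescent-cell experiment — random-walk truth, sensors starting
  empty, Kalman filter vs bootstrap particle filter;
* the two-regime experiment — hidden-Markov drift truth, sensors starting
  at random occupancy, GPB2 Kalman filter vs jump-Markov particle filter.

Both report, per estimator and sensor count, the averaged scaled RMSE, its
Monte Carlo standard error and wall time.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .gaussian_filters import GaussianBelief, JumpBelief, gpb2_run, kf_run
from .particle_filters import pf_run, pfmcmc_run
from .sensor_model import SensorParams
from .simulator import ProcessModel, RegimeModel, generate_dataset

__all__ = [
    "BenchmarkConfig",
    "scaled_rmse",
    "aggregate_rmse",
    "run_benchmark",
    "run_table1",
    "run_table2",
    "normal_cell_config",
    "two_state_config",
]

logger = logging.getLogger(__name__)

SCALE = 1e5  # concentrations are expressed in 1e-5 M units in the metric


@dataclass(frozen=True)
class BenchmarkConfig:
    """Everything one benchmark needs, with the study defaults filled in.

    The defaults are the study conditions: kA = 100 / (M s), kD = 1e-3 / s,
    NT = 10 sites, dt = 1 s; quiescent-cell runs are 2000 steps with
    random-walk variance 1e-16 M^2 from 1e-5 M and sensors starting empty;
    two-regime runs are 4000 steps with per-regime variances (1e-16,
    5e-14) M^2, switch probability 0.01 per second each way, and sensors
    starting at a uniform random count below 10.  Filters start from the
    deliberately wrong initial mean 2e-5 M with covariance 1e-10 M^2
    (sd = one state scale); ``literal_init_cov`` selects the printed 1e-5
    instead.  The particle filters use 200 particles.
    """

    scenario: str = "normal"  # "normal" | "two_state"
    estimators: tuple[str, ...] = ("PF", "KF")
    sensor_counts: tuple[int, ...] = (1, 5, 10, 20)
    n_runs: int = 100
    n_steps: int = 2000
    seed: int = 0
    # sensor kinetics
    kA: float = 100.0
    kD: float = 1e-3
    NT: int = 10
    dt: float = 1.0
    # truth process
    x0: float = 1e-5
    q: float = 1e-16
    qs: tuple[float, float] = (1e-16, 5e-14)
    Pi: tuple[tuple[float, float], ...] = ((0.99, 0.01), (0.01, 0.99))
    y0_policy: str = "zero"
    sampler: str = "ssa"
    forced_switch_time: Optional[int] = None
    # filter initialization
    init_mean: float = 2e-5
    init_cov: float = 1e-10
    literal_init_cov: bool = False
    n_particles: int = 200
    use_sqrt: bool = True

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if min(self.sensor_counts) < 1:
            raise ValueError("sensor counts must be >= 1")
        if self.scenario not in ("normal", "two_state"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        known = {"PF", "KF", "KF-GPB2", "PF-MCMC"}
        unknown = set(self.estimators) - known
        if unknown:
            raise ValueError(f"unknown estimators {sorted(unknown)}")

    @property
    def sensor_params(self) -> SensorParams:
        return SensorParams(kA=self.kA, kD=self.kD, NT=self.NT, dt=self.dt)

    @property
    def process_model(self) -> ProcessModel:
        if self.scenario == "normal":
            return ProcessModel(kind="random_walk", q=self.q, x0=self.x0)
        return ProcessModel(kind="regime_switching", x0=self.x0,
                            regime=self.regime_model)

    @property
    def regime_model(self) -> RegimeModel:
        return RegimeModel(Pi=np.asarray(self.Pi), qs=np.asarray(self.qs))

    @property
    def effective_init_cov(self) -> float:
        return 1e-5 if self.literal_init_cov else self.init_cov

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "BenchmarkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("estimators", "sensor_counts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "qs" in raw:
            raw["qs"] = tuple(raw["qs"])
        if "Pi" in raw:
            raw["Pi"] = tuple(tuple(row) for row in raw["Pi"])
        return cls(**raw)


def scaled_rmse(C_true: np.ndarray, C_hat: np.ndarray,
                use_sqrt: bool = True) -> float:
    """Root-mean-square error of a single run on the 1e5-scaled axis."""
    C_true = np.asarray(C_true, dtype=float)
    C_hat = np.asarray(C_hat, dtype=float)
    if C_true.shape != C_hat.shape:
        raise ValueError("trajectories must have equal length")
    msq = float(np.mean(((C_true - C_hat) * SCALE) ** 2))
    return float(np.sqrt(msq)) if use_sqrt else msq


def aggregate_rmse(per_run_msq: Sequence[float],
                   use_sqrt: bool = True) -> tuple[float, float]:
    """Combine per-run mean squared scaled errors over runs.

    Returns ``(rmse, mc_se)`` where rmse is the square root of the grand
    mean of squared scaled errors over all runs and samples, and mc_se the
    Monte Carlo standard error of that statistic (delta method on the mean
    of per-run mean squares).
    """
    msq = np.asarray(per_run_msq, dtype=float)
    grand = float(msq.mean())
    se_grand = float(msq.std(ddof=1) / np.sqrt(len(msq))) if len(msq) > 1 \
        else 0.0
    if not use_sqrt:
        return grand, se_grand
    rmse = float(np.sqrt(grand))
    mc_se = se_grand / (2.0 * rmse) if rmse > 0 else 0.0
    return rmse, mc_se


def _run_one(config: BenchmarkConfig, estimator: str, Ns: int,
             run_seed: np.random.SeedSequence) -> float:
    """One dataset + one filter; returns the run's mean squared scaled error."""
    rng = np.random.default_rng(run_seed)
    ds = generate_dataset(
        model=config.process_model,
        params=config.sensor_params,
        Ns=Ns,
        n_steps=config.n_steps,
        y0_policy=config.y0_policy,
        rng_seed=rng,
        sampler=config.sampler,
        forced_switch_time=config.forced_switch_time,
    )
    mean0, cov0 = config.init_mean, config.effective_init_cov
    if estimator == "KF":
        res = kf_run(ds, GaussianBelief(mean0, cov0), config.q)
    elif estimator == "PF":
        res = pf_run(ds, mean0, cov0, config.n_particles, config.q, rng)
    elif estimator == "KF-GPB2":
        regime = config.regime_model
        init = JumpBelief(
            [GaussianBelief(mean0, cov0) for _ in range(regime.H)],
            np.eye(regime.H)[0],
        )
        res = gpb2_run(ds, init, regime)
    elif estimator == "PF-MCMC":
        res = pfmcmc_run(ds, mean0, cov0, config.n_particles,
                         config.regime_model, rng)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(estimator)
    return scaled_rmse(ds.C_true, res.estimates, use_sqrt=False)


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Run every (estimator, sensor count) cell of the configured experiment.

    Each of the ``n_runs`` replicates redraws both the truth path and the
    sensor counts.  Replicate seeds are spawned deterministically from the
    base seed, and the same ``n_runs`` datasets are reused across
    estimators within a sensor count (paired comparison).
    """
    root = np.random.SeedSequence(config.seed)
    rows = []
    for Ns in config.sensor_counts:
        run_seeds = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(Ns,)
        ).spawn(config.n_runs)
        for estimator in config.estimators:
            t0 = time.perf_counter()
            msq = [_run_one(config, estimator, Ns, s) for s in run_seeds]
            elapsed = time.perf_counter() - t0
            rmse, mc_se = aggregate_rmse(msq, use_sqrt=config.use_sqrt)
            logger.info("%s Ns=%d: rmse=%.4f (se %.4f) in %.1fs",
                        estimator, Ns, rmse, mc_se, elapsed)
            rows.append({
                "estimator": estimator,
                "n_sensors": Ns,
                "n_runs": config.n_runs,
                "rmse": rmse,
                "mc_se": mc_se,
                "seconds": elapsed,
            })
    return pd.DataFrame(rows)


def normal_cell_config(**overrides) -> BenchmarkConfig:
    """Quiescent-cell experiment defaults (random-walk truth, KF vs PF)."""
    base = BenchmarkConfig(
        scenario="normal",
        estimators=("PF", "KF"),
        n_steps=2000,
        y0_policy="zero",
    )
    return replace(base, **overrides)


def two_state_config(**overrides) -> BenchmarkConfig:
    """Two-regime experiment defaults (HMM drift truth, GPB2 vs jump PF)."""
    base = BenchmarkConfig(
        scenario="two_state",
        estimators=("PF-MCMC", "KF-GPB2"),
        n_steps=4000,
        y0_policy="random",
    )
    return replace(base, **overrides)


def run_table1(config: Optional[BenchmarkConfig] = None) -> pd.DataFrame:
    """The quiescent-cell RMSE table (KF vs PF over sensor counts)."""
    config = config or normal_cell_config()
    if config.scenario != "normal":
        raise ValueError("table 1 requires the normal-cell scenario")
    return run_benchmark(config)


def run_table2(config: Optional[BenchmarkConfig] = None) -> pd.DataFrame:
    """The two-regime RMSE table (KF-GPB2 vs PF-MCMC over sensor counts)."""
    config = config or two_state_config()
    if config.scenario != "two_state":
        raise ValueError("table 2 requires the two-state scenario")
    return run_benchmark(config)
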