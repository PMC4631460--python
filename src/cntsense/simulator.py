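"""Synthetic ground truth and sensor data.

Generates the two study conditions the estimators are benchmarked under:

* a quiescent cell whose local signal-molecule concentration performs a
  slow Gaussian random walk around ~10 uM, and
* a two-regime cell (hidden Markov chain) whose concentration alternates
  between a near-static phase and an intermittently drifting phase with a
  much larger step variance — the tumor-like drift signature.

Sensor counts are sampled either by an exact Gillespie stochastic simulation
(kinetic Monte Carlo) of the adsorption/desorption jump process, or directly
from the analytic convolved-binomial transition kernel; the two samplers are
distributionally identical at the sampling instants and that equivalence is
covered by the test suite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

from .sensor_model import SensorParams, occupancy_fraction_arrays

__all__ = [
    "RegimeModel",
    "ProcessModel",
    "Dataset",
    "simulate_concentration",
    "simulate_counts_ssa",
    "simulate_counts_exact",
    "generate_dataset",
]

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class RegimeModel:
    """Hidden-Markov regime model for intermittent concentration drift.

    ``Pi`` is the H x H row-stochastic transition matrix of the hidden
    regime chain and ``qs`` the per-regime process-noise variances [M^2].
    Regime 0 is the quiescent (normal) state, regime 1 the drifting
    (tumor-like) state in the two-state case.
    """

    Pi: np.ndarray
    qs: np.ndarray

    def __post_init__(self) -> None:
        Pi = np.asarray(self.Pi, dtype=float)
        qs = np.asarray(self.qs, dtype=float)
        object.__setattr__(self, "Pi", Pi)
        object.__setattr__(self, "qs", qs)
        if Pi.ndim != 2 or Pi.shape[0] != Pi.shape[1]:
            raise ValueError("Pi must be a square matrix")
        if np.any(Pi < 0) or np.any(Pi > 1):
            raise ValueError("Pi entries must lie in [0, 1]")
        if not np.allclose(Pi.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows of Pi must sum to 1")
        if qs.shape != (Pi.shape[0],):
            raise ValueError("qs must have one variance per regime")
        if np.any(qs < 0):
            raise ValueError("process variances must be nonnegative")

    @property
    def H(self) -> int:
        return self.Pi.shape[0]


@dataclass(frozen=True)
class ProcessModel:
    """Ground-truth concentration dynamics.

    kind="random_walk": x_k = x_{k-1} + N(0, q).
    kind="regime_switching": the step variance is ``regime.qs[r_k]`` where
    r_k follows the hidden Markov chain of ``regime`` (starting in regime 0).
    Concentrations are clipped at zero — a physical floor; at the default
    noise scales the clip is never active in practice.
    """

    kind: Literal["random_walk", "regime_switching"] = "random_walk"
    q: float = 1e-16
    regime: Optional[RegimeModel] = None
    x0: float = 1e-5

    def __post_init__(self) -> None:
        if self.kind not in ("random_walk", "regime_switching"):
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.q < 0:
            raise ValueError("q must be nonnegative")
        if self.x0 < 0:
            raise ValueError("x0 must be nonnegative")
        if self.kind == "regime_switching" and self.regime is None:
            raise ValueError("regime_switching requires a RegimeModel")


@dataclass
class Dataset:
    """One synthetic experiment: shared truth plus per-sensor count data.

    ``counts[k, j]`` is sensor j's occupancy at time ``times[k]``; ``y0[j]``
    is its occupancy at t = 0, which the filters condition the first
    observation on.  ``regimes`` holds the true hidden regime per instant
    (0-based) for regime-switching truth, else None.
    """

    times: np.ndarray
    C_true: np.ndarray
    counts: np.ndarray
    y0: np.ndarray
    x0: float
    params: SensorParams
    regimes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.C_true = np.asarray(self.C_true, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=np.int64))
        self.y0 = np.atleast_1d(np.asarray(self.y0, dtype=np.int64))
        K = len(self.times)
        if self.C_true.shape != (K,) or self.counts.shape[0] != K:
            raise ValueError("times, C_true and counts must share the time axis")
        if self.counts.shape[1] != len(self.y0):
            raise ValueError("y0 must have one entry per sensor")
        if self.regimes is not None:
            self.regimes = np.asarray(self.regimes, dtype=np.int64)
            if self.regimes.shape != (K,):
                raise ValueError("regimes must align with times")
        lo, hi = self.counts.min(initial=0), self.counts.max(initial=0)
        if lo < 0 or hi > self.params.NT or self.y0.min(initial=0) < 0 \
                or self.y0.max(initial=0) > self.params.NT:
            raise ValueError(f"counts must lie in [0, {self.params.NT}]")

    @property
    def Ns(self) -> int:
        return self.counts.shape[1]

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def to_csv(self, path: Union[str, Path, io.TextIOBase]) -> None:
        """Write `t,C_true,regime,y_1,...,y_Ns` with a t=0 row holding x0/y0."""
        cols = {"t": np.concatenate([[0.0], self.times]),
                "C_true": np.concatenate([[self.x0], self.C_true])}
        if self.regimes is not None:
            cols["regime"] = np.concatenate([[0], self.regimes])
        else:
            cols["regime"] = [""] * (self.n_steps + 1)
        for j in range(self.Ns):
            cols[f"y_{j + 1}"] = np.concatenate([[self.y0[j]], self.counts[:, j]])
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path, io.TextIOBase],
                 params: SensorParams) -> "Dataset":
        df = pd.read_csv(path)
        ycols = [c for c in df.columns if c.startswith("y_")]
        regimes = None
        if "regime" in df.columns and not df["regime"].isna().all():
            regimes = df["regime"].to_numpy(dtype=np.int64)[1:]
        return cls(
            times=df["t"].to_numpy()[1:],
            C_true=df["C_true"].to_numpy()[1:],
            counts=df[ycols].to_numpy(dtype=np.int64)[1:],
            y0=df[ycols].to_numpy(dtype=np.int64)[0],
            x0=float(df["C_true"].iloc[0]),
            params=params,
            regimes=regimes,
        )


def simulate_concentration(
    model: ProcessModel,
    n_steps: int,
    rng_seed: RngLike,
    forced_switch_time: Optional[int] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Sample a ground-truth concentration path of ``n_steps`` instants.

    Returns ``(C_true, regimes)``; ``regimes`` is None for random-walk truth.
    For regime-switching truth the chain starts in regime 0 and is sampled
    from ``Pi`` unless ``forced_switch_time`` is given, in which case the
    regime is 0 before that step index and 1 from it onward (deterministic
    switch, for figure-style demonstrations and paired detection tests).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = _as_rng(rng_seed)
    if model.kind == "random_walk":
        steps = rng.normal(0.0, np.sqrt(model.q), size=n_steps)
        x = model.x0 + np.cumsum(steps)
        return np.maximum(x, 0.0), None

    regime = model.regime
    assert regime is not None
    if forced_switch_time is not None:
        regimes = np.zeros(n_steps, dtype=np.int64)
        regimes[forced_switch_time:] = 1
    else:
        regimes = np.empty(n_steps, dtype=np.int64)
        r = 0
        u = rng.random(n_steps)
        cum = np.cumsum(regime.Pi, axis=1)
        for k in range(n_steps):
            r = int(np.searchsorted(cum[r], u[k]))
            regimes[k] = r
    sd = np.sqrt(regime.qs[regimes])
    steps = rng.normal(0.0, 1.0, size=n_steps) * sd
    x = model.x0 + np.cumsum(steps)
    return np.maximum(x, 0.0), regimes


def simulate_counts_ssa(
    params: SensorParams,
    C_true: np.ndarray,
    y0: int,
    rng_seed: RngLike,
) -> np.ndarray:
    """Exact Gillespie (kinetic Monte Carlo) sensor-count trajectory.

    Within each sampling interval the concentration is held at that
    interval's value and the adsorption/desorption jump process is simulated
    event by event with propensities ``kA*C*(NT - y)`` and ``kD*y``; the
    occupancy is recorded at the end of each interval.
    """
    if not 0 <= y0 <= params.NT:
        raise ValueError(f"y0 must lie in [0, {params.NT}]")
    rng = _as_rng(rng_seed)
    C_true = np.asarray(C_true, dtype=float)
    kA, kD, NT, dt = params.kA, params.kD, params.NT, params.dt
    y = int(y0)
    out = np.empty(len(C_true), dtype=np.int64)
    exp_rv = rng.exponential
    uni = rng.random
    for k, C in enumerate(C_true):
        kAC = kA * C
        t = 0.0
        while True:
            a_ads = kAC * (NT - y)
            a_des = kD * y
            a_tot = a_ads + a_des
            if a_tot <= 0.0:
                break
            t += exp_rv(1.0 / a_tot)
            if t >= dt:
                break
            y += 1 if uni() * a_tot < a_ads else -1
        out[k] = y
    return out


def simulate_counts_exact(
    params: SensorParams,
    C_true: np.ndarray,
    y0: int,
    rng_seed: RngLike,
) -> np.ndarray:
    """Sample the analytic one-interval kernel instead of event-level KMC.

    Draws ``y_k ~ Binomial(y_{k-1}, lamF) + Binomial(NT - y_{k-1}, lamE)``;
    statistically indistinguishable from :func:`simulate_counts_ssa` at the
    sampling instants.
    """
    if not 0 <= y0 <= params.NT:
        raise ValueError(f"y0 must lie in [0, {params.NT}]")
    rng = _as_rng(rng_seed)
    C_true = np.asarray(C_true, dtype=float)
    lamF, lamE = occupancy_fraction_arrays(params, C_true)
    y = int(y0)
    out = np.empty(len(C_true), dtype=np.int64)
    for k in range(len(C_true)):
        y = int(rng.binomial(y, lamF[k]) + rng.binomial(params.NT - y, lamE[k]))
        out[k] = y
    return out


def generate_dataset(
    model: ProcessModel,
    params: SensorParams,
    Ns: int,
    n_steps: int,
    y0_policy: Literal["zero", "random"] = "zero",
    rng_seed: RngLike = 0,
    sampler: Literal["ssa", "exact"] = "ssa",
    forced_switch_time: Optional[int] = None,
    csv_path: Optional[Union[str, Path]] = None,
) -> Dataset:
    """One shared truth path plus ``Ns`` conditionally independent sensors.

    ``y0_policy="zero"`` starts every sensor empty; ``"random"`` draws each
    initial count uniformly from {0..9} (capped at NT).  With a fixed seed
    the dataset is bit-for-bit reproducible, including its CSV form.
    """
    if Ns < 1:
        raise ValueError("Ns must be >= 1")
    rng = _as_rng(rng_seed)
    C_true, regimes = simulate_concentration(
        model, n_steps, rng, forced_switch_time=forced_switch_time
    )
    if y0_policy == "zero":
        y0 = np.zeros(Ns, dtype=np.int64)
    elif y0_policy == "random":
        y0 = rng.integers(0, min(10, params.NT + 1), size=Ns)
    else:
        raise ValueError(f"unknown y0_policy {y0_policy!r}")
    sample = simulate_counts_ssa if sampler == "ssa" else simulate_counts_exact
    counts = np.column_stack(
        [sample(params, C_true, int(y0[j]), rng) for j in range(Ns)]
    )
    dt = params.dt
    ds = Dataset(
        times=dt * np.arange(1, n_steps + 1),
        C_true=C_true,
        counts=counts,
        y0=y0,
        x0=model.x0,
        params=params,
        regimes=regimes,
    )
    if csv_path is not None:
        ds.to_csv(csv_path)
    return ds
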