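"""Kalman filtering with the moment-matched Gaussian observation model.

The state is the scalar local concentration x_k [M] following a random walk
(state Jacobian exactly 1).  The observation of sensor j is its occupancy
count, approximated as

    y_kj ~ N( h(x_k, y_{k-1,j}),  r(x_k, y_{k-1,j}) )

where h and r are the exact conditional mean and variance of the
convolved-binomial kernel (moment matching is exact for binomials) and the
observation Jacobian dh/dC is analytic.  The jump-Markov extension is the
second-order generalized pseudo-Bayesian (GPB2) filter: one Kalman branch
per recent regime pair, merged back to one Gaussian per current regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .sensor_model import SensorParams, occupancy_fraction_arrays, \
    occupancy_fraction_derivatives
from .simulator import Dataset, RegimeModel

__all__ = [
    "GaussianBelief",
    "JumpBelief",
    "FilterResult",
    "kf_predict",
    "linearize_obs",
    "kf_update",
    "kf_run",
    "gpb2_step",
    "gpb2_run",
]

logger = logging.getLogger(__name__)

#: Absolute floor on the per-sensor observation variance [counts^2].  At a
#: clipped linearization point (C = 0, empty sensor) the Gaussian model's
#: variance is exactly zero while its concentration gradient is not, so an
#: unfloored update acquires unbounded information, collapses the state
#: covariance and leaves the filter unable to absorb the next nonzero
#: count.  1e-4 is ~1% of a typical operating variance (~1e-2), bounding
#: the per-step information while leaving regular updates unchanged.
_R_FLOOR = 1e-4

# negative-concentration clipping is routine during the initial transient;
# warn once, then demote to debug
_warned_negative_clip = False


@dataclass(frozen=True)
class GaussianBelief:
    """Scalar mean/variance state estimate: x ~ N(mean, cov)."""

    mean: float
    cov: float

    def __post_init__(self) -> None:
        if self.cov < 0:
            raise ValueError("covariance must be nonnegative")


@dataclass
class JumpBelief:
    """One Gaussian belief per current regime plus regime probabilities."""

    beliefs: list[GaussianBelief]
    regime_probs: np.ndarray

    def __post_init__(self) -> None:
        self.regime_probs = np.asarray(self.regime_probs, dtype=float)
        if len(self.beliefs) != len(self.regime_probs):
            raise ValueError("one belief per regime required")
        if np.any(self.regime_probs < 0) or \
                abs(self.regime_probs.sum() - 1.0) > 1e-9:
            raise ValueError("regime_probs must be a probability vector")


@dataclass
class FilterResult:
    """Per-step filter output.

    ``means``/``covs`` are the raw posterior moments; ``estimates`` is the
    reported point estimate, floored at zero (physical concentration).
    ``regime_probs`` is (K, H) for jump filters, None otherwise.
    """

    times: np.ndarray
    means: np.ndarray
    covs: np.ndarray
    regime_probs: np.ndarray | None = None

    @property
    def estimates(self) -> np.ndarray:
        return np.maximum(self.means, 0.0)

    def to_frame(self):
        import pandas as pd

        cols = {"t": self.times, "estimate": self.estimates,
                "variance": self.covs}
        if self.regime_probs is not None:
            for h in range(self.regime_probs.shape[1]):
                cols[f"p_regime_{h + 1}"] = self.regime_probs[:, h]
        return pd.DataFrame(cols)


def kf_predict(belief: GaussianBelief, q: float) -> GaussianBelief:
    """Time update for the random-walk state: mean unchanged, cov += q."""
    if q < 0:
        raise ValueError("process variance must be nonnegative")
    return GaussianBelief(belief.mean, belief.cov + q)


def linearize_obs(
    params: SensorParams, C: float, y_prev_vec: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observation mean, Jacobian and noise variance per sensor at C.

    Returns ``(h, Cbar, R)``: predicted counts, analytic dh/dC and the
    per-sensor observation variances (the diagonal measurement-noise
    matrix).  Negative C is clipped to 0 for robustness, with a warning.
    """
    if C < 0:
        global _warned_negative_clip
        if not _warned_negative_clip:
            logger.warning("linearize_obs: clipping negative concentration %g "
                           "(further occurrences logged at DEBUG)", C)
            _warned_negative_clip = True
        else:
            logger.debug("linearize_obs: clipping negative concentration %g", C)
        C = 0.0
    y_prev = np.asarray(y_prev_vec, dtype=float)
    lamF, lamE = occupancy_fraction_arrays(params, np.asarray(C))
    dlamF, dlamE = occupancy_fraction_derivatives(params, np.asarray(C))
    nE = params.NT - y_prev
    h = y_prev * lamF + nE * lamE
    Cbar = y_prev * dlamF + nE * dlamE
    R = y_prev * lamF * (1.0 - lamF) + nE * lamE * (1.0 - lamE)
    return h, Cbar, R


def _update_with_loglik(
    prior: GaussianBelief,
    y_vec: np.ndarray,
    y_prev_vec: np.ndarray,
    params: SensorParams,
) -> tuple[GaussianBelief, float]:
    """Innovation update; also returns the Gaussian innovation log-likelihood.

    With a scalar state the innovation covariance S = D + P c c^T is
    diagonal-plus-rank-one, so the gain, posterior and innovation
    log-likelihood come out in closed form (Sherman-Morrison /
    matrix-determinant lemma) in O(Ns):

        s1 = c^T D^-1 nu,  s2 = c^T D^-1 c,  a = 1 + P s2
        mean + = P s1 / a,     cov = P / a
        log|S| = sum log d + log a,  nu^T S^-1 nu = nu^T D^-1 nu - P s1^2 / a
    """
    y = np.asarray(y_vec, dtype=float)
    h, Cbar, R = linearize_obs(params, prior.mean, y_prev_vec)
    nu = y - h
    if np.all(R == 0.0) and np.all(Cbar == 0.0):
        logger.warning("kf_update: non-informative observation, skipping update")
        return prior, 0.0
    d = R + _R_FLOOR
    P = prior.cov
    c_over_d = Cbar / d
    s1 = float(c_over_d @ nu)
    s2 = float(c_over_d @ Cbar)
    alpha = 1.0 + P * s2
    mean = prior.mean + P * s1 / alpha
    cov = max(P / alpha, 0.0)
    quad = float(nu @ (nu / d)) - P * s1 * s1 / alpha
    logdet = float(np.sum(np.log(d))) + math.log(alpha)
    loglik = -0.5 * (len(y) * math.log(2.0 * math.pi) + logdet + quad)
    return GaussianBelief(mean, cov), loglik


def kf_update(
    prior: GaussianBelief,
    y_vec: np.ndarray,
    y_prev_vec: np.ndarray,
    params: SensorParams,
) -> GaussianBelief:
    """Measurement update against the stacked multi-sensor observation."""
    post, _ = _update_with_loglik(prior, y_vec, y_prev_vec, params)
    return post


def kf_run(dataset: Dataset, init: GaussianBelief, q: float) -> FilterResult:
    """Filter a whole dataset; the first update conditions on the recorded y0."""
    K = dataset.n_steps
    means = np.empty(K)
    covs = np.empty(K)
    belief = init
    y_prev = dataset.y0
    for k in range(K):
        belief = kf_predict(belief, q)
        belief = kf_update(belief, dataset.counts[k], y_prev, dataset.params)
        means[k] = belief.mean
        covs[k] = belief.cov
        y_prev = dataset.counts[k]
    return FilterResult(times=dataset.times, means=means, covs=covs)


def gpb2_step(
    belief: JumpBelief,
    y_vec: np.ndarray,
    y_prev_vec: np.ndarray,
    params: SensorParams,
    regime: RegimeModel,
) -> tuple[JumpBelief, float, float]:
    """One GPB2 branch/merge cycle.

    Branching runs a Kalman predict (process variance of the arriving
    regime) and update for every ordered regime pair (r_prev, r), recording
    the innovation log-likelihood.  Joint branch weights combine the
    previous regime posterior, the transition probability and that
    likelihood; merging collapses branches sharing r into one Gaussian
    (mean mixture plus spread-of-means covariance inflation).

    Returns (new belief, overall point estimate, overall covariance).
    """
    H = regime.H
    log_prior = np.full(H, -np.inf)
    pos = belief.regime_probs > 0
    log_prior[pos] = np.log(belief.regime_probs[pos])
    with np.errstate(divide="ignore"):
        log_Pi = np.log(regime.Pi)

    branch_mean = np.zeros((H, H))
    branch_cov = np.zeros((H, H))
    log_w = np.full((H, H), -np.inf)
    for rp in range(H):
        if not np.isfinite(log_prior[rp]):
            continue
        for r in range(H):
            if not np.isfinite(log_Pi[rp, r]):
                continue
            prior = kf_predict(belief.beliefs[rp], float(regime.qs[r]))
            post, ll = _update_with_loglik(prior, y_vec, y_prev_vec, params)
            branch_mean[rp, r] = post.mean
            branch_cov[rp, r] = post.cov
            log_w[rp, r] = log_prior[rp] + log_Pi[rp, r] + ll

    m = log_w.max()
    if not np.isfinite(m):
        logger.warning("gpb2_step: all branch likelihoods vanished; "
                       "falling back to transition-prior weights")
        log_w = log_prior[:, None] + log_Pi
        m = log_w.max()
    w = np.exp(log_w - m)
    w /= w.sum()  # joint p(r_prev, r | Y_k)

    p_r = w.sum(axis=0)
    new_beliefs: list[GaussianBelief] = []
    for r in range(H):
        if p_r[r] <= 0.0:
            # unreachable regime this step; carry its old belief forward
            new_beliefs.append(belief.beliefs[r])
            continue
        cw = w[:, r] / p_r[r]  # p(r_prev | r, Y_k)
        mean_r = float(cw @ branch_mean[:, r])
        cov_r = float(cw @ (branch_cov[:, r]
                            + (branch_mean[:, r] - mean_r) ** 2))
        new_beliefs.append(GaussianBelief(mean_r, cov_r))

    est = float(p_r @ [b.mean for b in new_beliefs])
    cov = float(p_r @ [b.cov + (b.mean - est) ** 2 for b in new_beliefs])
    return JumpBelief(new_beliefs, p_r), est, cov


def gpb2_run(
    dataset: Dataset, init: JumpBelief, regime: RegimeModel
) -> FilterResult:
    """GPB2 recursion over a dataset; outputs estimates and p(r_k | Y_k)."""
    K = dataset.n_steps
    means = np.empty(K)
    covs = np.empty(K)
    probs = np.empty((K, regime.H))
    belief = init
    y_prev = dataset.y0
    for k in range(K):
        belief, est, cov = gpb2_step(
            belief, dataset.counts[k], y_prev, dataset.params, regime
        )
        means[k] = est
        covs[k] = cov
        probs[k] = belief.regime_probs
        y_prev = dataset.counts[k]
    return FilterResult(times=dataset.times, means=means, covs=covs,
                        regime_probs=probs)
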