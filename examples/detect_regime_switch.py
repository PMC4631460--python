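"""Detect a tumor-like concentration drift with the jump-Markov filters.

Simulates a cell that switches from a quiescent regime (process variance
1e-16 M^2/step) to a drifting regime (5e-14 M^2/step) at t = 2000 s of a
4000 s run, observed through five sensors.  Runs the regime-aware filters
(GPB2 Kalman and jump-Markov particle filter) against their single-regime
counterparts on the same data and prints post-switch tracking errors and
the inferred drift-regime probability.
"""

import numpy as np

from cntsense import (
    GaussianBelief,
    JumpBelief,
    ProcessModel,
    RegimeModel,
    SensorParams,
    generate_dataset,
    gpb2_run,
    kf_run,
    pf_run,
    pfmcmc_run,
)
from cntsense.benchmark import scaled_rmse

params = SensorParams(kA=100.0, kD=1e-3, NT=10, dt=1.0)
regime = RegimeModel(Pi=np.array([[0.99, 0.01], [0.01, 0.99]]),
                     qs=np.array([1e-16, 5e-14]))
model = ProcessModel(kind="regime_switching", regime=regime, x0=1e-5)

switch = 2000
ds = generate_dataset(model, params, Ns=5, n_steps=4000, y0_policy="random",
                      rng_seed=5, forced_switch_time=switch)
print(f"truth: quiescent until t = {switch} s, drifting afterwards; "
      f"ends at {ds.C_true[-1]:.3e} M")

init_mean, init_var = 2e-5, 1e-10
kf = kf_run(ds, GaussianBelief(init_mean, init_var), q=1e-16)
gpb2 = gpb2_run(ds, JumpBelief([GaussianBelief(init_mean, init_var)] * 2,
                               np.array([1.0, 0.0])), regime)
pf = pf_run(ds, init_mean, init_var, M=200, q=1e-16, rng_seed=11)
pfm = pfmcmc_run(ds, init_mean, init_var, M=200, regime=regime, rng_seed=11)

truth_post = ds.C_true[switch:]
print("\npost-switch scaled RMSE (1.0 = 10 uM error):")
for name, res in (("KF (single regime)", kf), ("KF-GPB2", gpb2),
                  ("PF (single regime)", pf), ("PF-MCMC", pfm)):
    rmse = scaled_rmse(truth_post, res.estimates[switch:])
    print(f"  {name:20s} {rmse:.4f}")
print("(the regime-aware filters follow the drift; the single-regime "
      "filters assume it cannot happen and lag)")

for name, res in (("KF-GPB2", gpb2), ("PF-MCMC", pfm)):
    p2 = res.regime_probs[:, 1]
    print(f"{name}: mean P(drift regime) before switch "
          f"{p2[:switch].mean():.3f}, after {p2[switch:].mean():.3f}")
print("(single count observations barely separate the two step variances, "
      "so the regime posterior moves little from the chain's 50/50 "
      "stationary law — the tracking gain comes from branch-adaptive "
      "process noise, not from a confident regime call)")
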