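"""Receptive-field development with twenty inputs.

Trains a neuron on 20 circulant triangular stimuli (width 0.5) with the
weight-dependent rule at increasing feed-forward inhibition, and prints
the selectivity s and the excitation/inhibition imbalance m at each
level; standard BCM is shown for comparison.
"""

import numpy as np

import wdbcm as wb

ensemble = wb.make_triangular(20, 20, 0.5)

print(f"{'rule':>17s} {'u':>5s} {'s':>7s} {'m':>7s} {'active stimuli':>15s}")
for u in (0.5, 2.0, 5.0, 10.0):
    cfg = wb.PlasticityConfig(
        rule="weight_dependent", u=u, tau_theta=200, tau_w=2000,
        rng_seed=11, transfer=wb.TransferSpec("rectified"),
    )
    traj = wb.simulate(ensemble, cfg, n_presentations=300_000, record_every=20_000)
    y = traj.responses[-1]
    s = wb.selectivity(y)
    m = wb.imbalance(traj.final_state.w, u, ensemble)
    print(f"{'weight_dependent':>17s} {u:5.1f} {s:7.3f} {m:7.3f} {int(np.sum(y > 1e-6)):15d}")

cfg = wb.PlasticityConfig(
    rule="standard", tau_theta=200, tau_w=2000, rng_seed=11,
    transfer=wb.TransferSpec("rectified"),
)
traj = wb.simulate(ensemble, cfg, n_presentations=1_200_000, record_every=20_000)
y = traj.responses[-1]
print(f"{'standard':>17s} {'-':>5s} {wb.selectivity(y):7.3f} {'-':>7s} "
      f"{int(np.sum(y > 1e-6)):15d}")

print()
print("Selectivity rises and the E/I imbalance falls as inhibition grows;")
print("standard BCM reaches the fully selective winner-take-all state (s = 1).")
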