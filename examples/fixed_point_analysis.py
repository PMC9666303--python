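"""Phase-plane analysis: fixed points, stability and critical inhibition.

Enumerates every fixed point of the mean-field learning dynamics on the
phi = 0.4 stimulus pair at weak (u = 1.3) and strong (u = 2.3)
inhibition, and prints the critical inhibition levels bracketing the
weight-dependent regime.
"""

import numpy as np

import wdbcm as wb

ensemble = wb.make_pair2d(0.4)

u_star = float(np.max(wb.critical_inhibition_upper(ensemble)))
u_ss = wb.critical_inhibition_lower(ensemble)
print(f"critical inhibition: u* = {u_star:.4f} (winner-take-all above),")
print(f"                     u** = {u_ss:.4f} (weights pin at (-u,-u) below)")
print()

for u in (1.3, 2.3):
    cfg = wb.PlasticityConfig(rule="weight_dependent", u=u, tau_theta=20, tau_w=200)
    print(f"u = {u}:")
    for fp in wb.all_fixed_points_2d(ensemble, cfg):
        mark = "stable " if fp.stable else "unstable"
        print(f"  {mark} {fp.classification.value:20s} w = {np.round(fp.w_star, 3)}"
              f"  y = {np.round(fp.responses, 3)}")
    nc = wb.nullclines_2d(ensemble, cfg)
    crossings = wb.count_nullcline_crossings(nc, ensemble, cfg)
    print(f"  null-clines intersect {len(crossings)} times (origin counted separately)")
    print()

print("Below u* the winner-take-all points lose stability and a mirror pair")
print("of partially selective fixed points takes over; at u > u* they merge")
print("and the standard BCM solution is recovered.")
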