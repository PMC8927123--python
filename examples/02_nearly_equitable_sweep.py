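"""Detect nearly equitable clusters in a noisy network.

Perturbs the planted network with 10% multiplicative noise (so no exact
equitable partition survives), sweeps k = 2..N-1 with the k-medoids
variant of the refinement, and scores every partition with the
correction cost psi(k) and its scaled form psi_hat(k) = k psi(k).
"""

import dyncomm as dc
from dyncomm.network import random_quotient

spec = dc.QuotientSpec((10, 4, 7, 20, 9), random_quotient(5, seed=1))
net, planted = dc.planted_equitable_network(spec, seed=1)
noisy = dc.perturb(net, epsilon=0.1, kind="type1", seed=2)

sweep = dc.dynamical_communities_sweep(noisy, seed=3)
profile = dc.cost_profile(noisy, sweep)

k_best = profile.k_at_min_psi_hat()
print("k    psi      psi_hat")
for k, p, ph in list(zip(profile.ks, profile.psi, profile.psi_hat))[:8]:
    print(f"{k:<4d} {p:8.3f} {ph:8.3f}")
print(f"global minimum of psi_hat at k = {k_best}")
print(f"partition there matches planted: {sweep[k_best] == planted}")
# psi_hat penalizes the trivial decrease of psi with k; its global
# minimum marks the planted cluster count.
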