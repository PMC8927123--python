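"""Generate a network with planted equitable clusters and recover them.

Builds a 50-node weighted directed network whose 5 planted clusters
(sizes 10, 4, 7, 20, 9) form an exactly equitable partition, then runs
the iterative cluster-degree refinement from the all-in-one-cluster
start.
"""

import dyncomm as dc
from dyncomm.network import random_quotient

spec = dc.QuotientSpec((10, 4, 7, 20, 9), random_quotient(5, seed=1))
net, planted = dc.planted_equitable_network(spec, seed=1)

mbc = dc.minimum_balanced_coloring(net)
psi = dc.correction_cost(net, mbc)

print(f"planted clusters : {planted.k} (sizes {tuple(int(s) for s in planted.sizes())})")
print(f"recovered k*     : {mbc.k}")
print(f"matches planted  : {mbc == planted}")
print(f"correction cost  : {psi:.2e}")
# k* is the number of clusters of the minimum balanced coloring; the
# correction cost is ~0 because the partition is exactly equitable.
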