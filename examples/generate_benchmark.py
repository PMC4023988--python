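"""Generate a planted-partition benchmark graph and inspect its structure.

Draws one 60x120 network with three mode-1 communities targeting only two
mode-2 communities (the unequal_3_2 design), prints its exact density, the
fixed mode-1 degree, and the fraction of ties that landed inside their
designated region (binomially distributed around p_within = 0.9).
"""

import numpy as np

from bicomm import generate, small_config

cfg = small_config("unequal_3_2", seed=42)
graph, truth = generate(cfg)

k, d = graph.degrees()
print(f"network: {graph.n1} x {graph.n2}, {graph.m} edges, density {graph.density:.3f}")
print(f"mode-1 degrees: all equal to {k.min()} (= round(density * n2))")
print(f"mode-2 degrees: min {d.min()}, mean {d.mean():.1f}, max {d.max()} (free)")
print(f"planted communities: {truth.labels1.k} in mode 1, {truth.labels2.k} in mode 2")

regions = [set(range(60)), set(range(40, 80)), set(range(60, 120))]
sub = np.arange(60) // 20
within = sum(1 for i, j in graph.edges if j in regions[sub[i]])
print(f"within-region tie fraction: {within / graph.m:.3f} (target 0.9)")
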