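"""Structural metrics of one ego network.

Density is the realized share of possible alter-alter ties; components
count disconnected sub-groups (isolates included); Freeman degree
centralization is 1 when one alter dominates connectivity and 0 when all
degrees are equal.  Per-alter normalized degree and betweenness feed the
regression models after pooled z-scoring.
"""

from egosmoke import generate_population, network_metrics

networks, _ = generate_population(seed=1)
net = networks[0]
m = network_metrics(net)
print(f"ego {m.ego_id}: {m.n_alters} alters, {len(net.ties)} ties")
print(f"  density                : {m.density:.3f}")
print(f"  components             : {m.n_components}")
print(f"  degree centralization  : {m.degree_centralization:.3f}")
top = max(m.degree_norm, key=m.degree_norm.get)
print(f"  best-connected alter   : {top} "
      f"(degree {m.degree_norm[top]:.2f}, "
      f"betweenness {m.betweenness_norm[top]:.2f})")
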