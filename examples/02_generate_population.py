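"""Generate a synthetic population and check its descriptive profile.

Draws the default 76-ego population (20-25 alters each, planted-partition
alter graphs, homophily 0.3) and prints the descriptive summary: smoking
prevalences should sit near the configured 27.1/11.3/61.6% for alters,
mean density near 0.3, and a small median component count.
"""

from egosmoke import generate_population, summarize_population

networks, truth = generate_population(seed=1)
print(f"{len(networks)} ego networks, "
      f"{sum(n.n_alters for n in networks)} alters, "
      f"planted homophily h = {truth.homophily}")
print(summarize_population(networks).to_string(index=False))
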