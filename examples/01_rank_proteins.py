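"""Rank proteins by predicted essentiality with the ensemble framework.

Builds a synthetic benchmark (planted co-expressed essential cliques,
decoy hubs, random background), runs the ensemble with degree centrality
as base measure, and compares its top-60 hit count with plain degree
centrality.
"""

from encentra import (
    SyntheticSpec,
    degree_centrality,
    essential_in_top,
    generate,
    rank,
    run_ensemble,
)

spec = SyntheticSpec(seed=1)
net, expr, essential = generate(spec)
print(f"benchmark: {net.number_of_nodes()} proteins, {net.number_of_edges()} "
      f"interactions, {len(essential)} planted essential proteins")

ensemble = run_ensemble(net, expr, measure="DC", strategy="absolute")
plain = rank(degree_centrality(net))

n = 60
print(f"essential proteins in top {n}:")
print(f"  EnDC-a (ensemble, dominant weighting): {essential_in_top(ensemble, essential, n)}")
print(f"  DC (plain degree):                     {essential_in_top(plain, essential, n)}")
print("the ensemble concentrates on proteins whose interactions survive the")
print("co-expression thresholds; degree alone is captured by the decoy hubs")
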