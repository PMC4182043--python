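"""Node-removal reliability: random failure versus targeted hub attack.

Removes 0-10% of the integrated network's nodes and tracks global
efficiency and normalized structure entropy.  A heterogeneous but
redundant network barely notices random removal; hub-targeted removal
bites harder.
"""

from llgcrep import (
    RemovalExperiment,
    SyntheticSpec,
    build_integrated_graph,
    generate,
    run_experiment,
)

net, drug_sim, _, _ = generate(SyntheticSpec(seed=1))
g = build_integrated_graph(net, "M4", drug_sim, tau=0.5)
print(f"M4: {g.n_nodes} nodes, {g.n_edges} edges\n")

for mode in ("random", "targeted"):
    df = run_experiment(g, RemovalExperiment(mode=mode, fractions=[0.0, 0.05, 0.10],
                                             n_reps=20, seed=17))
    print(f"{mode} removal (random = mean of 20 repeats):")
    print(df.round(4).to_string(index=False), "\n")

print("efficiency at 10% random removal stays within a few percent of the "
      "intact value: the network is shock-resistant")
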