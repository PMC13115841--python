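"""Guimera-Amaral cartography: within-module degree z and participation P.

A star center wired only inside its own community is a provincial hub (R5);
its leaves are ultra-peripheral (R1).
"""

from socionet.cartography import cartography_profiles, detect_communities, graph_from_edges

nodes = ["hub"] + [f"leaf{i}" for i in range(10)] + ["x", "y", "z"]
edges = [("hub", f"leaf{i}") for i in range(10)]
edges += [("x", "y"), ("y", "z"), ("x", "z")]
g = graph_from_edges(nodes, edges)

part = detect_communities(g, seed=0)
print(f"communities: {len(set(part.assignment.values()))}, Q = {part.q:.3f}")

profiles = cartography_profiles(g, part.assignment)
print(profiles.to_string(index=False))
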