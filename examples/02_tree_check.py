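"""Topology test: is the query nested inside a supported alien clade?

Evaluates the three canonical patterns (nested-with-support, sister to
bacteria, nested-but-weakly-supported) and one simulated tree.
"""

from hgtscreen.synthetic_data import simulate_hgt_tree
from hgtscreen.tree_hgt import hgt_topology_test, read_newick

labels = {
    "P1": "Eukaryota",
    "P2": "Eukaryota",
    "B1": "Bacteria",
    "B2": "Bacteria",
    "Q": "Bacteria",
}
cases = {
    "query inside plant clade, support 0.95": "((Q,(P1,P2)0.9)0.95,(B1,B2)0.9);",
    "query sister to a bacterium": "((Q,B1)0.99,(P1,P2)0.9);",
    "plant clade but support only 0.5": "((Q,(P1,P2)0.9)0.5,(B1,B2)0.9);",
}
for desc, newick in cases.items():
    call = hgt_topology_test(read_newick(newick, is_string=True), "Q", labels)
    print(f"{desc:<42} -> {call.verdict}  (support={call.clade_support}, "
          f"purity={call.alien_purity:.2f})")

sim = simulate_hgt_tree(place_query="donor", seed=1)
call = hgt_topology_test(
    read_newick(sim.newick, is_string=True), sim.query_label, sim.label_map
)
print(f"\nsimulated query-in-donor-clade tree              -> {call.verdict}")

# hgt_consistent requires the smallest clade around the query to be pure
# alien (p_min=1.0) AND supported (s_min=0.8); weak support downgrades the
# call to 'unsupported' rather than accepting or rejecting it outright.
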