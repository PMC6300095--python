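"""Alien-hit-fraction screening of a (synthetic) proteome.

Builds a 200-query hit table with 10 planted high-alien-fraction queries,
screens it at the 80% threshold, and prints the top of the candidate list.
"""

from hgtscreen.hit_screen import screen_proteome
from hgtscreen.synthetic_data import simulate_hit_tables

sim = simulate_hit_tables(n_background=190, n_planted=10, seed=42)
results = screen_proteome(sim.hit_table, sim.taxonomy.table, tau=0.80)

candidates = [r for r in results if r.candidate]
print(f"{len(results)} queries screened, {len(candidates)} candidates at tau=0.80\n")
print("query        alien  focal  fraction  planted?")
for r in results[:12]:
    planted = "yes" if r.query_id in sim.planted_ids else "no"
    print(
        f"{r.query_id:<12} {r.n_alien:>5}  {r.n_focal:>5}  "
        f"{r.alien_fraction:>7.3f}   {planted}"
    )

# The alien fraction is the share of a query's homology hits whose taxon
# lies outside Bacteria; queries at or above 0.80 are HGT candidates for
# tree-based confirmation.  Planted queries should dominate the top rows.
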