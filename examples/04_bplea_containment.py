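"""Gene-in-island containment for the published BPLEA coordinates.

Pure interval arithmetic on the published gene positions and predicted
island regions of the three BPLEA-carrying contigs.
"""

from hgtscreen.bplea import bplea_containment_table

table = bplea_containment_table()
cols = ["species", "gene", "predictor", "relation", "nearest_distance_bp"]
print(table[cols].to_string(index=False))

# 'contained' means the predicted region fully covers the gene - the
# pattern expected if the expansin gene rode into the genome on a mobile
# island.  The a10 gene is 2,791 bp outside its nearest Alien_Hunter
# region, so only two of the three strains show the containment signal.
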