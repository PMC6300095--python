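"""Isoelectric points of expansin-style domain segments, per pKa preset.

Builds two toy two-domain proteins (an acidic and a basic C-terminal
domain) and prints their per-domain pI under each shipped pKa preset.
"""

from hgtscreen.domain_pi import PKA_SETS, domain_pi_table, pi_preset_comparison

proteins = {
    "acidic_cbd": "MKARH" + "G" * 95 + "DDCEEYDE" + "G" * 42,
    "basic_cbd": "MDAEE" + "G" * 95 + "KKRRHKRH" + "G" * 42,
}
annotations = [
    ("acidic_cbd", "DPBB", "IPR007112", 1, 100),
    ("acidic_cbd", "CBD", "IPR007117", 101, 150),
    ("basic_cbd", "DPBB", "IPR007112", 1, 100),
    ("basic_cbd", "CBD", "IPR007117", 101, 150),
]

print(domain_pi_table(proteins, annotations).to_string(index=False))
print()
comp = pi_preset_comparison(proteins, annotations, list(PKA_SETS))
print(comp.to_string(index=False))

# The pI is the pH at which the Henderson-Hasselbalch net charge of the
# segment vanishes.  Published pI tables rarely state their pKa constants,
# so the comparison view shows how far the presets can move each value -
# differences of a few tenths of a pH unit are normal.
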