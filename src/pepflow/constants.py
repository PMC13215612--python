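"""Physical constants used throughout (monoisotopic, Da)."""

PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863

# Sentinel token symbols.
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
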